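"""Validated pipeline configuration.

All stage parameters live in one YAML-loadable config with strict
validation: unknown keys are rejected and thresholds are range-checked,
so a typo fails loudly instead of silently running with a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DepOptions(_Strict):
    control_group: str = "pte_neg"
    experimental_group: str = "pte_pos"
    fc_threshold: float = Field(1.2, gt=1.0)
    adj_p_threshold: float = Field(0.1, gt=0.0, le=1.0)
    presence_fraction: float = Field(0.5, gt=0.0, le=1.0)
    log_scale: bool = True
    equal_var: bool = False


class FbaOptions(_Strict):
    model_path: str | None = None
    gpr_policy: str = "geometric_mean"
    proton_metabolite: str = "h_i"


class NetworkOptions(_Strict):
    min_confidence: float = Field(0.7, ge=0.0, le=1.0)
    weights: dict[str, float] | None = None
    damping: float = Field(0.85, gt=0.0, lt=1.0)
    fc_min: float = Field(1.5, gt=0.0)
    top_k: int = Field(10, ge=1)


class EegOptions(_Strict):
    min_duration_s: float = Field(5.0, gt=0.0)
    amplitude_ratio: float = Field(3.0, gt=0.0)
    require_evolution: bool = True


class SimulateOptions(_Strict):
    n_proteins: int = Field(300, ge=1)
    n_planted: int = Field(20, ge=0)
    planted_log2fc: float = 1.0
    noise_sd: float = Field(0.2, ge=0.0)
    dropout_rate: float = Field(0.0, ge=0.0, lt=1.0)
    biological_replicates_per_group: int = Field(5, ge=2)
    technical_replicates: int = Field(2, ge=1)
    ppin_nodes: int = Field(40, ge=3)
    ppin_hubs: int = Field(2, ge=1)
    eeg_duration_s: float = Field(300.0, gt=0.0)
    eeg_fs: float = Field(256.0, ge=100.0)
    model_capacity: float = Field(10.0, gt=0.0)


class PipelineConfig(_Strict):
    seed: int = 0
    deps: DepOptions = DepOptions()
    fba: FbaOptions = FbaOptions()
    network: NetworkOptions = NetworkOptions()
    eeg: EegOptions = EegOptions()
    simulate: SimulateOptions = SimulateOptions()


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
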