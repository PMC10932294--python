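"""Intensity-table container shared by the proteomics stages.

An :class:`AbundanceTable` holds a peptide- or protein-level intensity
matrix (rows = entities, columns = sample runs) together with the run
design: which experimental group each run belongs to and which biological
and technical replicate it is. Missing values (``NaN``) mean *not
detected* — label-free LC–MS/MS intensities are strictly positive where a
peptide was observed at all, so zero is never a valid detected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "DESIGN_COLUMNS"]

DESIGN_COLUMNS = ["group", "biological_replicate", "technical_replicate"]


class DataError(ValueError):
    """Raised when a table violates the contract it declares."""


@dataclass
class AbundanceTable:
    """Intensity matrix plus run annotations.

    Parameters
    ----------
    intensities
        DataFrame with entity ids (peptides or proteins) as the index and
        run ids as columns. ``NaN`` encodes "not detected"; detected
        values must be > 0.
    design
        DataFrame indexed by run id with columns ``group``,
        ``biological_replicate`` and ``technical_replicate``.
    peptide_to_protein
        Optional mapping used by the peptide→protein rollup.
    detection
        Optional per-entity detection counts (filled in by
        :func:`blastpte.proteomics.average_technical_replicates`): a
        DataFrame with a two-level column index ``(group, {"detected",
        "total"})`` counting technical runs.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    peptide_to_protein: dict[str, str] | None = None
    detection: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise DataError(f"design is missing columns {missing}")
        runs = set(self.intensities.columns)
        annotated = set(self.design.index)
        if runs - annotated:
            raise DataError(f"runs without design rows: {sorted(runs - annotated)[:5]}")
        if self.design.index.has_duplicates:
            raise DataError("duplicate run ids in design")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise DataError("detected intensities must be strictly positive")

    # -- convenience ------------------------------------------------------
    @property
    def runs(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.design.loc[self.runs, "group"]))

    def runs_in_group(self, group: str) -> list[str]:
        mask = self.design.loc[self.runs, "group"] == group
        return [r for r, m in zip(self.runs, mask) if m]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask, same shape as ``intensities``."""
        return self.intensities.notna()

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, intensity_path: str | Path, design_path: str | Path) -> None:
        """Write the matrix and its sidecar design file as TSV."""
        ints = self.intensities.copy()
        ints.index.name = "entity"
        ints.to_csv(intensity_path, sep="\t")
        design = self.design.copy()
        design.index.name = "run"
        design.to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        intensity_path: str | Path,
        design_path: str | Path,
        peptide_to_protein: dict[str, str] | None = None,
    ) -> "AbundanceTable":
        ints = pd.read_csv(intensity_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(ints, design, peptide_to_protein=peptide_to_protein)
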