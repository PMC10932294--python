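"""Label-free differential-protein analysis.

The processing chain mirrors the standard label-free workflow for
shotgun LC–MS/MS run in technical duplicate:

1. :func:`normalize_peptide_intensities` — total-intensity normalization
   so every sample run sums to the same total.
2. :func:`rollup_peptides_to_proteins` — protein abundance as the sum of
   its detected peptides.
3. :func:`average_technical_replicates` — technical runs of one animal
   averaged before any cross-animal statistics; per-group technical
   detection counts are retained for the presence filter.
4. :func:`compute_group_stats` — per-protein fold change and a two-sample
   t-test (Welch by default, on log2 intensities) with
   Benjamini–Hochberg FDR adjustment across proteins.
5. :func:`call_deps` — differentially-expressed-protein (DEP) flags from
   the conjunction of a fold-change threshold (default 1.2, two-sided on
   the linear ratio), an adjusted-p threshold (default 0.1) and a
   presence filter (detected in at least half of the overexpressing
   group's technical runs, the 5-of-10 rule for a 5-animal × 2-run
   design).

Proteins undetected in one entire group have no finite ratio and no
t-test; they carry a *sentinel* fold change instead — 100 when absent
from the control group, 0.1 when absent from the experimental group —
and are reported as a separate DEP stratum gated only by the presence
filter.

:func:`ora_enrichment` is a generic hypergeometric over-representation
test for annotation sets (e.g. GO terms supplied as plain id sets).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, DataError

__all__ = [
    "normalize_peptide_intensities",
    "rollup_peptides_to_proteins",
    "average_technical_replicates",
    "benjamini_hochberg",
    "compute_group_stats",
    "call_deps",
    "ora_enrichment",
    "RESULT_COLUMNS",
    "SENTINEL_ABSENT_CONTROL",
    "SENTINEL_ABSENT_EXPERIMENTAL",
]

log = logging.getLogger(__name__)

#: fold-change placeholder for a protein never detected in the control group
SENTINEL_ABSENT_CONTROL = 100.0
#: fold-change placeholder for a protein never detected in the experimental group
SENTINEL_ABSENT_EXPERIMENTAL = 0.1

RESULT_COLUMNS = [
    "protein",
    "mean_control",
    "mean_experimental",
    "fc",
    "log2fc",
    "pvalue",
    "padj",
    "presence_count",
    "presence_total",
    "sentinel",
    "is_dep",
    "dep_stratum",
]


def normalize_peptide_intensities(table: AbundanceTable) -> AbundanceTable:
    """Equalize total intensity across sample runs.

    Every run is rescaled so its summed intensity equals the mean of the
    input run totals; within-run relative intensities are untouched.
    """
    totals = table.intensities.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DataError(f"runs with zero total intensity: {bad}")
    target = totals.mean()
    scaled = table.intensities * (target / totals)
    return AbundanceTable(
        scaled, table.design, peptide_to_protein=table.peptide_to_protein
    )


def rollup_peptides_to_proteins(
    table: AbundanceTable,
    peptide_to_protein: dict[str, str] | None = None,
    on_unmapped: str = "error",
) -> AbundanceTable:
    """Sum peptide intensities into protein abundances.

    A protein is absent in a run iff all of its peptides are absent
    there. ``on_unmapped`` controls peptides without a protein
    assignment: ``"error"`` (default) raises, ``"drop"`` discards them
    with a warning.
    """
    mapping = peptide_to_protein or table.peptide_to_protein
    if mapping is None:
        raise ValueError("no peptide→protein mapping available")
    unmapped = [p for p in table.intensities.index if p not in mapping]
    if unmapped:
        if on_unmapped == "drop":
            warnings.warn(f"dropping {len(unmapped)} unmapped peptides")
        else:
            raise DataError(f"unmapped peptides: {unmapped[:5]}")
    kept = table.intensities.drop(index=unmapped)
    groups = pd.Series({p: mapping[p] for p in kept.index}, name="protein")
    # min_count=1 keeps NaN where every peptide of the protein is absent
    rolled = kept.groupby(groups).sum(min_count=1)
    rolled.index.name = "protein"
    return AbundanceTable(rolled, table.design)


def average_technical_replicates(table: AbundanceTable) -> AbundanceTable:
    """Collapse technical runs of each animal to their mean.

    The mean is taken over the runs in which the entity was detected; the
    entity counts as detected for an animal if it was seen in at least
    one of its technical runs. Per-group technical detection counts are
    stored on the returned table (``.detection``) for the downstream
    presence filter.
    """
    design = table.design.loc[table.runs]
    key = list(zip(design["group"], design["biological_replicate"]))
    animals = list(dict.fromkeys(key))  # preserve run order

    cols = {}
    new_design = {}
    for group, bio in animals:
        runs = [r for r, k in zip(table.runs, key) if k == (group, bio)]
        label = f"{group}_b{bio}"
        cols[label] = table.intensities[runs].mean(axis=1, skipna=True)
        new_design[label] = {
            "group": group,
            "biological_replicate": bio,
            "technical_replicate": 1,
        }
    averaged = pd.DataFrame(cols)
    averaged.index.name = table.intensities.index.name

    detected = table.detected()
    blocks = {}
    for group in dict.fromkeys(design["group"]):
        runs = table.runs_in_group(group)
        blocks[(group, "detected")] = detected[runs].sum(axis=1).astype(int)
        blocks[(group, "total")] = len(runs)
    detection = pd.DataFrame(blocks)
    detection.columns = pd.MultiIndex.from_tuples(detection.columns)

    out = AbundanceTable(
        averaged,
        pd.DataFrame(new_design).T,
        detection=detection,
    )
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order. NaNs pass through and
    do not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    if mask.sum():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if len(a) < 2 or len(b) < 2:
        return np.nan
    res = stats.ttest_ind(b, a, equal_var=equal_var)
    return float(res.pvalue)


def compute_group_stats(
    table: AbundanceTable,
    control_group: str,
    experimental_group: str,
    log_scale: bool = True,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-protein fold change, t-test p and BH-adjusted p for one contrast.

    ``table`` must be technical-replicate averaged (one column per
    animal); fold change is the ratio of the experimental to the control
    group mean over detected values. The t-test is Welch's by default
    (``equal_var=True`` gives Student's) and runs on log2 intensities
    unless ``log_scale=False``. Proteins detected in fewer than two
    animals in either group are not tested (p = NaN); proteins with zero
    detections in exactly one group receive a sentinel fold change
    instead of a ratio; proteins absent from both groups are dropped with
    a warning.

    Returns a DataFrame with the columns in :data:`RESULT_COLUMNS` (DEP
    columns are filled by :func:`call_deps`).
    """
    ctrl_runs = table.runs_in_group(control_group)
    exp_runs = table.runs_in_group(experimental_group)
    if not ctrl_runs or not exp_runs:
        raise ValueError("both groups must be present in the design")

    detection = table.detection
    rows = []
    dropped = 0
    for protein, vals in table.intensities.iterrows():
        c = vals[ctrl_runs].dropna().to_numpy(dtype=float)
        e = vals[exp_runs].dropna().to_numpy(dtype=float)
        if len(c) == 0 and len(e) == 0:
            dropped += 1
            continue

        if detection is not None:
            n_c = int(detection.loc[protein, (control_group, "detected")])
            n_e = int(detection.loc[protein, (experimental_group, "detected")])
            tot_c = int(detection.loc[protein, (control_group, "total")])
            tot_e = int(detection.loc[protein, (experimental_group, "total")])
        else:
            n_c, n_e = len(c), len(e)
            tot_c, tot_e = len(ctrl_runs), len(exp_runs)

        sentinel = None
        p = np.nan
        if len(c) == 0:
            fc = SENTINEL_ABSENT_CONTROL
            sentinel = SENTINEL_ABSENT_CONTROL
        elif len(e) == 0:
            fc = SENTINEL_ABSENT_EXPERIMENTAL
            sentinel = SENTINEL_ABSENT_EXPERIMENTAL
        else:
            fc = float(e.mean() / c.mean())
            if len(c) >= 2 and len(e) >= 2:
                if log_scale:
                    p = _welch_p(np.log2(c), np.log2(e), equal_var)
                else:
                    p = _welch_p(c, e, equal_var)

        # presence is counted in the overexpressing group's technical runs
        if sentinel == SENTINEL_ABSENT_CONTROL or (sentinel is None and fc > 1):
            presence, presence_total = n_e, tot_e
        else:
            presence, presence_total = n_c, tot_c

        rows.append(
            {
                "protein": protein,
                "mean_control": c.mean() if len(c) else np.nan,
                "mean_experimental": e.mean() if len(e) else np.nan,
                "fc": fc,
                "log2fc": np.log2(fc) if sentinel is None else np.nan,
                "pvalue": p,
                "presence_count": presence,
                "presence_total": presence_total,
                "sentinel": sentinel,
            }
        )
    if dropped:
        warnings.warn(f"dropped {dropped} proteins absent from both groups")

    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    result["padj"] = benjamini_hochberg(result["pvalue"])
    result["is_dep"] = False
    result["dep_stratum"] = None
    return result[RESULT_COLUMNS]


def call_deps(
    results: pd.DataFrame,
    fc_threshold: float = 1.2,
    adj_p_threshold: float = 0.1,
    presence_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag DEPs by fold change, adjusted p and replicate presence.

    A tested protein is a DEP iff ``|log2 FC| >= log2(fc_threshold)``,
    ``padj < adj_p_threshold`` and it was detected in at least
    ``presence_fraction`` of the overexpressing group's technical runs.
    Sentinel-coded proteins (no ratio, no p) pass the fold-change
    criterion by construction and are flagged solely on the presence
    filter, in a separate ``"sentinel"`` stratum.
    """
    out = results.copy()
    need = np.ceil(presence_fraction * out["presence_total"].to_numpy(dtype=float))
    present = out["presence_count"].to_numpy(dtype=float) >= need

    is_sentinel = out["sentinel"].notna()
    log2_cut = np.log2(fc_threshold)
    tested = (
        ~is_sentinel
        & (out["log2fc"].abs() >= log2_cut)
        & (out["padj"] < adj_p_threshold)
        & present
    )
    sentinel_dep = is_sentinel & present

    out["is_dep"] = tested | sentinel_dep
    out["dep_stratum"] = None
    out.loc[tested, "dep_stratum"] = "tested"
    out.loc[sentinel_dep, "dep_stratum"] = "sentinel"
    log.info(
        "DEP call: %d tested, %d sentinel, of %d proteins",
        int(tested.sum()),
        int(sentinel_dep.sum()),
        len(out),
    )
    return out


def ora_enrichment(
    selected: set[str],
    annotation_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation sets.

    For each set the p-value is the exact upper-tail probability of
    drawing at least the observed overlap when ``len(selected)`` proteins
    are sampled without replacement from ``universe``; BH adjustment is
    applied across sets. ``selected`` must be a subset of the universe
    and each annotation set is intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected proteins must be a subset of the universe")

    rows = []
    for set_id, members in annotation_sets.items():
        members = set(members) & universe
        overlap = len(members & selected)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(selected))
        )
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(members),
                "selected": len(selected),
                "overlap": overlap,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["padj"] = benjamini_hochberg(table["pvalue"])
        table = table.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return table
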