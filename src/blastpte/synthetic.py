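"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments (including the
seed) and returns the generated artifact together with a
:class:`PlantedTruth` record of what was planted, so downstream stages
can be scored for parameter recovery without any external data:

* grouped log-normal protein intensity tables with planted fold
  changes, a biological/technical replicate hierarchy and optional
  detection dropout (stand-in for deposited label-free LC–MS/MS runs);
* small stoichiometric models with a designated biomass-maintenance
  objective and closed-form LP optima, including an electron-transport
  -chain toy whose inner-membrane proton is pumped by two complexes;
* interaction graphs with planted hubs or preferential attachment,
  with edge confidences on the [0, 1] combined-score scale;
* EEG traces with planted high-amplitude bursts whose instantaneous
  frequency sweeps monotonically (the evolution criterion).

Defaults mirror the study design the pipeline targets: three groups
(sham, epileptic and non-epileptic injured), five animals per group, two
technical LC–MS/MS runs per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import chirp

from .flux import MetabolicModel, Metabolite, Reaction
from .tables import AbundanceTable

__all__ = [
    "PlantedTruth",
    "generate_abundance_table",
    "generate_toy_metabolic_model",
    "generate_ppin",
    "generate_eeg",
]

DEFAULT_GROUPS = ("sham", "pte_neg", "pte_pos")


@dataclass
class PlantedTruth:
    """Record of the structure planted by a generator."""

    dep_proteins: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    hub_nodes: list[str] = field(default_factory=list)
    eeg_events: list[tuple[float, float, float]] = field(default_factory=list)
    model_optimum: float | None = None


# ---------------------------------------------------------------------------
# proteomics tables
# ---------------------------------------------------------------------------


def generate_abundance_table(
    n_proteins: int,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    biological_replicates_per_group: int = 5,
    technical_replicates: int = 2,
    planted: list[tuple[int | str, tuple[str, str], float]] = (),
    noise_sd: float = 0.2,
    dropout_rate: float = 0.0,
    seed: int = 0,
    peptides_per_protein: int = 1,
) -> tuple[AbundanceTable, PlantedTruth]:
    """Grouped log-normal intensity table with planted fold changes.

    Intensities are multiplicative: ``log2 I = baseline + group effect +
    biological noise + technical noise``, with technical noise standard
    deviation fixed at ``noise_sd / 4`` (technical runs of one animal
    are far more alike than different animals). ``planted`` entries are
    ``(protein, (control_group, experimental_group), log2fc)``; the
    effect is added to the experimental group so the expected group-mean
    log2 ratio equals ``log2fc`` exactly. ``dropout_rate`` removes each
    detected value independently (missing = absent, not zero). With
    ``peptides_per_protein > 1`` the table is emitted at peptide level
    with a peptide→protein map, each protein's intensity split over its
    peptides by fixed random fractions.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    name_of = {i: p for i, p in enumerate(proteins)}

    effects = np.zeros((n_proteins, len(groups)))
    group_idx = {g: j for j, g in enumerate(groups)}
    truth = PlantedTruth()
    for prot, contrast, log2fc in planted:
        if isinstance(prot, int):
            if not 0 <= prot < n_proteins:
                raise ValueError(f"planted protein index {prot} out of range")
            prot = name_of[prot]
        elif prot not in proteins:
            raise ValueError(f"planted protein {prot!r} not in table")
        ctrl, exp = contrast
        if ctrl not in group_idx or exp not in group_idx:
            raise ValueError(f"unknown group in contrast {contrast}")
        if log2fc == 0 or not np.isfinite(log2fc):
            raise ValueError("planted log2 fold changes must be finite and nonzero")
        effects[proteins.index(prot), group_idx[exp]] += log2fc
        truth.dep_proteins.append((prot, (ctrl, exp), float(log2fc)))

    baseline = rng.normal(20.0, 1.5, size=n_proteins)

    runs, run_design = [], {}
    for g in groups:
        for b in range(1, biological_replicates_per_group + 1):
            for t in range(1, technical_replicates + 1):
                rid = f"{g}_b{b}_t{t}"
                runs.append(rid)
                run_design[rid] = {
                    "group": g,
                    "biological_replicate": b,
                    "technical_replicate": t,
                }

    n_bio = biological_replicates_per_group
    bio_noise = rng.normal(0.0, noise_sd, size=(n_proteins, len(groups), n_bio))
    tech_noise = rng.normal(
        0.0, noise_sd / 4.0, size=(n_proteins, len(groups), n_bio, technical_replicates)
    )
    log2_int = np.empty((n_proteins, len(runs)))
    for k, rid in enumerate(runs):
        d = run_design[rid]
        j = group_idx[d["group"]]
        b = d["biological_replicate"] - 1
        t = d["technical_replicate"] - 1
        log2_int[:, k] = (
            baseline + effects[:, j] + bio_noise[:, j, b] + tech_noise[:, j, b, t]
        )
    intensities = pd.DataFrame(np.exp2(log2_int), index=proteins, columns=runs)

    if dropout_rate > 0:
        drop = rng.random(intensities.shape) < dropout_rate
        intensities = intensities.mask(drop)

    design = pd.DataFrame(run_design).T
    mapping = None
    if peptides_per_protein > 1:
        fractions = rng.dirichlet(np.ones(peptides_per_protein), size=n_proteins)
        rows, mapping = {}, {}
        for i, prot in enumerate(proteins):
            for q in range(peptides_per_protein):
                pep = f"{prot}_pep{q + 1}"
                rows[pep] = intensities.loc[prot] * fractions[i, q]
                mapping[pep] = prot
        intensities = pd.DataFrame(rows).T

    return AbundanceTable(intensities, design, peptide_to_protein=mapping), truth


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------


def generate_toy_metabolic_model(
    kind: str,
    capacity: float = 10.0,
    seed: int = 0,
    branch_capacities: tuple[float, float] | None = None,
) -> tuple[MetabolicModel, PlantedTruth]:
    """Desk-scale stoichiometric models with known LP optima.

    ``linear_chain``: uptake → A → B → biomass, bottlenecked by the
    uptake capacity; optimum = capacity. ``branched``: two parallel
    sources feed the objective; optimum = sum of the branch capacities
    (``branch_capacities`` defaults to a 40/60 split of ``capacity``).
    ``etc_toy``: a miniature electron transport chain with BiGG-style
    compartment suffixes (``_c`` cytosol, ``_m`` mitochondrion, ``_i``
    inner membrane) in which the inner-membrane proton ``h_i`` is
    produced by the complex-III and complex-IV analogues and consumed by
    ATP synthase; optimum = 2 × capacity.
    """
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    big = 1000.0

    def rxn(rid, eq_stoich, lb, ub, gpr=""):
        return Reaction(rid, eq_stoich, lb, ub, gpr)

    if kind == "linear_chain":
        mets = {m: Metabolite(m, "c") for m in ("a_c", "b_c")}
        rxns = {
            "UPTAKE": rxn("UPTAKE", {"a_c": 1.0}, 0.0, capacity, gpr="P_UPTAKE"),
            "CONV": rxn("CONV", {"a_c": -1.0, "b_c": 1.0}, 0.0, big, gpr="P_CONV"),
            "BIOMASS_maint": rxn("BIOMASS_maint", {"b_c": -1.0}, 0.0, big),
        }
        model = MetabolicModel(mets, rxns, "BIOMASS_maint")
        return model, PlantedTruth(model_optimum=capacity)

    if kind == "branched":
        c1, c2 = branch_capacities or (0.4 * capacity, 0.6 * capacity)
        mets = {m: Metabolite(m, "c") for m in ("a_c", "b_c", "x_c")}
        rxns = {
            "SRC_A": rxn("SRC_A", {"a_c": 1.0}, 0.0, c1, gpr="P_SRC_A"),
            "SRC_B": rxn("SRC_B", {"b_c": 1.0}, 0.0, c2, gpr="P_SRC_B"),
            "PATH_A": rxn("PATH_A", {"a_c": -1.0, "x_c": 1.0}, 0.0, big, gpr="P_PATH_A"),
            "PATH_B": rxn("PATH_B", {"b_c": -1.0, "x_c": 1.0}, 0.0, big, gpr="P_PATH_B"),
            "BIOMASS_maint": rxn("BIOMASS_maint", {"x_c": -1.0}, 0.0, big),
        }
        model = MetabolicModel(mets, rxns, "BIOMASS_maint")
        return model, PlantedTruth(model_optimum=float(c1 + c2))

    if kind == "etc_toy":
        met_ids = [
            ("glc_c", "c"),
            ("nadh_m", "m"),
            ("q10h2_m", "m"),
            ("focytc_m", "m"),
            ("ficytc_m", "m"),
            ("o2_m", "m"),
            ("h_i", "i"),
            ("atp_c", "c"),
        ]
        mets = {mid: Metabolite(mid, comp) for mid, comp in met_ids}
        rxns = {
            "EX_glc": rxn("EX_glc", {"glc_c": 1.0}, 0.0, capacity),
            "DH": rxn("DH", {"glc_c": -1.0, "nadh_m": 1.0}, 0.0, big, gpr="Ndufv3"),
            "CI": rxn("CI", {"nadh_m": -1.0, "q10h2_m": 1.0}, 0.0, big, gpr="Ndufb4 and Ndufv3"),
            # complex III analogue: oxidizes QH2, reduces cytochrome c, pumps protons
            "CIII": rxn(
                "CIII",
                {"q10h2_m": -1.0, "ficytc_m": -2.0, "focytc_m": 2.0, "h_i": 4.0},
                0.0,
                big,
                gpr="Uqcrb",
            ),
            # complex IV analogue: re-oxidizes cytochrome c, pumps protons
            "CIV": rxn(
                "CIV",
                {"focytc_m": -2.0, "o2_m": -0.5, "ficytc_m": 2.0, "h_i": 2.0},
                0.0,
                big,
                gpr="Cox4",
            ),
            "EX_o2": rxn("EX_o2", {"o2_m": 1.0}, 0.0, big),
            "ATPS": rxn("ATPS", {"h_i": -3.0, "atp_c": 1.0}, 0.0, big, gpr="Atp5pf"),
            "BIOMASS_maint": rxn("BIOMASS_maint", {"atp_c": -1.0}, 0.0, big),
        }
        model = MetabolicModel(mets, rxns, "BIOMASS_maint")
        # per unit uptake: CIII pumps 4 and CIV pumps 2 protons; ATPS uses 3
        # protons per ATP, so the optimum is 6/3 = 2 × capacity
        return model, PlantedTruth(model_optimum=2.0 * capacity)

    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------


def generate_ppin(
    n_nodes: int,
    mode: str = "planted_hub",
    seed: int = 0,
    n_hubs: int = 1,
    confidence_threshold: float = 0.7,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Edge list with confidences in [0, 1] and planted structure.

    ``planted_hub``: non-hub nodes sit on a high-confidence ring (degree
    2) with sparse low-confidence chords; each hub attaches to half of
    the non-hubs at high confidence, guaranteeing hub degree at least 3×
    the median non-hub degree after thresholding. ``preferential_
    attachment``: a Barabási–Albert graph with uniform confidences.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    names = [f"G{i:03d}" for i in range(n_nodes)]
    rows: list[tuple[str, str, float]] = []

    if mode == "planted_hub":
        if not 1 <= n_hubs < n_nodes - 2:
            raise ValueError("n_hubs out of range")
        hubs = names[:n_hubs]
        others = names[n_hubs:]
        m = len(others)
        for i in range(m):  # high-confidence ring among non-hubs
            a, b = others[i], others[(i + 1) % m]
            rows.append((a, b, float(rng.uniform(0.75, 0.95))))
        n_chords = max(1, m // 4)  # low-confidence chords, removed by the filter
        for _ in range(n_chords):
            a, b = rng.choice(m, size=2, replace=False)
            rows.append((others[a], others[b], float(rng.uniform(0.05, 0.65))))
        attach = max(9, m // 2)
        for h in hubs:
            targets = rng.choice(m, size=min(attach, m), replace=False)
            for t in targets:
                rows.append((h, others[t], float(rng.uniform(0.75, 0.98))))
        truth = PlantedTruth(hub_nodes=hubs)
    elif mode == "preferential_attachment":
        import networkx as nx

        G = nx.barabasi_albert_graph(n_nodes, 2, seed=int(rng.integers(2**31)))
        for a, b in G.edges():
            rows.append((names[a], names[b], float(rng.uniform(0.0, 1.0))))
        truth = PlantedTruth()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    return edges, truth


# ---------------------------------------------------------------------------
# EEG traces
# ---------------------------------------------------------------------------


def generate_eeg(
    duration_s: float,
    fs: float = 256.0,
    events: list[tuple[float, float, float, tuple[float, float]]] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    taper_fraction: float = 0.15,
):
    """Stationary Gaussian background with planted oscillatory bursts.

    Each event ``(start_s, duration_s, amplitude_ratio, (f0, f1))`` is a
    linear chirp from ``f0`` to ``f1`` Hz (monotone instantaneous
    frequency) whose envelope RMS is ``amplitude_ratio ×`` the background
    RMS (``noise_sd``), tapered at the edges by a Tukey window.
    Overlapping events are rejected.
    """
    from .eeg import EEGTrace  # local import to avoid a cycle at module load

    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    spans = sorted((float(s), float(s) + float(d)) for s, d, *_ in events)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("events overlap")
    for s, d, *_ in events:
        if s < 0 or s + d > duration_s:
            raise ValueError("event outside the trace")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = rng.normal(0.0, noise_sd, size=n)

    truth = PlantedTruth()
    for start, dur, ratio, sweep in events:
        f0, f1 = sweep
        i0 = int(round(start * fs))
        i1 = min(int(round((start + dur) * fs)), n)
        t = np.arange(i1 - i0) / fs
        burst = chirp(t, f0=f0, f1=f1, t1=dur, method="linear")
        from scipy.signal.windows import tukey

        env = tukey(i1 - i0, alpha=2 * taper_fraction)
        # sine RMS is amplitude/sqrt(2); scale so the burst RMS hits the ratio
        x[i0:i1] += ratio * noise_sd * np.sqrt(2.0) * env * burst
        truth.eeg_events.append((float(start), float(dur), float(ratio)))

    return EEGTrace(x, fs), truth
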