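"""Recovery experiments on synthetic data.

Each experiment generates seeded synthetic inputs with
:mod:`blastpte.synthetic`, runs the corresponding analysis stage
end-to-end, and scores how well the planted structure is recovered.
They quantify what the pipeline can and cannot detect under the
simulated study design (three groups, five animals per group, two
technical runs; planted-hub networks; chirped high-amplitude EEG
bursts) — not on real data, whose noise structure is richer.
"""

from __future__ import annotations

import numpy as np

from . import eeg as eeg_mod
from . import network as net_mod
from . import proteomics as prot_mod
from . import synthetic

__all__ = [
    "dep_recovery",
    "hub_recovery",
    "eeg_screening",
    "screened_incidence",
]

CONTRAST = ("pte_neg", "pte_pos")


def dep_recovery(
    n_simulations: int = 100,
    n_proteins: int = 200,
    n_planted: int = 20,
    log2fc: float = 1.0,
    noise_sd: float = 0.2,
    biological_replicates: int = 5,
    technical_replicates: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity and false-positive rate of the DEP caller.

    Each simulation plants ``n_planted`` proteins at ±``log2fc`` between
    the epileptic and non-epileptic injured groups, runs normalization,
    technical averaging, group statistics and DEP calling at the default
    thresholds, and scores recovery of the planted set.
    """
    rng = np.random.default_rng(seed)
    planted = [
        (i, CONTRAST, log2fc if i % 2 == 0 else -log2fc) for i in range(n_planted)
    ]
    planted_ids = {f"P{i:04d}" for i in range(n_planted)}
    sens, fpr = [], []
    for _ in range(n_simulations):
        table, _ = synthetic.generate_abundance_table(
            n_proteins,
            biological_replicates_per_group=biological_replicates,
            technical_replicates=technical_replicates,
            planted=planted,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        table = prot_mod.normalize_peptide_intensities(table)
        averaged = prot_mod.average_technical_replicates(table)
        stats = prot_mod.compute_group_stats(averaged, *CONTRAST)
        called = prot_mod.call_deps(stats)
        dep_ids = set(called.loc[called["is_dep"], "protein"])
        sens.append(len(dep_ids & planted_ids) / n_planted)
        fpr.append(len(dep_ids - planted_ids) / (n_proteins - n_planted))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": float(np.mean(fpr)),
        "n_simulations": n_simulations,
    }


def hub_recovery(
    n_networks: int = 100,
    n_nodes: int = 40,
    n_hubs: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of planted-hub networks whose hubs head the weighted ranking."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_networks):
        edges, truth = synthetic.generate_ppin(
            n_nodes, mode="planted_hub", seed=int(rng.integers(2**31)), n_hubs=n_hubs
        )
        G = net_mod.build_network(edges)
        ranking = net_mod.weighted_rank(net_mod.compute_centralities(G))
        if set(ranking.order[:n_hubs]) == set(truth.hub_nodes):
            hits += 1
    return {"recovery_rate": hits / n_networks, "n_networks": n_networks}


def _jaccard(a0: float, a1: float, b0: float, b1: float) -> float:
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    return inter / union if union > 0 else 0.0


def eeg_screening(
    n_traces: int = 100,
    duration_s: float = 300.0,
    fs: float = 200.0,
    seed: int = 0,
    jaccard_min: float = 0.8,
) -> dict[str, float]:
    """Event-level sensitivity and false-event rate of the seizure screen.

    Each trace carries two planted bursts (amplitude ratio 4–6, duration
    8–12 s, monotone frequency sweep). A planted event counts as
    recovered if a detected event overlaps it with Jaccard ≥
    ``jaccard_min``; detections overlapping no planted event are false
    events, reported per 10 minutes of screened signal.
    """
    rng = np.random.default_rng(seed)
    n_planted = n_detected_true = n_false = 0
    for _ in range(n_traces):
        d1, d2 = rng.uniform(8, 12, size=2)
        events = [
            (float(rng.uniform(20, 100)), float(d1), float(rng.uniform(4, 6)),
             (float(rng.uniform(3, 6)), float(rng.uniform(8, 14)))),
            (float(rng.uniform(150, 250)), float(d2), float(rng.uniform(4, 6)),
             (float(rng.uniform(3, 6)), float(rng.uniform(8, 14)))),
        ]
        trace, truth = synthetic.generate_eeg(
            duration_s, fs=fs, events=events, seed=int(rng.integers(2**31))
        )
        detected = eeg_mod.detect_events(trace)
        n_planted += len(truth.eeg_events)
        matched = set()
        for start, dur, _ in truth.eeg_events:
            for k, ev in enumerate(detected):
                if _jaccard(ev.start, ev.end, start, start + dur) >= jaccard_min:
                    n_detected_true += 1
                    matched.add(k)
                    break
        n_false += sum(
            1
            for k, ev in enumerate(detected)
            if k not in matched
            and all(
                _jaccard(ev.start, ev.end, s, s + d) == 0.0
                for s, d, _ in truth.eeg_events
            )
        )
    minutes = n_traces * duration_s / 60.0
    return {
        "sensitivity": n_detected_true / n_planted,
        "false_events_per_10min": n_false / (minutes / 10.0),
        "n_traces": n_traces,
    }


def screened_incidence(
    n_animals: int = 53,
    n_epileptic: int = 11,
    duration_s: float = 60.0,
    fs: float = 128.0,
    seed: int = 0,
) -> int:
    """Cohort seizure incidence (rounded integer percent) from screening.

    Emulates chronic video-EEG monitoring of an injured cohort in which
    ``n_epileptic`` animals develop electrographic seizures: epileptic
    animals receive one planted qualifying burst per trace, the rest are
    background only; every trace is screened with the default criteria
    and incidence is the fraction of animals with at least one accepted
    event.
    """
    rng = np.random.default_rng(seed)
    cohort: dict[str, list] = {}
    for i in range(n_animals):
        events = []
        if i < n_epileptic:
            start = float(rng.uniform(15, duration_s - 15))
            events = [(start, float(rng.uniform(8, 12)), float(rng.uniform(4, 6)),
                       (float(rng.uniform(3, 6)), float(rng.uniform(8, 14))))]
        trace, _ = synthetic.generate_eeg(
            duration_s, fs=fs, events=events, seed=int(rng.integers(2**31))
        )
        cohort[f"animal{i:02d}"] = eeg_mod.detect_events(trace)
    return eeg_mod.seizure_incidence(cohort)
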