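"""Differential-protein pipeline: oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blastpte.proteomics import (
    SENTINEL_ABSENT_CONTROL,
    SENTINEL_ABSENT_EXPERIMENTAL,
    average_technical_replicates,
    benjamini_hochberg,
    call_deps,
    compute_group_stats,
    normalize_peptide_intensities,
    ora_enrichment,
    rollup_peptides_to_proteins,
)
from blastpte.tables import AbundanceTable, DataError


def _design(runs):
    rows = {
        r: {"group": r.split("_")[0], "biological_replicate": int(r.split("_b")[1][0]),
            "technical_replicate": int(r.split("_t")[1])}
        for r in runs
    }
    return pd.DataFrame(rows).T


class TestNormalization:
    def test_run_totals_equalized_to_mean(self):
        runs = ["a_b1_t1", "a_b1_t2"]
        ints = pd.DataFrame({"a_b1_t1": [40.0, 60.0], "a_b1_t2": [150.0, 50.0]},
                            index=["P1", "P2"])
        out = normalize_peptide_intensities(AbundanceTable(ints, _design(runs)))
        totals = out.intensities.sum()
        # totals 100 and 200 scale by 1.5 and 0.75 to a common 150
        assert np.allclose(out.intensities["a_b1_t1"], [60.0, 90.0])
        assert np.allclose(out.intensities["a_b1_t2"], [112.5, 37.5])
        assert np.allclose(totals, 150.0, rtol=1e-9)

    def test_equal_totals_and_single_run_unchanged(self, small_table):
        scaled = small_table.intensities / small_table.intensities.sum()
        table = AbundanceTable(scaled, small_table.design)
        out = normalize_peptide_intensities(table)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)
        one = AbundanceTable(
            small_table.intensities.iloc[:, [0]], small_table.design
        )
        pd.testing.assert_frame_equal(
            normalize_peptide_intensities(one).intensities, one.intensities
        )

    def test_relative_intensities_preserved(self, small_table):
        out = normalize_peptide_intensities(small_table)
        for run in small_table.runs:
            ratio = out.intensities[run] / small_table.intensities[run]
            assert np.allclose(ratio, ratio.iloc[0])

    def test_zero_total_run_is_data_error(self):
        runs = ["a_b1_t1", "a_b1_t2"]
        ints = pd.DataFrame({"a_b1_t1": [1.0], "a_b1_t2": [np.nan]}, index=["P1"])
        with pytest.raises(DataError):
            normalize_peptide_intensities(AbundanceTable(ints, _design(runs)))


class TestRollup:
    def test_sum_and_absence_propagation(self):
        runs = ["a_b1_t1", "a_b1_t2"]
        ints = pd.DataFrame(
            {"a_b1_t1": [3.0, 7.0, 2.0], "a_b1_t2": [np.nan, np.nan, 5.0]},
            index=["pep1", "pep2", "pep3"],
        )
        mapping = {"pep1": "PA", "pep2": "PA", "pep3": "PB"}
        out = rollup_peptides_to_proteins(AbundanceTable(ints, _design(runs)), mapping)
        assert out.intensities.loc["PA", "a_b1_t1"] == 10.0
        assert np.isnan(out.intensities.loc["PA", "a_b1_t2"])  # all peptides absent
        assert out.intensities.loc["PB", "a_b1_t2"] == 5.0

    def test_matches_bruteforce_groupby_oracle(self, small_table):
        rng = np.random.default_rng(7)
        ints = small_table.intensities.rename(index=lambda p: f"{p}_pep")
        ints = ints.mask(rng.random(ints.shape) < 0.3)
        mapping = {pep: f"PROT{int(i) % 3}" for i, pep in enumerate(ints.index)}
        table = AbundanceTable(ints, small_table.design)
        out = rollup_peptides_to_proteins(table, mapping)
        for prot in out.intensities.index:
            peps = [p for p, q in mapping.items() if q == prot]
            for run in table.runs:
                vals = [ints.loc[p, run] for p in peps if not np.isnan(ints.loc[p, run])]
                expected = sum(vals) if vals else np.nan
                got = out.intensities.loc[prot, run]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)

    def test_unmapped_peptide_raises_or_drops(self, small_table):
        mapping = {p: "PX" for p in small_table.intensities.index[:-1]}
        with pytest.raises(DataError):
            rollup_peptides_to_proteins(small_table, mapping)
        with pytest.warns(UserWarning):
            out = rollup_peptides_to_proteins(small_table, mapping, on_unmapped="drop")
        assert list(out.intensities.index) == ["PX"]


class TestTechnicalAveraging:
    def test_mean_and_single_detection(self):
        runs = ["a_b1_t1", "a_b1_t2"]
        ints = pd.DataFrame({"a_b1_t1": [4.0, 8.0], "a_b1_t2": [6.0, np.nan]},
                            index=["P1", "P2"])
        out = average_technical_replicates(AbundanceTable(ints, _design(runs)))
        assert out.intensities.loc["P1", "a_b1"] == 5.0
        assert out.intensities.loc["P2", "a_b1"] == 8.0
        assert out.detection.loc["P2", ("a", "detected")] == 1
        assert out.detection.loc["P2", ("a", "total")] == 2

    def test_matches_per_animal_mean_oracle(self, small_table):
        rng = np.random.default_rng(3)
        ints = small_table.intensities.mask(rng.random(small_table.intensities.shape) < 0.25)
        table = AbundanceTable(ints, small_table.design)
        out = average_technical_replicates(table)
        for prot in ints.index:
            for col in out.intensities.columns:
                g, b = col.rsplit("_b", 1)
                runs = [
                    r for r in table.runs
                    if table.design.loc[r, "group"] == g
                    and str(table.design.loc[r, "biological_replicate"]) == b
                ]
                vals = [ints.loc[prot, r] for r in runs if not np.isnan(ints.loc[prot, r])]
                expected = np.mean(vals) if vals else np.nan
                got = out.intensities.loc[prot, col]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.04, 0.01, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert np.allclose(benjamini_hochberg(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_permutation_invariant(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = benjamini_hochberg(np.asarray(p)[perm])
        assert np.allclose(adj_perm, adj[perm])


def _averaged(ints: dict[str, list[float]]) -> AbundanceTable:
    """Helper: build an averaged 3+3-animal table with detection counts."""
    runs = [f"{g}_b{b}_t{t}" for g in ("ctrl", "exp") for b in (1, 2, 3) for t in (1, 2)]
    data = {}
    for r in runs:
        g, b = r.split("_")[0], int(r.split("_b")[1][0])
        data[r] = [row[(0 if g == "ctrl" else 3) + b - 1] for row in ints.values()]
    table = AbundanceTable(
        pd.DataFrame(data, index=list(ints.keys())), _design(runs)
    )
    return average_technical_replicates(table)


class TestGroupStats:
    def test_identical_groups_give_unit_fc(self):
        avg = _averaged({"P1": [10.0, 12.0, 11.0, 10.0, 12.0, 11.0]})
        res = compute_group_stats(avg, "ctrl", "exp")
        assert res.loc[0, "fc"] == pytest.approx(1.0)
        assert res.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_welch_matches_textbook_formula(self):
        c, e = [10.0, 12.0, 11.0], [20.0, 22.0, 21.0]
        avg = _averaged({"P1": c + e})
        res = compute_group_stats(avg, "ctrl", "exp", log_scale=False)
        assert res.loc[0, "fc"] == pytest.approx(np.mean(e) / np.mean(c))
        # independent Welch computation from the textbook formulas
        va, vb = np.var(c, ddof=1), np.var(e, ddof=1)
        na = nb = 3
        t = (np.mean(e) - np.mean(c)) / math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df)
        assert res.loc[0, "pvalue"] == pytest.approx(p, rel=1e-10)

    def test_sentinels_for_group_absence(self):
        runs = [f"{g}_b{b}_t1" for g in ("ctrl", "exp") for b in (1, 2)]
        ints = pd.DataFrame(
            {
                runs[0]: [np.nan, 5.0],
                runs[1]: [np.nan, 6.0],
                runs[2]: [9.0, np.nan],
                runs[3]: [8.0, np.nan],
            },
            index=["only_exp", "only_ctrl"],
        )
        avg = average_technical_replicates(AbundanceTable(ints, _design(runs)))
        res = compute_group_stats(avg, "ctrl", "exp").set_index("protein")
        assert res.loc["only_exp", "fc"] == SENTINEL_ABSENT_CONTROL
        assert res.loc["only_ctrl", "fc"] == SENTINEL_ABSENT_EXPERIMENTAL
        assert np.isnan(res.loc["only_exp", "pvalue"])
        # sentinel exclusivity: a protein never carries both codes
        assert res["sentinel"].notna().sum() == 2
        assert set(res["sentinel"].dropna()) == {100.0, 0.1}

    def test_absent_everywhere_dropped_with_warning(self):
        runs = [f"{g}_b{b}_t1" for g in ("ctrl", "exp") for b in (1, 2)]
        ints = pd.DataFrame(
            np.array([[np.nan] * 4, [2.0, 3.0, 2.5, 3.5]]), index=["gone", "ok"],
            columns=runs,
        )
        avg = average_technical_replicates(AbundanceTable(ints, _design(runs)))
        with pytest.warns(UserWarning, match="absent from both"):
            res = compute_group_stats(avg, "ctrl", "exp")
        assert list(res["protein"]) == ["ok"]


class TestDepCalling:
    def _results(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["protein", "fc", "padj", "presence_count", "presence_total"],
        )
        df["log2fc"] = np.log2(df["fc"])
        df["sentinel"] = None
        df["pvalue"] = df["padj"]
        df["mean_control"] = 1.0
        df["mean_experimental"] = df["fc"]
        df["is_dep"] = False
        df["dep_stratum"] = None
        return df

    def test_unit_fc_never_a_dep(self):
        res = call_deps(self._results([["P1", 1.0, 1e-9, 10, 10]]))
        assert not res["is_dep"].any()

    def test_threshold_rule(self):
        res = call_deps(
            self._results(
                [
                    ["pass", 1.25, 0.05, 6, 10],
                    ["low_fc", 1.1, 0.001, 10, 10],
                    ["high_p", 1.5, 0.2, 10, 10],
                    ["absent", 2.0, 0.01, 4, 10],
                    ["down", 1 / 1.3, 0.05, 6, 10],
                ]
            )
        )
        assert list(res.loc[res["is_dep"], "protein"]) == ["pass", "down"]

    def test_exhaustive_filter_conjunction_on_toy(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(20):
            fc = float(rng.uniform(0.5, 2.5))
            padj = float(rng.uniform(0, 0.3))
            pres = int(rng.integers(0, 11))
            rows.append([f"P{i:02d}", fc, padj, pres, 10])
        res = call_deps(self._results(rows))
        expected = {
            r[0]
            for r in rows
            if abs(np.log2(r[1])) >= np.log2(1.2) and r[2] < 0.1 and r[3] >= 5
        }
        assert set(res.loc[res["is_dep"], "protein"]) == expected

    def test_sentinel_stratum_gated_by_presence(self):
        df = self._results([["s1", 100.0, np.nan, 6, 10], ["s2", 0.1, np.nan, 3, 10]])
        df.loc[df["protein"] == "s1", "sentinel"] = 100.0
        df.loc[df["protein"] == "s2", "sentinel"] = 0.1
        df["log2fc"] = np.nan
        res = call_deps(df).set_index("protein")
        assert res.loc["s1", "is_dep"] and res.loc["s1", "dep_stratum"] == "sentinel"
        assert not res.loc["s2", "is_dep"]


class TestOra:
    def test_exhaustive_selection_gives_unit_p(self):
        universe = {f"P{i}" for i in range(12)}
        sets = {"s1": set(list(universe)[:4]), "s2": set(list(universe)[2:9])}
        table = ora_enrichment(universe, sets, universe)
        assert np.allclose(table["pvalue"], 1.0)

    def test_exact_combinatorial_example(self):
        universe = {f"P{i}" for i in range(20)}
        chosen = set(sorted(universe)[:5])
        table = ora_enrichment(chosen, {"hit": chosen}, universe)
        assert table.loc[0, "pvalue"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_bruteforce_tail_sum(self):
        rng = np.random.default_rng(5)
        universe = {f"P{i}" for i in range(30)}
        selected = set(rng.choice(sorted(universe), size=8, replace=False))
        annot = set(rng.choice(sorted(universe), size=12, replace=False))
        table = ora_enrichment(selected, {"a": annot}, universe)
        k_obs = len(annot & selected)
        M, K, N = 30, len(annot), len(selected)
        tail = sum(
            math.comb(K, k) * math.comb(M - K, N - k) / math.comb(M, N)
            for k in range(k_obs, min(K, N) + 1)
        )
        assert table.loc[0, "overlap"] == k_obs
        assert table.loc[0, "pvalue"] == pytest.approx(tail, rel=1e-10)

    def test_empty_universe_and_bad_subset(self):
        with pytest.raises(ValueError):
            ora_enrichment(set(), {}, set())
        with pytest.raises(ValueError):
            ora_enrichment({"x"}, {}, {"y"})
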