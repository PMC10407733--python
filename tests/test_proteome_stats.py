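"""Differential abundance (s0 statistic, permutation FDR), iBAQ ranks, and
set algebra over dysregulated proteins."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otskit import (
    DEConfig,
    DifferentialAbundanceModel,
    QuantTable,
    differential_abundance,
    overlap_sets,
    rank_abundance,
    remove_common_core,
)
from otskit import synthetic_data as sd


def exhaustive_permutation_oracle(X, n_a):
    """Brute force: per protein, |t| of every distinct 3v3 label assignment
    and the share at least as extreme as the observed labelling."""
    n = X.shape[1]
    out = []
    for row in X:
        t_obs = stats.ttest_ind(row[n_a:], row[:n_a], equal_var=True).statistic
        hits = total = 0
        for a_cols in itertools.combinations(range(n), n_a):
            b_cols = [c for c in range(n) if c not in a_cols]
            t_p = stats.ttest_ind(row[b_cols], row[list(a_cols)],
                                  equal_var=True).statistic
            total += 1
            if abs(t_p) >= abs(t_obs) - 1e-12:
                hits += 1
        out.append(hits / total)
    return np.array(out)


class TestDifferentialAbundance:
    def test_exhaustive_oracle_equality_on_toy_table(self, toy_quant_table):
        """With s0=0 the modified statistic is the classical t statistic and the
        permutation p equals exhaustive enumeration."""
        cfg = DEConfig(s0=0.0, n_permutations=25)
        res = DifferentialAbundanceModel(toy_quant_table, "A", "B", cfg).fit(seed=0)
        assert res.exhaustive and res.n_assignments == 20

        X = np.log2(toy_quant_table.lfq_matrix(
            toy_quant_table.samples_for("A") + toy_quant_table.samples_for("B")
        ))
        # d == t when s0 = 0
        np.testing.assert_allclose(res.frame["d_stat"], res.frame["t_stat"],
                                   rtol=1e-12)
        # parametric p agrees with scipy's equal-variance t-test
        p_scipy = stats.ttest_ind(X[:, 3:], X[:, :3], axis=1, equal_var=True).pvalue
        np.testing.assert_allclose(res.frame["p_value"], p_scipy, rtol=1e-9)
        # permutation p agrees with brute-force enumeration
        np.testing.assert_allclose(
            res.frame["perm_p"], exhaustive_permutation_oracle(X, 3), rtol=1e-12
        )

    def test_spike_in_recovery(self):
        table, truth = sd.simulate_proteome(
            2000, 3, frac_dys=0.05, log2_effect=2.0, rep_sd_log2=0.25, seed=10
        )
        res = differential_abundance(table, "BG", "OTS", seed=10)
        labels = truth.params["labels"]
        truth_pos = {p for p, l in labels.items() if l != "null"}
        sig = res.significant_proteins()
        recall = len(sig & truth_pos) / len(truth_pos)
        efdr = len(sig - truth_pos) / max(len(sig), 1)
        assert recall >= 0.8
        assert efdr <= 0.15
        # direction agrees with the spiked sign
        up = res.significant_proteins("up")
        assert up <= {p for p, l in labels.items() if l == "up"} | (sig - truth_pos)

    def test_null_simulation_is_fdr_controlled(self):
        table, _ = sd.simulate_proteome(2000, 3, frac_dys=0.0, seed=21)
        res = differential_abundance(table, "BG", "OTS", seed=21)
        assert (res.frame["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        assert len(res.significant_proteins()) <= 10

    def test_min_valid_exclusion_reported(self):
        table, _ = sd.simulate_proteome(300, 3, missing_rate=0.4, seed=2)
        res = differential_abundance(table, "BG", "OTS", seed=2)
        assert len(res.frame) + len(res.excluded) == 300
        assert (res.frame[["n_valid_a", "n_valid_b"]] >= 2).all().all()

    def test_unknown_condition_raises(self, toy_quant_table):
        with pytest.raises(ValueError):
            DifferentialAbundanceModel(toy_quant_table, "A", "Z")


class TestRankAbundance:
    def _table(self, ibaq_by_rep):
        n = len(next(iter(ibaq_by_rep.values())))
        data = {"protein_id": [f"P{i}" for i in range(n)]}
        design = {}
        for rep, vals in ibaq_by_rep.items():
            data[f"LFQ.{rep}"] = np.full(n, 100.0)
            data[f"iBAQ.{rep}"] = np.asarray(vals, dtype=float)
            design[rep] = "C"
        return QuantTable(frame=pd.DataFrame(data), design=design)

    def test_top_protein_rank_one(self):
        t = self._table({"r1": [9, 5, 1], "r2": [9, 5, 1], "r3": [9, 5, 1]})
        r = rank_abundance(t, "C", "P0")
        assert r.mean == 1.0 and r.sd == 0.0

    def test_reported_mean_and_sd_convention(self):
        """Replicate ranks {99, 101, 103} report as mean 101, SD 2."""
        vals = {}
        for rep, target in (("r1", 99), ("r2", 101), ("r3", 103)):
            v = np.arange(200, 0, -1.0)  # protein i has rank i+1
            vals[rep] = np.concatenate([[v[target - 1] + 0.5], v])[:200]
        # construct directly: protein P0 gets rank `target` per replicate
        n = 200
        data = {"protein_id": [f"P{i}" for i in range(n)]}
        design = {}
        for rep, target in (("r1", 99), ("r2", 101), ("r3", 103)):
            col = np.arange(n, 0, -1.0) * 10  # P0 would rank 1
            col[0] = col[target - 1] - 5  # push P0 between ranks target-1, target
            data[f"LFQ.{rep}"] = np.full(n, 100.0)
            data[f"iBAQ.{rep}"] = col
            design[rep] = "C"
        t = QuantTable(frame=pd.DataFrame(data), design=design)
        r = rank_abundance(t, "C", "P0")
        assert r.ranks == [99, 101, 103]
        assert r.mean == 101.0 and r.sd == 2.0
        assert str(r) == "101 ± 2"

    def test_ties_share_minimal_rank(self):
        t = self._table({"r1": [7, 7, 1], "r2": [7, 7, 1], "r3": [7, 7, 1]})
        assert rank_abundance(t, "C", "P0").ranks == [1, 1, 1]
        assert rank_abundance(t, "C", "P1").ranks == [1, 1, 1]
        assert rank_abundance(t, "C", "P2").ranks == [3, 3, 3]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(10, 2, size=50)
        t1 = self._table({"r1": base})
        t2 = self._table({"r1": np.log1p(base) ** 3})
        for p in ("P0", "P7", "P33"):
            assert rank_abundance(t1, "C", p).ranks == rank_abundance(t2, "C", p).ranks

    def test_absent_protein_raises(self):
        t = self._table({"r1": [1, 2, 3]})
        with pytest.raises(ValueError):
            rank_abundance(t, "C", "P99")


class TestSetAlgebra:
    def test_overlap_enumeration(self):
        table = overlap_sets({"A": {"p1", "p2", "p3"}, "B": {"p2", "p3", "p4"}})
        assert table.shared_all == {"p2", "p3"}
        assert table.unique("A") == {"p1"}
        assert table.unique("B") == {"p4"}

    def test_identical_and_disjoint_sets(self):
        same = overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert same.shared_all == {"x", "y"} and not same.unique("A")
        disj = overlap_sets({"A": {"a", "b", "c"}, "B": {"d", "e", "f", "g", "h"}})
        assert len(disj.unique("A")) == 3 and len(disj.unique("B")) == 5
        assert not disj.shared_all

    def test_overlap_conservation(self):
        rng = np.random.default_rng(0)
        universe = [f"p{i}" for i in range(100)]
        a = set(rng.choice(universe, 40, replace=False))
        b = set(rng.choice(universe, 55, replace=False))
        t = overlap_sets({"A": a, "B": b})
        assert len(t.unique("A")) + len(t.unique("B")) + len(t.shared_all) == len(a | b)

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets({"A": {"p1"}})

    def test_remove_common_core(self, toy_quant_table):
        res = differential_abundance(
            toy_quant_table, "A", "B", DEConfig(n_permutations=25), seed=0
        )
        core = set(res.frame["protein_id"][:2])
        filtered = remove_common_core(res, core)
        assert set(filtered.frame["protein_id"]) == set(res.frame["protein_id"]) - core
        assert filtered.cutoff_d == res.cutoff_d

    def test_remove_core_superset_empties(self, toy_quant_table):
        res = differential_abundance(
            toy_quant_table, "A", "B", DEConfig(n_permutations=25), seed=0
        )
        assert len(remove_common_core(res, set(res.frame["protein_id"])).frame) == 0


def test_reader_drops_flagged_rows(tmp_path):
    from otskit.proteome_stats import read_quant_table

    df = pd.DataFrame(
        {
            "protein_id": ["P1", "CON_P2", "REV_P3"],
            "flags": ["", "+", "+"],
            "LFQ.s1": [10.0, 20.0, 30.0],
            "iBAQ.s1": [1.0, 2.0, 3.0],
            "LFQ.s2": [11.0, 21.0, 31.0],
            "iBAQ.s2": [1.1, 2.1, 3.1],
        }
    )
    df.to_csv(tmp_path / "quant.tsv", sep="\t", index=False)
    table = read_quant_table(tmp_path / "quant.tsv", {"s1": "A", "s2": "B"})
    assert list(table.protein_ids) == ["P1"]
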