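"""Response classification, hypergeometric enrichment, BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secscreen.response import (
    bh_adjust,
    classify_response,
    classify_table,
    condition_means,
    enrich_gene_sets,
    hypergeometric_enrichment,
    hypergeometric_tail,
    log2_response,
    summarize_classes,
)


def _table(rng, n_genes=20, n_reps=3):
    cols = {}
    for geno in ("CTL", "KO"):
        for cond in ("fasting", "refeeding"):
            for rep in range(1, n_reps + 1):
                cols[f"{geno}_{cond}_rep{rep}"] = rng.gamma(2, 10, n_genes)
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])


class TestConditionMeans:
    def test_matches_group_by_oracle(self, rng):
        table = _table(rng)
        means = condition_means(table)
        for geno in ("CTL", "KO"):
            for cond in ("fasting", "refeeding"):
                cols = [c for c in table.columns
                        if c.startswith(f"{geno}_{cond}_")]
                expected = table[cols].to_numpy().mean(axis=1)
                assert np.allclose(means[(geno, cond)], expected)

    def test_missing_cell_raises(self, rng):
        table = _table(rng)
        table = table.drop(columns=[c for c in table.columns
                                    if c.startswith("KO_fasting")])
        with pytest.raises(ValueError, match="KO/fasting"):
            condition_means(table)

    def test_malformed_column_raises(self, rng):
        table = _table(rng).rename(columns={"CTL_fasting_rep1": "weird"})
        with pytest.raises(ValueError, match="weird"):
            condition_means(table)


class TestLog2Response:
    def test_no_change_is_zero(self, rng):
        table = _table(rng)
        means = condition_means(table)
        for geno in ("CTL", "KO"):
            means[(geno, "refeeding")] = means[(geno, "fasting")]
        assert np.allclose(log2_response(means), 0.0)

    def test_pseudocount_guards_zero(self):
        means = pd.DataFrame(
            {("CTL", "fasting"): [0.0], ("CTL", "refeeding"): [3.0],
             ("KO", "fasting"): [0.0], ("KO", "refeeding"): [3.0]})
        out = log2_response(means, pseudocount=1.0)
        assert out["CTL"].iloc[0] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        means = condition_means(_table(rng))
        out = log2_response(means, pseudocount=1.0)
        for gene in means.index:
            expected = np.log2(
                (means.loc[gene, ("CTL", "refeeding")] + 1)
                / (means.loc[gene, ("CTL", "fasting")] + 1))
            assert out.loc[gene, "CTL"] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_pseudocount_rejected(self, rng):
        with pytest.raises(ValueError):
            log2_response(condition_means(_table(rng)), pseudocount=0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "ctl, ko, status, reversed_flag",
        [
            (2.0, 2.0, "concordant", False),
            (2.0, 0.0, "blunted", False),
            (-2.0, -4.0, "enhanced", False),
            (0.58, 0.58, "not_responsive", False),  # 1.5-fold: below gate
            (2.0, -1.5, "blunted", True),  # reversed response
            (-2.0, 1.5, "blunted", True),
            (1.0, 5.0, "not_responsive", False),  # gate is strict
        ],
    )
    def test_worked_examples(self, ctl, ko, status, reversed_flag):
        assert classify_response(ctl, ko) == (status, reversed_flag)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_response(float("nan"), 1.0)
        with pytest.raises(ValueError):
            classify_response(2.0, float("inf"))

    @given(ctl=st.floats(-8, 8), ko=st.floats(-8, 8))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_under_joint_negation(self, ctl, ko):
        assert classify_response(ctl, ko) == classify_response(-ctl, -ko)

    @given(ctl=st.floats(1.1, 6), ko=st.floats(-6, 6),
           shrink=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_shrinking_ko_never_moves_blunted_to_enhanced(self, ctl, ko,
                                                          shrink):
        before, _ = classify_response(ctl, ko)
        after, _ = classify_response(ctl, shrink * ko)
        ranking = {"blunted": 0, "concordant": 1, "enhanced": 2}
        assert ranking[after] <= ranking[before]

    def test_vectorized_table_agrees_with_scalar(self, rng):
        means = condition_means(_table(rng, n_genes=50))
        table = classify_table(means)
        log2fc = log2_response(means)
        for gene in means.index:
            status, rev = classify_response(log2fc.loc[gene, "CTL"],
                                            log2fc.loc[gene, "KO"])
            assert table.loc[gene, "status"] == status
            assert bool(table.loc[gene, "reversed_flag"]) == rev


class TestSummarize:
    def test_blunted_fraction(self):
        statuses = ["blunted"] * 17 + ["enhanced"] * 3 + ["concordant"] * 5
        table = pd.DataFrame({"status": statuses,
                              "reversed_flag": [False] * 25})
        summary = summarize_classes(table)
        assert summary["n_altered"] == 20
        assert summary["blunted_fraction"] == 0.85
        assert summary["n_responsive"] == 25

    def test_no_altered_genes_fraction_missing(self):
        table = pd.DataFrame({"status": ["concordant"] * 4,
                              "reversed_flag": [False] * 4})
        assert summarize_classes(table)["blunted_fraction"] is None

    def test_counts_conserved(self, rng):
        table = classify_table(condition_means(_table(rng, n_genes=30)))
        summary = summarize_classes(table)
        assert sum(summary["counts"].values()) == 30


def hypergeom_enumeration(N, K, n):
    """Tail probabilities by explicit enumeration of all draws."""
    hist = np.zeros(min(n, K) + 1)
    for draw in itertools.combinations(range(N), n):
        hist[sum(1 for i in draw if i < K)] += 1
    hist /= hist.sum()
    return hist  # hist[k] = P(X = k)


class TestHypergeometric:
    def test_worked_example(self):
        assert hypergeometric_tail(4, 10, 5, 4) == pytest.approx(5 / 210)

    def test_k_zero_is_one(self):
        assert hypergeometric_tail(0, 10, 5, 4) == 1.0

    def test_selected_equals_universe(self):
        universe = {f"g{i}" for i in range(8)}
        result = hypergeometric_enrichment(universe, {"g0", "g1"}, universe)
        assert result.p_value == 1.0
        assert result.k == 2

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, {"x"}, {"a", "b"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 0, 0, 0)

    def test_matches_enumeration_small_universes(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    pmf = hypergeom_enumeration(N, K, n)
                    for k in range(min(n, K) + 2):
                        expected = pmf[k:].sum()
                        assert hypergeometric_tail(k, N, K, n) == pytest.approx(
                            expected, abs=1e-12)

    def test_matches_scipy_cross_check(self, rng):
        from scipy.stats import hypergeom
        for _ in range(50):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeometric_tail(k, N, K, n) == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), abs=1e-10)


class TestBH:
    def test_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)


class TestEnrichGeneSets:
    def test_enriched_set_ranks_first(self, rng):
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(20)}
        sets = {
            "target": [f"g{i}" for i in range(15)],  # heavy overlap
            "decoy1": [f"g{i}" for i in range(50, 65)],
            "decoy2": [f"g{i}" for i in range(70, 85)],
        }
        table = enrich_gene_sets(selected, sets, universe)
        assert table.index[0] == "target"
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
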