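"""Generator contracts: determinism, planted structure, analytic limits."""

import numpy as np
import pandas as pd
import pytest

from secscreen import SimConfig, SimConfigError
from secscreen import simulate as sim
from secscreen.response import classify_table, condition_means


class TestConfig:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"module_size": 500, "n_genes": 400},
            {"noise_sd": 0.0},
            {"noise_sd": -1.0},
            {"blunted_fraction": 0.7, "enhanced_fraction": 0.5},
            {"module_loading": 0.0},
            {"n_cells_per_cluster": []},
            {"n_responsive": 10_000},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(SimConfigError):
            SimConfig(**overrides)

    def test_round_trip_dict(self, small_config):
        assert SimConfig.from_dict(small_config.to_dict()) == small_config

    def test_unknown_key_rejected(self):
        with pytest.raises(SimConfigError, match="unknown"):
            SimConfig.from_dict({"seed": 1, "n_gene": 5})


class TestDeterminism:
    def test_coexpression_identical_across_runs(self, small_config):
        a1, b1, t1 = sim.gen_coexpression_tissues(small_config)
        a2, b2, t2 = sim.gen_coexpression_tissues(small_config)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_profile_and_response_identical(self, small_config):
        p1, _ = sim.gen_tissue_profiles(small_config)
        p2, _ = sim.gen_tissue_profiles(small_config)
        pd.testing.assert_frame_equal(p1, p2)
        r1, s1, _ = sim.gen_response_dataset(small_config)
        r2, s2, _ = sim.gen_response_dataset(small_config)
        pd.testing.assert_frame_equal(r1, r2)
        assert s1 == s2

    def test_single_cell_identical_sparse(self, small_config):
        d1, _ = sim.gen_single_cell(small_config)
        d2, _ = sim.gen_single_cell(small_config)
        assert (d1.X != d2.X).nnz == 0
        assert list(d1.obs["cluster"]) == list(d2.obs["cluster"])

    def test_different_seeds_differ(self, small_config):
        a1, _, _ = sim.gen_coexpression_tissues(small_config)
        other = SimConfig.from_dict({**small_config.to_dict(), "seed": 2})
        a2, _, _ = sim.gen_coexpression_tissues(other)
        assert not a1.equals(a2)


class TestCoexpression:
    def test_truth_partitions_universe(self, small_config):
        _, _, truth = sim.gen_coexpression_tissues(small_config)
        counts = truth.class_counts()
        assert counts[sim.BOTH_TISSUE] == small_config.module_size
        assert counts[sim.SINGLE_TISSUE] == small_config.module_size
        assert counts.sum() == small_config.n_genes
        assert set(truth.anchor_ids) <= set(truth.genes_with(sim.BOTH_TISSUE))

    def test_noise_free_module_correlation_is_one(self):
        cfg = SimConfig(seed=7, n_genes=100, module_size=10, n_tissues=6,
                        n_decoy_groups=1, module_loading=1.0, noise_sd=1e-8,
                        n_responsive=20)
        a, _, truth = sim.gen_coexpression_tissues(cfg)
        module = truth.genes_with(sim.BOTH_TISSUE)
        anchor = truth.anchor_ids[0]
        for gene in module[2:6]:
            r = np.corrcoef(a.loc[gene], a.loc[anchor])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_mean_within_module_r_matches_factor_model(self):
        # one-factor model: r = loading^2 / (loading^2 + noise_sd^2)
        cfg = SimConfig(seed=1, n_genes=200, module_size=40,
                        module_loading=0.9, noise_sd=0.5,
                        n_samples_per_tissue=60, n_tissues=8)
        a, _, truth = sim.gen_coexpression_tissues(cfg)
        module = truth.genes_with(sim.BOTH_TISSUE)
        block = a.loc[module].to_numpy()
        corr = np.corrcoef(block)
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        expected = sim.within_module_correlation(cfg)
        assert np.mean(off_diag) == pytest.approx(expected, abs=0.1)


class TestTissueProfiles:
    def test_zero_noise_broad_rows_constant(self, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(),
                                   "profile_noise_sd": 0.0})
        profile, truth = sim.gen_tissue_profiles(cfg)
        for gene in truth.genes_with(sim.BROAD)[:5]:
            row = profile.loc[gene]
            assert row.nunique() == 1

    def test_zero_noise_restricted_shares_are_half(self, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(),
                                   "profile_noise_sd": 0.0})
        profile, truth = sim.gen_tissue_profiles(cfg)
        restricted = truth.genes_with(sim.TISSUE_RESTRICTED)
        shares = profile.loc[restricted].div(
            profile.loc[restricted].sum(axis=1), axis=0)
        assert np.allclose(shares[["liver", "intestine"]], 0.5)
        assert np.allclose(shares.drop(columns=["liver", "intestine"]), 0.0)

    def test_restricted_top2_tissues_are_designated_pair(self):
        cfg = SimConfig(seed=3, n_tissues=10)
        profile, truth = sim.gen_tissue_profiles(cfg)
        for gene in truth.genes_with(sim.TISSUE_RESTRICTED):
            top2 = set(profile.loc[gene].nlargest(2).index)
            assert top2 == {"liver", "intestine"}

    def test_too_few_tissues_rejected(self, small_config):
        cfg = small_config.to_dict()
        cfg.update(n_tissues=2, n_decoy_groups=0)
        with pytest.raises(SimConfigError):
            sim.gen_tissue_profiles(SimConfig.from_dict(cfg))


class TestSingleCell:
    def test_negative_binomial_moments(self, rng):
        draws = sim._nb_counts(rng, np.full(500, 5.0), dispersion=2.0)
        assert draws.mean() == pytest.approx(5.0, rel=0.10)
        # var = mu + mu^2 / dispersion = 17.5
        assert draws.var() == pytest.approx(17.5, rel=0.35)

    def test_zero_mean_gives_zero_counts(self, rng):
        assert sim._nb_counts(rng, np.zeros(100), 2.0).sum() == 0

    def test_exactly_one_small_cluster_required(self, small_config):
        cfg = small_config.to_dict()
        cfg["n_cells_per_cluster"] = [50, 40]
        with pytest.raises(SimConfigError, match="< 10"):
            sim.gen_single_cell(SimConfig.from_dict(cfg))
        cfg["n_cells_per_cluster"] = [50]
        with pytest.raises(SimConfigError):
            sim.gen_single_cell(SimConfig.from_dict(cfg))

    def test_restricted_genes_elevated_in_cluster0_only(self, small_config):
        adata, truth = sim.gen_single_cell(small_config)
        restricted = truth.genes_with(sim.CELLTYPE_RESTRICTED)
        counts = np.asarray(adata[:, restricted].X.todense())
        hep = adata.obs["cluster"] == "hepatocytes"
        assert counts[hep.to_numpy()].mean() > 10 * counts[~hep.to_numpy()].mean()


class TestResponse:
    def test_planted_fraction_is_exact(self):
        cfg = SimConfig(seed=11, n_genes=2000, n_responsive=200,
                        blunted_fraction=0.85, enhanced_fraction=0.15)
        _, _, truth = sim.gen_response_dataset(cfg)
        counts = truth.class_counts()
        assert counts[sim.RESP_BLUNTED] == 170
        assert counts[sim.RESP_ENHANCED] == 30
        altered = counts[sim.RESP_BLUNTED] + counts[sim.RESP_ENHANCED]
        assert counts[sim.RESP_BLUNTED] / altered == 0.85

    def test_noise_free_classification_recovers_planting(self, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(),
                                   "response_noise_sd": 0.0})
        table, _, truth = sim.gen_response_dataset(cfg)
        classified = classify_table(condition_means(table))
        planted = truth.table["planted_class"]
        mapping = {sim.RESP_BLUNTED: "blunted", sim.RESP_ENHANCED: "enhanced",
                   sim.RESP_CONCORDANT: "concordant", sim.NULL: "not_responsive"}
        for gene, cls in planted.items():
            assert classified.loc[gene, "status"] == mapping[cls], gene

    def test_no_responsive_genes_in_noise_free_limit(self, small_config):
        cfg = SimConfig.from_dict({**small_config.to_dict(),
                                   "n_responsive": 0,
                                   "response_noise_sd": 0.0})
        table, _, _ = sim.gen_response_dataset(cfg)
        classified = classify_table(condition_means(table))
        assert (classified["status"] == "not_responsive").all()

    def test_enriched_set_is_mostly_blunted(self, small_config):
        _, sets, truth = sim.gen_response_dataset(small_config)
        blunted = set(truth.genes_with(sim.RESP_BLUNTED))
        lipid = set(sets["lipid_biosynthesis"])
        assert len(lipid & blunted) / len(lipid) >= 0.75
        for name, members in sets.items():
            if name.startswith("decoy"):
                assert not set(members) & blunted
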