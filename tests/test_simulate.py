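"""Synthetic-data generators: determinism, error models, generative truth."""

import numpy as np
import pytest

from epivar.simulate import (
    EpimutationConfig,
    ExpressionSimTruth,
    PopulationSimConfig,
    ReadSimConfig,
    simulate_epimutation_population,
    simulate_expression,
    simulate_genotypes,
    simulate_methylomes,
    simulate_reads,
    simulate_traits,
)


class TestEpimutation:
    def test_no_gain_stays_unmethylated(self):
        cfg = EpimutationConfig(
            n_sites=5, gain_base=0.0, gain_coop=0.0, loss_rate=0.1,
            n_generations=200, n_lineages=20, seed=0,
        )
        res = simulate_epimutation_population(cfg)
        assert np.all(res["levels"] == 0.0)

    def test_no_loss_absorbs_fully_methylated(self):
        cfg = EpimutationConfig(
            n_sites=5, gain_base=0.01, gain_coop=0.0, loss_rate=0.0,
            n_generations=5000, n_lineages=50, seed=0,
        )
        res = simulate_epimutation_population(cfg)
        assert res["levels"].mean() > 0.99

    def test_deterministic_under_seed(self):
        cfg = EpimutationConfig(n_generations=200, n_lineages=10, seed=7)
        a = simulate_epimutation_population(cfg)["states"]
        b = simulate_epimutation_population(cfg)["states"]
        assert np.array_equal(a, b)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            EpimutationConfig(gain_base=1.5)

    def test_default_regime_is_bimodal(self):
        """Cooperative gain makes the population distribution of gene mCG
        bimodal: mass near 0 and near the high fixed point, a dip between."""
        cfg = EpimutationConfig(n_generations=30000, n_lineages=740, seed=3)
        lv = simulate_epimutation_population(cfg)["levels"]
        low = (lv < 0.2).mean()
        high = (lv > 0.4).mean()
        mid = ((lv >= 0.2) & (lv <= 0.4)).mean()
        assert low > 0.2 and high > 0.2
        assert mid < min(low, high)

    def test_higher_gain_raises_methylated_class_frequency(self):
        freqs = []
        for gb in (2e-4, 2e-3):
            cfg = EpimutationConfig(
                gain_base=gb, n_generations=20000, n_lineages=300, seed=5
            )
            lv = simulate_epimutation_population(cfg)["levels"]
            freqs.append((lv > 0.4).mean())
        assert freqs[1] > freqs[0]


class TestGenotypes:
    def test_single_population_frequencies_homogeneous(self):
        cfg = PopulationSimConfig(
            n_accessions=400, n_snps=300, n_subpopulations=1, divergence=0.0,
            ld_rho=0.0, seed=0,
        )
        G = simulate_genotypes(cfg)["genotypes"].astype(float)
        half = G.shape[0] // 2
        diff = np.abs(G[:half].mean(0) - G[half:].mean(0))
        # pure binomial sampling noise: sd <= sqrt(2 * 0.25 / 200) = 0.05
        assert diff.mean() < 3 * 0.05

    def test_divergent_subpopulations_separate_on_pc1(self):
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LogisticRegression

        cfg = PopulationSimConfig(
            n_accessions=300, n_snps=400, n_subpopulations=2, divergence=0.3,
            seed=1,
        )
        res = simulate_genotypes(cfg)
        pc1 = PCA(n_components=1).fit_transform(
            res["genotypes"].astype(float)
        )
        acc = (
            LogisticRegression()
            .fit(pc1, res["subpop"])
            .score(pc1, res["subpop"])
        )
        assert acc > 0.95

    def test_seed_reproducible(self):
        cfg = PopulationSimConfig(n_accessions=50, n_snps=60, seed=9)
        a = simulate_genotypes(cfg)["genotypes"]
        b = simulate_genotypes(cfg)["genotypes"]
        assert np.array_equal(a, b)

    def test_ld_decays_with_distance(self):
        cfg = PopulationSimConfig(
            n_accessions=2000, n_snps=20, ld_block_size=20, ld_rho=0.8, seed=2
        )
        G = simulate_genotypes(cfg)["genotypes"].astype(float)
        c = np.corrcoef(G.T)
        assert c[0, 1] > c[0, 5] > c[0, 15]


class TestReads:
    def test_error_free_reads_match_truth(self):
        states = np.array([True] * 50 + [False] * 50)
        cfg = ReadSimConfig(
            mean_depth=200, nonconversion_rate=0.0, overconversion_rate=0.0,
            seed=0,
        )
        tab = simulate_reads(states, cfg)
        frac = tab["reads_meth"] / tab["reads_total"]
        assert np.all(frac[:50] == 1.0)
        assert np.all(frac[50:] == 0.0)

    def test_nonconversion_rate_recovered(self):
        states = np.zeros(4000, dtype=bool)
        cfg = ReadSimConfig(mean_depth=25, nonconversion_rate=0.005, seed=1)
        tab = simulate_reads(states, cfg)
        pooled = tab["reads_meth"].sum() / tab["reads_total"].sum()
        assert 0.004 <= pooled <= 0.006

    def test_deterministic(self):
        states = np.random.default_rng(0).random(100) < 0.5
        cfg = ReadSimConfig(seed=3)
        assert simulate_reads(states, cfg).equals(simulate_reads(states, cfg))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ReadSimConfig(nonconversion_rate=0.6)


class TestExpression:
    def _markers(self, n, seed=0):
        rng = np.random.default_rng(seed)
        gbm = rng.random((n, 60))
        tem = rng.random((n, 30))
        G = (rng.random((n, 100)) < 0.3).astype(float)
        return gbm, tem, G

    def test_zero_targets_give_pure_noise(self):
        n = 1000
        gbm, tem, G = self._markers(n)
        truth = ExpressionSimTruth(0.0, 0.0, 0.0, seed=1)
        res = simulate_expression(gbm, tem, G, truth)
        assert abs(res["expression"].var() - 1.0) < 0.1

    def test_realized_fractions_near_targets(self):
        n = 1000
        gbm, tem, G = self._markers(n, seed=2)
        truth = ExpressionSimTruth(0.15, 0.25, 0.25, seed=3)
        res = simulate_expression(gbm, tem, G, truth)
        for name, target in (("gbm", 0.15), ("tem", 0.25), ("snp", 0.25)):
            assert abs(truth.realized_pve[name] - target) < 0.03

    def test_single_causal_marker_no_noise_is_collinear(self):
        n = 200
        rng = np.random.default_rng(4)
        gbm = rng.random((n, 1))
        tem = np.empty((n, 0))
        G = np.empty((n, 0))
        truth = ExpressionSimTruth(1.0, 0.0, 0.0, seed=5)
        res = simulate_expression(gbm, tem, G, truth, n_causal=(1, 1, 1))
        r = np.corrcoef(res["expression"], gbm[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(
                np.zeros((10, 2)), np.zeros((11, 2)), np.zeros((10, 2)),
                ExpressionSimTruth(0.1, 0.1, 0.1),
            )


class TestTraits:
    def test_no_effects_is_noise(self):
        rng = np.random.default_rng(0)
        E = (rng.random((2000, 50)) < 0.5).astype(float)
        res = simulate_traits(E, seed=2)
        assert abs(res["trait"].var() - 1.0) < 0.15

    def test_truth_records_causal_genes(self):
        rng = np.random.default_rng(1)
        E = (rng.random((300, 50)) < 0.5).astype(float)
        res = simulate_traits(E, causal_genes=[3, 7], causal_pve=0.3, seed=2)
        assert res["causal_genes"] == [3, 7]


class TestMethylomes:
    def test_truth_matrix_shapes_and_classes(self):
        sim = simulate_methylomes(n_genes=20, n_accessions=10, seed=0)
        assert sim["truth_states"].shape == (20, 10)
        assert set(np.unique(sim["truth_states"])) <= {"gbm", "tem", "um"}
        # teM carriers methylate non-CG sites; gbM carriers never do
        sites = sim["sites"]
        for (g, a), grp in sites.groupby(["gene_id", "accession"]):
            state = sim["truth_states"].loc[g, a]
            noncg_meth = grp[(grp["context"] != "CG") & grp["true_methylated"]]
            if state == "tem":
                assert len(noncg_meth) >= 1
            else:
                assert len(noncg_meth) == 0

    def test_deterministic(self):
        a = simulate_methylomes(n_genes=5, n_accessions=4, seed=3)
        b = simulate_methylomes(n_genes=5, n_accessions=4, seed=3)
        assert a["sites"].equals(b["sites"])
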