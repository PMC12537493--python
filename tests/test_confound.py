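"""Genetic-confound checks: cis scans, nested populations, haplogroups, LD."""

import numpy as np
import pytest

from epivar.confound import (
    cis_scan,
    define_haplogroups,
    ld_epiallele_snp,
    nested_population_test,
    sv_invariant_test,
    trans_pve,
    within_haplogroup_association,
)


class TestCisScan:
    def test_perfect_snp_is_significant(self):
        rng = np.random.default_rng(0)
        G = (rng.random((100, 10)) < 0.4).astype(float)
        expr = G[:, 3].copy()
        scan = cis_scan(expr, G)
        assert scan.loc[3, "significant"]
        assert scan.loc[3, "p_value"] < 1e-20

    def test_null_scan_controls_false_positives(self):
        rng = np.random.default_rng(1)
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            G = (r.random((600, 50)) < 0.4).astype(float)
            expr = r.normal(size=600)
            hits += cis_scan(expr, G)["significant"].any()
        assert hits / 40 <= 0.15  # per-scan FWER near alpha = 0.05

    def test_monomorphic_window_flagged(self):
        G = np.ones((50, 4))
        scan = cis_scan(np.random.default_rng(2).normal(size=50), G)
        assert scan["monomorphic"].all()
        assert not scan["significant"].any()


class TestNestedPopulations:
    def test_collinear_mcg_not_retained(self):
        rng = np.random.default_rng(3)
        snp = (rng.random(200) < 0.5).astype(float)
        mcg = snp * 0.7  # zero variance within each allele class
        expr = snp + rng.normal(scale=0.2, size=200)
        out = nested_population_test(mcg, expr, snp)
        assert out["status"] in ("lost", "untestable")
        assert out["status"] != "retained"

    def test_independent_epigenetic_effect_retained(self):
        kept = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            n = 600
            snp = (rng.random(n) < 0.5).astype(float)
            mcg = (rng.random(n) < 0.5).astype(float) * 0.6
            expr = np.sqrt(0.1) * (mcg - mcg.mean()) / mcg.std() + np.sqrt(
                0.9
            ) * rng.normal(size=n)
            out = nested_population_test(mcg, expr, snp)
            kept += out["status"] == "retained"
        assert kept / 30 >= 0.95

    def test_small_class_skipped(self):
        rng = np.random.default_rng(4)
        snp = np.r_[np.zeros(10), np.ones(100)]
        mcg = rng.random(110)
        expr = 2 * mcg + rng.normal(scale=0.1, size=110)
        out = nested_population_test(mcg, expr, snp, min_n=15)
        small = [r for r in out["nested"] if r["allele"] == 0.0][0]
        assert not small["valid"]
        assert out["status"] == "retained"  # decided by the large class


class TestHaplogroups:
    def test_min_size_boundary(self):
        G = np.zeros((29, 3))
        G[:14, 0] = 1  # 14 identical accessions -> discarded
        groups = define_haplogroups(G, min_size=15)
        sizes = {g.size: g.kept for g in groups}
        assert sizes[14] is False
        assert sizes[15] is True

    def test_one_snp_difference_separates(self):
        G = np.zeros((30, 4))
        G[15:, 2] = 1
        groups = define_haplogroups(G)
        assert len(groups) == 2

    def test_partition_covers_complete_accessions(self):
        rng = np.random.default_rng(5)
        G = (rng.random((80, 3)) < 0.5).astype(float)
        G[5, 0] = np.nan  # excluded: incomplete window genotype
        groups = define_haplogroups(G, min_size=1)
        members = np.concatenate([g.members for g in groups])
        assert sorted(members) == [i for i in range(80) if i != 5]
        assert len(set(members)) == len(members)


class TestWithinHaplogroup:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(6)
        G = np.zeros((60, 2))
        state = (rng.random(60) < 0.5).astype(float)
        trait = rng.normal(size=60)
        groups = define_haplogroups(G)
        out = within_haplogroup_association(groups, state, trait, binary_state=True)
        assert out["p_value"].iloc[0] > 0.05

    def test_shifted_classes_detected(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            G = np.zeros((60, 2))
            state = np.r_[np.zeros(30), np.ones(30)]
            trait = rng.normal(size=60) + state  # 1 sd shift
            groups = define_haplogroups(G)
            out = within_haplogroup_association(
                groups, state, trait, binary_state=True
            )
            hits += out["p_value"].iloc[0] < 0.01
        assert hits / 30 >= 0.9

    def test_single_class_untestable(self):
        G = np.zeros((40, 2))
        state = np.ones(40)
        trait = np.random.default_rng(7).normal(size=40)
        out = within_haplogroup_association(
            define_haplogroups(G), state, trait, binary_state=True
        )
        assert not out["testable"].iloc[0]


class TestSVInvariant:
    def test_no_sv_polymorphism_equals_full_test(self):
        rng = np.random.default_rng(8)
        mcg = rng.random(100)
        expr = 2 * mcg + rng.normal(scale=0.3, size=100)
        sv = np.zeros((100, 2))
        out = sv_invariant_test(mcg, expr, sv)
        assert out["n"] == 100
        assert out["status"] == "retained"

    def test_sv_driven_association_lost(self):
        lost = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 300
            sv = (rng.random(n) < 0.5).astype(float)[:, None]
            mcg = sv[:, 0] * 0.6  # mCG collinear with the SV
            expr = sv[:, 0] + rng.normal(scale=0.5, size=n)
            out = sv_invariant_test(mcg, expr, sv)
            lost += out["status"] in ("lost", "untestable")
        assert lost / 20 >= 0.9

    def test_independent_sv_retained(self):
        rng = np.random.default_rng(9)
        n = 400
        sv = (rng.random(n) < 0.5).astype(float)[:, None]
        mcg = (rng.random(n) < 0.5).astype(float) * 0.6
        expr = 1.5 * mcg + rng.normal(scale=0.5, size=n)
        out = sv_invariant_test(mcg, expr, sv)
        assert out["status"] == "retained"


class TestLD:
    def test_coupled_haplotypes_complete_ld(self):
        a = np.r_[np.ones(50), np.zeros(50)]
        ld = ld_epiallele_snp(a, a)
        assert ld.r == pytest.approx(1.0)
        assert ld.d_prime == pytest.approx(1.0)

    def test_counts_worked_example(self):
        # haplotype counts AB=40, Ab=10, aB=10, ab=40
        a = np.r_[np.ones(50), np.zeros(50)]
        b = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        ld = ld_epiallele_snp(a, b)
        assert ld.d == pytest.approx(0.15)
        assert ld.d_prime == pytest.approx(0.6)
        assert ld.r == pytest.approx(0.6)

    def test_independence_gives_zero(self):
        a = np.r_[np.ones(50), np.zeros(50)]
        b = np.tile([1, 0], 50)
        ld = ld_epiallele_snp(a, b)
        assert ld.r == pytest.approx(0.0)
        assert ld.d_prime == pytest.approx(0.0)

    def test_monomorphic_flagged(self):
        assert not ld_epiallele_snp(np.ones(20), np.r_[np.ones(10), np.zeros(10)]).defined


class TestTransPve:
    def test_focal_equals_snp_gives_100(self):
        rng = np.random.default_rng(10)
        G = (rng.random((200, 30)) < 0.4).astype(float)
        est = trans_pve(G[:, 7].copy(), G)
        assert est.percent == pytest.approx(100.0)

    def test_null_attributes_almost_nothing(self):
        rng = np.random.default_rng(11)
        G = (rng.random((625, 500)) < 0.4).astype(float)
        mcg = rng.normal(size=625)
        est = trans_pve(mcg, G)
        # most runs find no Bonferroni hit at all; when one appears it
        # explains a trivial share
        assert est.percent < 5.0

    def test_no_mcg_variance_rejected(self):
        with pytest.raises(ValueError):
            trans_pve(np.ones(50), np.random.default_rng(0).random((50, 5)))
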