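"""Site calling, segmentation, gene classification and population summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epivar.methylome import (
    assign_sites_to_genes,
    call_site,
    call_sites,
    classify_gene,
    conservation_summary,
    gene_mean_mcg,
    min_sufficient_coverage,
    segment_gene,
    state_count_correlation,
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["pos", "context", "status"])


class TestCallSite:
    @pytest.mark.parametrize(
        "meth, total, expected",
        [
            (4, 10, "partial"),  # significant vs error but < 45% methylated
            (0, 50, "unmethylated"),
            (9, 10, "methylated"),
            (1, 2, "insufficient"),  # depth 2 cannot separate the two models
        ],
    )
    def test_worked_examples(self, meth, total, expected):
        assert call_site(meth, total, error_rate=0.01, alpha=0.05) == expected

    def test_binomial_tail_significance_matches_scipy(self):
        # (9, 10) at error 0.01: upper tail is astronomically small and the
        # methylated fraction 0.9 >= 0.45
        p = stats.binom.sf(8, 10, 0.01)
        assert p < 0.05
        assert call_site(9, 10, 0.01, 0.05) == "methylated"

    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            call_site(5, 3)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        total = rng.integers(0, 60, size=200)
        meth = rng.binomial(total, 0.3)
        vec = call_sites(meth, total, 0.01, 0.05)
        for m, t, s in zip(meth, total, vec):
            assert call_site(int(m), int(t), 0.01, 0.05) == s

    @given(
        total=st.integers(4, 80),
        frac=st.floats(0.0, 1.0),
        a1=st.sampled_from([0.01, 0.05]),
        a2=st.sampled_from([0.1, 0.2]),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_alpha_never_unmethylates(self, total, frac, a1, a2):
        """Monotonicity: a looser alpha can only move calls toward
        methylated/partial, never from methylated back to unmethylated."""
        meth = int(round(frac * total))
        lo = call_site(meth, total, 0.01, min(a1, a2))
        hi = call_site(meth, total, 0.01, max(a1, a2))
        if lo in ("methylated", "partial"):
            assert hi != "unmethylated"

    def test_min_sufficient_coverage_fisher_boundary(self):
        # at error 0.01 the extreme 2x2 table [[0,n],[n,0]] first reaches
        # two-sided significance 2/C(2n,n) < 0.05 at n = 4
        assert min_sufficient_coverage(0.01, 0.05) == 4


class TestSegmentation:
    def test_cg_only_run_is_gbm_like(self):
        s = _sites([(0, "CG", "methylated"), (50, "CG", "methylated"),
                    (100, "CG", "methylated")])
        segs = segment_gene(s, max_gap=200)
        assert len(segs) == 1
        assert segs[0].seg_class == "gbm"
        assert segs[0].n_cg_methylated == 3

    def test_noncg_methylation_makes_tem_like(self):
        s = _sites([(0, "CG", "methylated"), (40, "CHH", "methylated"),
                    (80, "CHH", "methylated"), (120, "CG", "methylated")])
        segs = segment_gene(s, max_gap=200)
        assert len(segs) == 1
        assert segs[0].seg_class == "tem"

    def test_gap_splits_segments(self):
        s = _sites([(0, "CG", "methylated"), (100, "CG", "unmethylated"),
                    (500, "CG", "methylated")])
        segs = segment_gene(s, max_gap=200)
        assert len(segs) == 2

    def test_unsorted_input_rejected(self):
        s = _sites([(100, "CG", "methylated"), (0, "CG", "methylated")])
        with pytest.raises(ValueError):
            segment_gene(s)


class TestClassifyGene:
    def test_gbm_rule(self):
        s = _sites([(0, "CG", "methylated"), (50, "CG", "unmethylated"),
                    (100, "CG", "methylated")])
        segs = segment_gene(s, max_gap=200)
        assert classify_gene(segs, s) == "gbm"

    def test_tem_overlap_demotes_to_both(self):
        from epivar.methylome import MethSegment

        segs = [
            MethSegment(0, 400, "gbm", n_cg_sites=5, n_cg_methylated=3),
            MethSegment(500, 620, "tem", n_cg_sites=2, n_cg_methylated=1),
        ]
        # teM segment is 120 bp >= 25% of the 400 bp gbM segment
        assert classify_gene(segs, _sites([])) == "both"

    def test_um_rule_needs_three_unmethylated(self):
        s = _sites([(0, "CG", "unmethylated"), (50, "CG", "unmethylated"),
                    (100, "CG", "unmethylated")])
        assert classify_gene([], s) == "um"
        s2 = _sites([(0, "CG", "unmethylated"), (50, "CG", "unmethylated")])
        assert classify_gene([], s2) == "indeterminate"

    def test_short_tem_segment_is_indeterminate(self):
        from epivar.methylome import MethSegment

        segs = [MethSegment(0, 100, "tem", n_cg_sites=2, n_cg_methylated=1)]
        s = _sites([(0, "CG", "methylated"), (50, "CHH", "methylated")])
        assert classify_gene(segs, s) == "indeterminate"


class TestMeanMcg:
    @pytest.mark.parametrize(
        "n_meth, n_unmeth, n_partial, n_insuff, expected",
        [(6, 4, 3, 0, 0.6), (0, 10, 0, 0, 0.0), (5, 0, 0, 2, 1.0)],
    )
    def test_partial_and_insufficient_excluded(
        self, n_meth, n_unmeth, n_partial, n_insuff, expected
    ):
        rows = (
            [(i, "CG", "methylated") for i in range(n_meth)]
            + [(100 + i, "CG", "unmethylated") for i in range(n_unmeth)]
            + [(200 + i, "CG", "partial") for i in range(n_partial)]
            + [(300 + i, "CG", "insufficient") for i in range(n_insuff)]
        )
        assert gene_mean_mcg(_sites(rows)) == pytest.approx(expected)

    def test_no_called_sites_is_missing(self):
        assert np.isnan(gene_mean_mcg(_sites([(0, "CG", "partial")])))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        rows = [(i, "CG", rng.choice(["methylated", "unmethylated", "partial"]))
                for i in range(30)]
        base = gene_mean_mcg(_sites(rows))
        rng.shuffle(rows)
        assert gene_mean_mcg(_sites(rows)) == pytest.approx(base)


class TestPopulationSummaries:
    def test_conservation_frequencies_and_bins(self):
        states = pd.DataFrame(
            {f"a{i}": ["gbm" if i < 100 else "um", "gbm", "both"]
             for i in range(400)},
            index=["g1", "g2", "g3"],
        )
        summ = conservation_summary(states)
        assert summ.loc["g1", "gbm_freq"] == pytest.approx(0.25)
        assert summ.loc["g1", "gbm_bin"] == "[10,90)"
        assert summ.loc["g2", "gbm_bin"] == "100%"
        assert np.isnan(summ.loc["g3", "gbm_freq"])  # no available calls

    def test_state_count_correlation_closed_form(self):
        gbm = [10, 20, 30, 40]
        tem = [5, 4, 9, 8]
        states = _counts_to_states(gbm, tem)
        res = state_count_correlation(states)
        # independent closed-form Pearson oracle
        x, y = np.array(gbm, float), np.array(tem, float)
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_perfect_and_anti_correlation(self):
        states = _counts_to_states([1, 2, 3], [1, 2, 3])
        assert state_count_correlation(states)["r"] == pytest.approx(1.0)
        states = _counts_to_states([1, 2, 3], [3, 2, 1])
        assert state_count_correlation(states)["r"] == pytest.approx(-1.0)

    def test_constant_counts_flagged(self):
        states = _counts_to_states([2, 2, 2], [1, 2, 3])
        assert not state_count_correlation(states)["defined"]


def _counts_to_states(gbm_counts, tem_counts):
    n_genes = max(gbm_counts) + max(tem_counts)
    cols = {}
    for a, (g, t) in enumerate(zip(gbm_counts, tem_counts)):
        col = ["gbm"] * g + ["tem"] * t + ["um"] * (n_genes - g - t)
        cols[f"acc{a}"] = col
    return pd.DataFrame(cols)


def test_assign_sites_to_genes_interval_lookup():
    genes = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "chrom": ["Chr1", "Chr1"],
         "start": [0, 1000], "end": [500, 1500], "strand": ["+", "+"]}
    )
    sites = pd.DataFrame(
        {"chrom": ["Chr1"] * 3, "pos": [100, 700, 1200]}
    )
    hit = assign_sites_to_genes(sites, genes)
    assert list(hit["gene_id"]) == ["g1", "g2"]
    assert list(hit["pos"]) == [100, 1200]
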