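"""Annotation statistics: metaprofiles, occupancy, enrichment, rank sums."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nedomains import annotate as an
from nedomains.domains import DomainSet
from tests.conftest import make_track


def exact_binomial_upper_tail(k: int, n: int, p: Fraction) -> float:
    """Independent oracle: rational-arithmetic sum of C(n,i) p^i (1-p)^(n-i)."""
    import math

    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return float(total)


class TestBoundaryMetaprofile:
    def test_constant_track_flat_profile(self):
        track = make_track(np.arange(1000) * 50, np.full(1000, 2.0))
        domains = DomainSet(
            "EAD", pd.DataFrame({"chrom": ["chr1"], "start": [20_000], "end": [30_000]})
        )
        prof = an.boundary_metaprofile(domains, track, flank_bp=5000, step_bp=500)
        covered = prof[prof["n_probes"] > 0]
        assert np.allclose(covered["mean_score"], 2.0)

    def test_step_track_transitions_at_boundary(self):
        values = np.zeros(2000)
        values[800:1200] = 1.0  # domain from 40 kb to 60 kb
        track = make_track(np.arange(2000) * 50, values)
        domains = DomainSet(
            "EAD", pd.DataFrame({"chrom": ["chr1"], "start": [40_000], "end": [60_000]})
        )
        prof = an.boundary_metaprofile(domains, track, flank_bp=10_000, step_bp=1000)
        outside = prof[prof["offset"] < -1000]["mean_score"].mean()
        inside = prof[prof["offset"] >= 1000]["mean_score"].mean()
        assert outside < 0.05 and inside > 0.95

    def test_flank_smaller_than_step_single_bin(self):
        track = make_track(np.arange(100) * 50, np.ones(100))
        domains = DomainSet(
            "EAD", pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})
        )
        prof = an.boundary_metaprofile(domains, track, flank_bp=200, step_bp=1000)
        assert len(prof) == 1

    def test_zero_domains_raises(self):
        track = make_track([0], [1.0])
        empty = DomainSet("EAD", pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError):
            an.boundary_metaprofile(empty, track)

    def test_shuffled_boundaries_flat_on_step_track(self):
        """Random boundaries average a planted step track to a flat profile."""
        rng = np.random.default_rng(0)
        n = 40_000
        values = np.zeros(n)
        # planted domains ~35% of probes
        pos = 0
        while pos < n - 600:
            pos += int(rng.integers(300, 900))
            width = int(rng.integers(200, 500))
            values[pos : pos + width] = 1.0
            pos += width
        track = make_track(np.arange(n) * 50, values)
        starts = rng.integers(30_000, n * 50 - 30_000, size=1000)
        domains = DomainSet(
            "shuffled",
            pd.DataFrame(
                {"chrom": "chr1", "start": np.sort(starts) * 2, "end": np.sort(starts) * 2 + 1}
            ).drop_duplicates(subset="start"),
        )
        prof = an.boundary_metaprofile(domains, track, flank_bp=10_000, step_bp=1000)
        covered = prof[prof["n_probes"] > 100]
        spread = covered["mean_score"].max() - covered["mean_score"].min()
        assert spread <= 0.1


class TestGeneOccupancy:
    def test_mean_of_overlapping_probes(self):
        track = make_track([1100, 1500], [1.0, 3.0])
        gene = an.GeneModel("g1", "chr1", "+", 1000, 2000)
        out = an.gene_occupancy(track, [gene])
        assert out.iloc[0]["mean_score"] == 2.0
        assert bool(out.iloc[0]["anchored"])

    def test_no_probes_missing(self):
        track = make_track([5000], [1.0])
        gene = an.GeneModel("g1", "chr1", "+", 1000, 2000)
        out = an.gene_occupancy(track, [gene])
        assert np.isnan(out.iloc[0]["mean_score"])
        assert not bool(out.iloc[0]["anchored"])

    def test_strand_invariance(self):
        track = make_track([1100, 1500, 1900], [1.0, -2.0, 4.0])
        plus = an.GeneModel("g1", "chr1", "+", 1000, 2000)
        minus = an.GeneModel("g2", "chr1", "-", 2000, 1000)
        out = an.gene_occupancy(track, [plus, minus])
        assert out.iloc[0]["mean_score"] == out.iloc[1]["mean_score"]

    def test_uniform_track_every_gene_equal(self):
        track = make_track(np.arange(100) * 50, np.full(100, 1.7))
        genes = [
            an.GeneModel(f"g{i}", "chr1", "+", i * 500, i * 500 + 400) for i in range(5)
        ]
        out = an.gene_occupancy(track, genes)
        assert np.allclose(out["mean_score"], 1.7)


class TestFeatureEnrichment:
    def test_exact_tail_sum_oracle(self):
        # 30 of 100 probes in promoters at background 0.2
        classes = pd.Series(["promoter"] * 30 + ["intron"] * 70)
        res = an.feature_enrichment(classes, {"promoter": 0.2})[0]
        expected = exact_binomial_upper_tail(30, 100, Fraction(1, 5))
        assert res.direction == "enriched"
        assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_depletion_closed_form(self):
        # 0 of 100 in exons at background 0.25 -> p = 0.75^100
        classes = pd.Series(["intron"] * 100)
        res = an.feature_enrichment(classes, {"exon": 0.25})[0]
        assert res.direction == "depleted"
        assert res.p_value == pytest.approx(0.75**100, rel=1e-10)

    def test_observed_equals_background_large_p(self):
        classes = pd.Series(["promoter"] * 20 + ["intron"] * 80)
        res = an.feature_enrichment(classes, {"promoter": 0.2})[0]
        assert res.p_value >= 0.5

    @pytest.mark.parametrize("n,k,num,den", [(500, 150, 1, 4), (350, 20, 1, 10)])
    def test_exact_oracle_larger_n(self, n, k, num, den):
        classes = pd.Series(["exon"] * k + ["intron"] * (n - k))
        res = an.feature_enrichment(classes, {"exon": num / den})[0]
        p = Fraction(num, den)
        if k / n >= num / den:
            expected = exact_binomial_upper_tail(k, n, p)
        else:
            expected = 1 - exact_binomial_upper_tail(k + 1, n, p)
        assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_degenerate_background_raises(self):
        classes = pd.Series(["exon"] * 10)
        with pytest.raises(ValueError):
            an.feature_enrichment(classes, {"exon": 1.0})


class TestClassifyProbes:
    def test_priority_promoter_over_exon_over_intron(self):
        # minus-strand gene: promoter upstream of TSS means to the right
        gene = an.GeneModel(
            "g1", "chr1", "+", 3000, 6000, exons=[(3000, 3500), (5000, 6000)]
        )
        track = make_track([500, 3200, 4000, 8000], [0.0] * 4)
        classes = an.classify_probes(track, [gene], promoter_bp=3000)
        assert list(classes) == ["promoter", "exon", "intron", "intergenic"]

    def test_minus_strand_promoter_location(self):
        gene = an.GeneModel("g1", "chr1", "-", 6000, 3000, exons=[(3000, 6000)])
        track = make_track([4000, 6500], [0.0, 0.0])  # sorted probe order
        classes = an.classify_probes(track, [gene], promoter_bp=3000)
        assert list(classes) == ["exon", "promoter"]


class TestCompareGeneSets:
    def test_enumeration_example(self):
        # [1,2,3] vs [4,5,6]: 1 of C(6,3)=20 assignments as extreme
        _, p = an.compare_gene_sets([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_sets_two_sided_p_one(self):
        _, p = an.compare_gene_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        a = [0.1, 0.5, 2.0, 3.0]
        b = [0.2, 1.0, 4.0]
        s1, p1 = an.compare_gene_sets(a, b)
        s2, p2 = an.compare_gene_sets(np.exp(a), np.exp(b))
        assert s1 == s2 and p1 == p2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_small_n(self, seed):
        """Exact p equals a from-scratch enumeration for n1+n2 <= 12."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 7))
        pooled = rng.integers(0, 8, size=n1 + n2).astype(float)  # ties likely
        a, b = pooled[:n1], pooled[n1:]
        _, p = an.compare_gene_sets(a, b, alternative="greater")
        ranks = stats.rankdata(pooled)
        obs = ranks[:n1].sum()
        sums = [
            sum(ranks[list(c)])
            for c in itertools.combinations(range(n1 + n2), n1)
        ]
        expected = np.mean([s >= obs - 1e-9 for s in sums])
        assert p == pytest.approx(expected)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            an.compare_gene_sets([], [1.0])

    def test_large_sample_normal_path_close_to_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.5, 1, 50)
        _, p = an.compare_gene_sets(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(ref)


class TestTrackCorrelation:
    def test_self_correlation_one(self):
        t = make_track(np.arange(100) * 50, np.random.default_rng(0).normal(size=100))
        assert an.track_correlation(t, t) == pytest.approx(1.0)

    def test_negated_minus_one(self):
        t = make_track(np.arange(100) * 50, np.random.default_rng(0).normal(size=100))
        neg = t.with_scores(-t.values())
        assert an.track_correlation(t, neg) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        t = make_track([0, 50], [1.0, 1.0])
        u = make_track([0, 50], [1.0, 2.0])
        with pytest.raises(ValueError):
            an.track_correlation(t, u)
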