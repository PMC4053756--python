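"""Relating domains and elements to genome annotation.

Covers the descriptive statistics used to interpret called domains:
metaprofiles of a secondary signal around domain boundaries, per-gene
occupancy scores, promoter/exon/intron enrichment by exact binomial
tests, Wilcoxon rank-sum comparisons between gene sets, and Pearson
correlations between tracks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nedomains.tracks import DomainSet, ProbeTrack


@dataclass
class GeneModel:
    """Minimal gene annotation: span, strand, exons and tissue labels.

    ``tss``/``tes`` are transcription start/end in genomic coordinates
    (tss > tes on the minus strand); exons are 0-based half-open
    intervals inside the gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        lo, hi = self.span()
        for s, e in self.exons:
            if s < lo or e > hi:
                raise ValueError(f"exon [{s},{e}) outside gene span of {self.gene_id}")

    def span(self) -> tuple[int, int]:
        """Genomic span (min, max) regardless of strand."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter(self, promoter_bp: int = 3000) -> tuple[int, int]:
        """Strand-aware window of up to ``promoter_bp`` upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.tss - promoter_bp), self.tss)
        return (self.tss, self.tss + promoter_bp)


def boundary_metaprofile(
    domains: DomainSet,
    secondary: ProbeTrack,
    flank_bp: int = 20_000,
    step_bp: int = 500,
    side: str = "left",
) -> pd.DataFrame:
    """Average a secondary signal as a function of distance from domain edges.

    For every domain boundary, probes of the secondary track are binned by
    the offset of their start from the boundary (negative offsets lie
    outside the domain for left boundaries).  Returns a DataFrame
    (offset, mean_score, n_probes); offsets label bin left edges.
    ``side`` may be "left", "right" (offsets mirrored so positive points
    into the domain) or "both".
    """
    if len(domains) == 0:
        raise ValueError("metaprofile requires at least one domain")
    if side not in {"left", "right", "both"}:
        raise ValueError("side must be 'left', 'right' or 'both'")
    values = secondary.values()
    n_bins = max(1, int(np.ceil(2 * flank_bp / step_bp)))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    by_chrom = {c: sl for c, sl in secondary.chrom_slices()}
    starts_all = secondary.probes["start"].to_numpy()

    def accumulate(chrom: str, boundary: int, mirror: bool) -> None:
        sl = by_chrom.get(chrom)
        if sl is None:
            return
        starts = starts_all[sl]
        lo = np.searchsorted(starts, boundary - flank_bp, "left")
        hi = np.searchsorted(starts, boundary + flank_bp, "left")
        offs = starts[lo:hi] - boundary
        if mirror:
            offs = -offs - 1  # reflect so positive offsets point into the domain
        bins = ((offs + flank_bp) // step_bp).astype(int)
        ok = (bins >= 0) & (bins < n_bins)
        np.add.at(sums, bins[ok], values[sl][lo:hi][ok])
        np.add.at(counts, bins[ok], 1)

    for chrom, start, end in zip(
        domains.intervals["chrom"], domains.intervals["start"], domains.intervals["end"]
    ):
        if side in {"left", "both"}:
            accumulate(chrom, int(start), mirror=False)
        if side in {"right", "both"}:
            accumulate(chrom, int(end), mirror=True)

    offsets = -flank_bp + step_bp * np.arange(n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_score": means, "n_probes": counts})


def gene_occupancy(track: ProbeTrack, genes: list[GeneModel]) -> pd.DataFrame:
    """Mean score of probes overlapping each gene span by >= 1 bp.

    Occupancy is span-based and therefore strand-invariant.  Genes with
    no overlapping probe get NaN and ``anchored`` = False; otherwise
    ``anchored`` records whether the mean score is positive (the gene is
    at the nuclear envelope in most cells).
    """
    values = track.values()
    by_chrom = {c: sl for c, sl in track.chrom_slices()}
    starts_all = track.probes["start"].to_numpy()
    ends_all = track.probes["end"].to_numpy()
    rows = []
    for gene in genes:
        lo_bp, hi_bp = gene.span()
        sl = by_chrom.get(gene.chrom)
        mean = np.nan
        n = 0
        if sl is not None:
            starts = starts_all[sl]
            ends = ends_all[sl]
            # probes with start < gene end and end > gene start overlap >= 1 bp
            lo = np.searchsorted(ends, lo_bp, "right")
            hi = np.searchsorted(starts, hi_bp, "left")
            if hi > lo:
                mean = float(values[sl][lo:hi].mean())
                n = int(hi - lo)
        rows.append((gene.gene_id, mean, n, bool(n and mean > 0)))
    return pd.DataFrame(rows, columns=["gene_id", "mean_score", "n_probes", "anchored"])


def classify_probes(
    track: ProbeTrack, genes: list[GeneModel], promoter_bp: int = 3000
) -> pd.Series:
    """Assign each probe to promoter/exon/intron/intergenic.

    A probe belongs to a class when its start falls inside a region of
    that class; overlaps resolve by the fixed precedence
    promoter > exon > intron.
    """
    starts_all = track.probes["start"].to_numpy()
    by_chrom = {c: sl for c, sl in track.chrom_slices()}
    labels = np.full(track.n_probes, "intergenic", dtype=object)
    rank = {"intergenic": 0, "intron": 1, "exon": 2, "promoter": 3}

    def mark(regions: list[tuple[str, int, int]], name: str) -> None:
        for chrom, lo_bp, hi_bp in regions:
            sl = by_chrom.get(chrom)
            if sl is None:
                continue
            starts = starts_all[sl]
            lo = np.searchsorted(starts, lo_bp, "left") + sl.start
            hi = np.searchsorted(starts, hi_bp, "left") + sl.start
            for i in range(lo, hi):
                if rank[labels[i]] < rank[name]:
                    labels[i] = name

    introns, exons, promoters = [], [], []
    for g in genes:
        promoters.append((g.chrom,) + g.promoter(promoter_bp))
        span = g.span()
        covered = sorted(g.exons)
        exons.extend((g.chrom, s, e) for s, e in covered)
        cursor = span[0]
        for s, e in covered:
            if s > cursor:
                introns.append((g.chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < span[1]:
            introns.append((g.chrom, cursor, span[1]))
    mark(introns, "intron")
    mark(exons, "exon")
    mark(promoters, "promoter")
    return pd.Series(labels, name="feature_class")


@dataclass
class EnrichmentResult:
    """One-sided binomial test of a feature class against the genome."""

    feature_class: str
    observed: int
    total: int
    observed_fraction: float
    background_fraction: float
    direction: str  # "enriched" or "depleted"
    p_value: float


def feature_enrichment(
    element_classes: pd.Series,
    background_fractions: dict[str, float],
) -> list[EnrichmentResult]:
    """Exact one-sided binomial enrichment per feature class.

    ``element_classes`` holds the class of each element probe (from
    :func:`classify_probes`); ``background_fractions`` the genome-wide
    fraction of probes in each class.  The tail is chosen by the sign of
    observed minus expected: upper tail P(X >= k) for enrichment, lower
    tail P(X <= k) for depletion.
    """
    n = len(element_classes)
    if n == 0:
        raise ValueError("no element probes supplied")
    results = []
    for cls, bg in background_fractions.items():
        if not (0 < bg < 1):
            raise ValueError(f"degenerate background fraction for {cls!r}: {bg}")
        k = int((element_classes == cls).sum())
        if k / n >= bg:
            direction = "enriched"
            p = float(stats.binom.sf(k - 1, n, bg))  # P(X >= k)
        else:
            direction = "depleted"
            p = float(stats.binom.cdf(k, n, bg))  # P(X <= k)
        results.append(
            EnrichmentResult(cls, k, n, k / n, bg, direction, min(p, 1.0))
        )
    return results


def background_fractions(
    track: ProbeTrack, genes: list[GeneModel], promoter_bp: int = 3000
) -> dict[str, float]:
    """Genome background: fraction of all probes in each feature class."""
    classes = classify_probes(track, genes, promoter_bp)
    return {
        cls: float((classes == cls).mean())
        for cls in ("promoter", "exon", "intron")
    }


def compare_gene_sets(
    values_a: np.ndarray,
    values_b: np.ndarray,
    alternative: str = "two-sided",
    exact_max_n: int = 16,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two sets of per-gene scores.

    Returns (statistic, p).  The statistic is the Mann-Whitney U of the
    first sample.  Small problems (combined n <= ``exact_max_n``) are
    solved by full enumeration of label assignments, which is exact even
    under ties; otherwise ties permitting, SciPy's exact method is used
    below 20 per group, and the tie-corrected normal approximation above.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene sets must be non-empty")
    if len(a) + len(b) <= exact_max_n:
        return _rank_sum_enumeration(a, b, alternative)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not has_ties and min(len(a), len(b)) < 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _rank_sum_enumeration(
    a: np.ndarray, b: np.ndarray, alternative: str
) -> tuple[float, float]:
    """Exact permutation distribution of the rank-sum by enumeration."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    observed = float(ranks[:n_a].sum())
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    )
    eps = 1e-9
    p_less = float(np.mean(sums <= observed + eps))
    p_greater = float(np.mean(sums >= observed - eps))
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_less, p_greater))
    else:
        raise ValueError("alternative must be 'less', 'greater' or 'two-sided'")
    u_stat = observed - n_a * (n_a + 1) / 2  # Mann-Whitney U of the first sample
    return u_stat, p


def track_correlation(
    a: ProbeTrack, b: ProbeTrack, bin_bp: int | None = None
) -> float:
    """Pearson correlation between two tracks, optionally pre-binned."""
    a.require_same_probes(b)
    if bin_bp is not None:
        from nedomains.normalize import bin_average

        xa = bin_average(a, bin_bp)["score"].to_numpy()
        xb = bin_average(b, bin_bp)["score"].to_numpy()
    else:
        xa, xb = a.values(), b.values()
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(xa, xb)[0, 1])
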