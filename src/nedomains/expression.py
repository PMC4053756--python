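"""Locus expression and SAM-style differential-expression selection.

Expression of a locus is the median of its per-exon values, each exon
value being the median per-base coverage over the exon; sample columns
are quantile-normalized before testing.  Differential loci between two
genotype groups are selected with a significance-analysis-of-microarrays
(SAM) procedure: a moderated t-like statistic d with a fudge factor s0,
compared against permutation-expected order statistics, thresholded at a
deviation Delta (default 4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nedomains.normalize import quantile_normalize


@dataclass
class ExpressionMatrix:
    """Locus-by-sample expression with genotype group labels."""

    values: pd.DataFrame  # loci x samples
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def quantile_normalized(self) -> "ExpressionMatrix":
        mat = quantile_normalize(self.values.to_numpy())
        return ExpressionMatrix(
            pd.DataFrame(mat, index=self.values.index, columns=self.values.columns),
            self.groups,
        )


@dataclass
class SamParams:
    """SAM tuning: fudge-factor rule, permutations, Delta threshold.

    s0 is picked among percentiles of the per-locus standard errors
    {s_i}; ``delta`` is the minimum deviation of an ordered d statistic
    from its permutation-expected value for a locus to seed a cutoff.
    """

    delta: float = 4.0
    #: "percentile": s0 is the ``s0_percentile`` quantile of {s_i} (the
    #: original SAM choice).  "auto": the percentile minimizing the CV of
    #: windowed MADs of d across s-quantile bins; suited to raw-intensity
    #: data whose error scale varies with s, but degenerate on
    #: quantile-normalized log coverage where {s_i} is nearly flat.
    s0_rule: str = "percentile"
    s0_percentile: float = 5.0
    s0_percentiles: tuple[float, ...] = field(
        default_factory=lambda: tuple(range(0, 101, 5))
    )
    max_permutations: int = 500
    seed: int = 0
    #: compute d on log2(x + 1).  Coverage noise is multiplicative, so the
    #: log scale makes the per-locus scatter independent of expression
    #: level, which the fudge-factor rule assumes.
    log2_transform: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.max_permutations < 1:
            raise ValueError("need at least one permutation")


def exon_expression(coverage: np.ndarray, exon: tuple[int, int]) -> float:
    """Median per-base coverage within one exon.

    ``coverage`` holds per-base values over the exon span [start, end).
    """
    start, end = exon
    if end <= start:
        raise ValueError("exon has zero or negative length")
    cov = np.asarray(coverage, float)
    if len(cov) != end - start:
        raise ValueError("coverage vector does not match exon length")
    return float(np.median(cov))


def locus_expression(
    exon_values: pd.Series | dict[str, float], exon_to_locus: dict[str, str]
) -> pd.Series:
    """Per-locus median of its exons' expression values."""
    values = pd.Series(exon_values, dtype=float)
    loci = values.index.map(lambda e: exon_to_locus[e])
    return values.groupby(loci).median().rename("expression")


def locus_matrix_from_exons(
    exon_table: pd.DataFrame,
    exon_to_locus: dict[str, str],
    groups: dict[str, str],
) -> ExpressionMatrix:
    """Exon coverage table -> normalized locus expression matrix.

    Quantile normalization is applied at the exon level across samples,
    and locus expression is then the median over the locus's exons.  The
    exon-level order matters: the median across exons is robust to the
    rank-tail distortion quantile normalization can introduce in single
    exon values.
    """
    qn = quantile_normalize(exon_table.to_numpy(dtype=float))
    normalized = pd.DataFrame(qn, index=exon_table.index, columns=exon_table.columns)
    loci = normalized.index.map(lambda e: exon_to_locus[e])
    values = normalized.groupby(loci).median()
    return ExpressionMatrix(values, groups)


def _d_statistic(
    mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated difference statistic d_i and its pooled standard error s_i."""
    a = mat[:, idx_a]
    b = mat[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (na + nb - 2)
    s = np.sqrt(pooled_var * (1 / na + 1 / nb))
    d = (mean_b - mean_a) / (s + s0)
    return d, s


def _choose_s0(mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, params: SamParams) -> float:
    """Fudge factor by the classic SAM rule.

    For each candidate percentile of the per-locus standard errors {s_i},
    loci are windowed into ~100 quantile bins of s_i; within each window
    the spread of d is summarized by its MAD; the candidate minimizing
    the coefficient of variation of these window spreads is chosen, i.e.
    s0 makes the spread of d independent of s.  Scale-based by
    construction, so d is invariant under adding a constant to all
    samples of a locus.
    """
    _, s = _d_statistic(mat, idx_a, idx_b, 0.0)
    if params.s0_rule == "percentile":
        return float(np.percentile(s, params.s0_percentile))
    if params.s0_rule != "auto":
        raise ValueError("s0_rule must be 'percentile' or 'auto'")
    n = len(s)
    n_windows = min(100, max(2, n // 10))
    order = np.argsort(s, kind="mergesort")
    windows = np.array_split(order, n_windows)
    candidates = np.unique(np.percentile(s, params.s0_percentiles))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d, _ = _d_statistic(mat, idx_a, idx_b, float(s0))
        spreads = np.array(
            [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64 for w in windows]
        )
        mean = spreads.mean()
        if mean == 0:
            continue
        cv = spreads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(
    idx_a: np.ndarray, idx_b: np.ndarray, params: SamParams
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All distinct relabelings of samples into two groups of the original sizes.

    With the small replicate counts typical of this design the full set is
    enumerated, removing Monte-Carlo noise; above ``max_permutations`` a
    seeded random subset is drawn.
    """
    pool = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)
    combos = list(itertools.combinations(range(len(pool)), n_a))
    if len(combos) > params.max_permutations:
        rng = np.random.default_rng(params.seed)
        chosen = rng.choice(len(combos), size=params.max_permutations, replace=False)
        combos = [combos[i] for i in chosen]
    perms = []
    for combo in combos:
        mask = np.zeros(len(pool), dtype=bool)
        mask[list(combo)] = True
        perms.append((pool[mask], pool[~mask]))
    return perms


@dataclass
class SamResult:
    """Per-locus d and Delta values plus the significant set."""

    table: pd.DataFrame  # locus, d, s, expected_d, delta_dev, significant
    s0: float
    cut_up: float | None
    cut_low: float | None
    n_permutations: int

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def sam_select(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    params: SamParams | None = None,
) -> SamResult:
    """SAM selection of loci differing between two genotype groups.

    d_i = (mean_b - mean_a) / (s_i + s0) with s_i the pooled standard
    error; expected order statistics come from label permutations; the
    deviation of the ordered d from its expectation defines Delta.  The
    cutoffs follow the SAM rule: the least extreme ordered d whose
    deviation exceeds ``params.delta`` on each side sets a cut value, and
    every locus beyond a cut is significant.

    The matrix should already be quantile-normalized across samples
    (see :meth:`ExpressionMatrix.quantile_normalized`).
    """
    params = params or SamParams()
    idx_a = np.array([matrix.values.columns.get_loc(s) for s in matrix.samples_in(group_a)])
    idx_b = np.array([matrix.values.columns.get_loc(s) for s in matrix.samples_in(group_b)])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    mat = matrix.values.to_numpy(dtype=float)
    if params.log2_transform:
        mat = np.log2(mat + 1.0)
    s0 = _choose_s0(mat, idx_a, idx_b, params)
    d, s = _d_statistic(mat, idx_a, idx_b, s0)

    order = np.argsort(d)
    d_sorted = d[order]
    perms = _label_permutations(idx_a, idx_b, params)
    expected = np.zeros(len(d))
    for pa, pb in perms:
        dp, _ = _d_statistic(mat, pa, pb, s0)
        expected += np.sort(dp)
    expected /= len(perms)

    dev = d_sorted - expected
    # SAM cutoffs: least extreme ordered d exceeding delta on each side
    cut_up: float | None = None
    up = np.flatnonzero((dev >= params.delta) & (d_sorted > 0))
    if len(up):
        cut_up = float(d_sorted[up[0]])
    cut_low: float | None = None
    low = np.flatnonzero((dev <= -params.delta) & (d_sorted < 0))
    if len(low):
        cut_low = float(d_sorted[low[-1]])
    significant_sorted = np.zeros(len(d), dtype=bool)
    if cut_up is not None:
        significant_sorted |= d_sorted >= cut_up
    if cut_low is not None:
        significant_sorted |= d_sorted <= cut_low

    table = pd.DataFrame(
        {
            "d": d_sorted,
            "s": s[order],
            "expected_d": expected,
            "delta_dev": dev,
            "significant": significant_sorted,
        },
        index=matrix.values.index[order],
    )
    table = table.loc[matrix.values.index]  # restore input locus order
    return SamResult(table, s0, cut_up, cut_low, len(perms))


def fold_change_table(
    matrix: ExpressionMatrix,
    loci: list[str],
    group_wt: str,
    group_mut: str,
) -> pd.DataFrame:
    """Mutant-over-wild-type fold change with min/max over replicate pairings.

    The point estimate is the ratio of group means; the min and max over
    all per-replicate-pair ratios bound the spread.  Loci whose wild-type
    mean is zero are flagged undefined (NaN fold change).
    """
    if not loci:
        raise ValueError("locus set must be non-empty")
    wt_cols = matrix.samples_in(group_wt)
    mut_cols = matrix.samples_in(group_mut)
    rows = []
    for locus in loci:
        wt = matrix.values.loc[locus, wt_cols].to_numpy(dtype=float)
        mut = matrix.values.loc[locus, mut_cols].to_numpy(dtype=float)
        if wt.mean() == 0:
            rows.append((locus, np.nan, np.nan, np.nan, False))
            continue
        fold = mut.mean() / wt.mean()
        pair_ratios = [m / w for m in mut for w in wt if w > 0]
        rows.append(
            (
                locus,
                float(fold),
                float(min(pair_ratios)) if pair_ratios else np.nan,
                float(max(pair_ratios)) if pair_ratios else np.nan,
                True,
            )
        )
    return pd.DataFrame(
        rows, columns=["locus", "fold_change", "fold_min", "fold_max", "defined"]
    ).set_index("locus")
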