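"""Probe-level normalization of DamID log-ratio tracks.

Raw tracks hold per-probe log2 ratios of the tethered Dam fusion over a
freely diffusing Dam control.  The chain applied here mirrors standard
tiling-array practice for this assay:

1. :func:`gc_normalize` — robust standardization of probes within GC
   strata, removing GC-dependent hybridization bias.
2. :func:`median_smooth` — running median over a genomic window
   (default 300 bp) to suppress single-probe noise.
3. :func:`quantile_normalize` — forces all replicate/background score
   vectors onto a common distribution so strains are comparable.
4. :func:`average_replicates` — arithmetic mean over biological
   replicates, with pairwise Pearson correlations reported for QC.
5. :func:`bin_average` — non-overlapping fixed-width bins (default
   100 kb) for chromosome-scale visualization.

The standardized, smoothed value attached to each probe is the score
used by every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nedomains.tracks import ProbeTrack, TrackShapeError

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD an unbiased scale estimate for
#: Gaussian data (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826


@dataclass
class NormalizationParams:
    """Tuning knobs of the probe-normalization chain.

    gc_bin_width
        Width of GC-count strata (GC-count units, default 1: one stratum
        per distinct GC count).
    min_probes_per_bin
        Strata smaller than this are merged with the nearest stratum
        before location/scale estimation.
    smooth_window_bp
        Full width of the running-median window in bp.
    robust_scale_constant
        Multiplier applied to the MAD when standardizing.
    """

    gc_bin_width: int = 1
    min_probes_per_bin: int = 10
    smooth_window_bp: int = 300
    robust_scale_constant: float = MAD_SCALE

    def __post_init__(self) -> None:
        if self.smooth_window_bp <= 0:
            raise ValueError("smoothing window must be positive")
        if self.min_probes_per_bin < 2:
            raise ValueError("need at least 2 probes per GC bin")
        if self.gc_bin_width < 1:
            raise ValueError("GC bin width must be >= 1")


def _gc_bin_assignment(gc: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Assign each probe a GC stratum id, merging sparse strata.

    Strata are contiguous in GC; a stratum with fewer than
    ``min_probes_per_bin`` members is merged with its nearest (by GC)
    non-empty neighbor, iterating until all strata are large enough or
    only one remains.
    """
    bins = gc // params.gc_bin_width
    uniq = np.unique(bins)
    # map bin id -> representative GC level for nearest-neighbor merging
    mapping = {int(b): int(b) for b in uniq}
    counts = {int(b): int(np.sum(bins == b)) for b in uniq}
    levels = sorted(counts)
    merged = True
    while merged and len(levels) > 1:
        merged = False
        for b in list(levels):
            if counts[b] < params.min_probes_per_bin:
                others = [x for x in levels if x != b]
                nearest = min(others, key=lambda x: (abs(x - b), x))
                counts[nearest] += counts[b]
                del counts[b]
                for k, v in mapping.items():
                    if v == b:
                        mapping[k] = nearest
                levels = sorted(counts)
                merged = True
                break
    return np.array([mapping[int(b)] for b in bins])


def gc_normalize(raw: ProbeTrack, params: NormalizationParams | None = None) -> ProbeTrack:
    """Standardize scores within GC strata: (x - median) / (c * MAD).

    Each replicate column is standardized independently.  A stratum with
    zero MAD (constant scores) falls back to a divisor of 1 so that its
    output is exactly the centered values (all zero when constant).
    """
    params = params or NormalizationParams()
    gc = raw.probes["gc_count"].to_numpy()
    assignment = _gc_bin_assignment(gc, params)
    out = np.empty_like(raw.scores)
    for b in np.unique(assignment):
        rows = assignment == b
        block = raw.scores[rows]
        med = np.median(block, axis=0)
        mad = np.median(np.abs(block - med), axis=0)
        scale = params.robust_scale_constant * mad
        degenerate = scale == 0
        if np.any(degenerate):
            logger.warning(
                "GC stratum %s has zero MAD in %d replicate(s); scale guard applied",
                b,
                int(degenerate.sum()),
            )
            scale = np.where(degenerate, 1.0, scale)
        out[rows] = (block - med) / scale
    return raw.with_scores(out)


def median_smooth(track: ProbeTrack, window_bp: int = 300) -> ProbeTrack:
    """Running median over probes within +/- window_bp/2 of each probe start.

    The window is centered on the probe start and always includes the
    probe itself; an isolated probe is returned unchanged.  Windows never
    reach across chromosomes.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if track.n_probes == 0:
        return track
    half = window_bp / 2.0
    out = np.empty_like(track.scores)
    for _, sl in track.chrom_slices():
        starts = track.probes["start"].to_numpy()[sl].astype(float)
        block = track.scores[sl]
        lo = np.searchsorted(starts, starts - half, side="left")
        hi = np.searchsorted(starts, starts + half, side="right")
        for i in range(len(starts)):
            out[sl][i] = np.median(block[lo[i] : hi[i]], axis=0)
    return track.with_scores(out)


def quantile_normalize(vectors: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Map each column onto the mean of across-column order statistics.

    Parameters
    ----------
    vectors
        Array of shape (n, k) or list of k equal-length vectors.

    Returns
    -------
    Array (n, k): column j holds the reference distribution (mean of the
    k sorted columns) reassigned according to column j's ranks.  Tied
    values receive the mean of the reference values over their shared
    rank span, so ties remain ties.
    """
    mat = np.column_stack(vectors) if isinstance(vectors, list) else np.asarray(vectors, float)
    if mat.ndim != 2:
        raise TrackShapeError("expected a 2-D matrix of score vectors")
    if mat.shape[1] < 2:
        raise TrackShapeError("quantile normalization needs >= 2 vectors")
    n = mat.shape[0]
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        # average reference over spans of tied input values
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[i : k + 1] = ranked[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    return out


def average_replicates(track: ProbeTrack) -> ProbeTrack:
    """Per-probe mean across replicate columns.

    Pairwise replicate Pearson correlations are computed and logged as a
    QC readout; they are also stored under ``track.sample`` metadata by
    the pipeline driver.
    """
    if track.n_replicates == 1:
        return track
    corr = replicate_correlations(track)
    pairs = [
        f"r({i},{j})={corr[i, j]:.3f}"
        for i in range(track.n_replicates)
        for j in range(i + 1, track.n_replicates)
    ]
    logger.info("replicate correlations %s: %s", track.sample, ", ".join(pairs))
    return track.with_scores(track.scores.mean(axis=1))


def replicate_correlations(track: ProbeTrack) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the replicate columns.

    A zero-variance replicate yields NaN entries rather than an error.
    """
    with np.errstate(invalid="ignore"):
        return np.corrcoef(track.scores, rowvar=False)


def bin_average(track: ProbeTrack, bin_bp: int = 100_000) -> pd.DataFrame:
    """Mean score in non-overlapping fixed-width bins, keyed by probe start.

    Returns a DataFrame (chrom, start, end, score, n_probes); genomic
    stretches without probes produce no row (missing bins are simply
    absent).
    """
    if bin_bp <= 0:
        raise ValueError("bin width must be positive")
    values = track.values()
    rows = []
    for chrom, sl in track.chrom_slices():
        starts = track.probes["start"].to_numpy()[sl]
        bins = starts // bin_bp
        for b in np.unique(bins):
            mask = bins == b
            rows.append(
                (
                    chrom,
                    int(b) * bin_bp,
                    (int(b) + 1) * bin_bp,
                    float(values[sl][mask].mean()),
                    int(mask.sum()),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_probes"])


def normalize_track(
    raw: ProbeTrack, params: NormalizationParams | None = None
) -> ProbeTrack:
    """GC-standardize then median-smooth each replicate of a raw track."""
    params = params or NormalizationParams()
    return median_smooth(gc_normalize(raw, params), params.smooth_window_bp)
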