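"""Sliding-window calling of nuclear-envelope-associated domains.

Scores are binarized to their sign, averaged in overlapping fixed-size
probe windows (default 200 probes, one-probe offset), and windows whose
mean binary value reaches a threshold are joined into domains.  The
threshold is calibrated so that the empirical false discovery rate —
estimated from the identical procedure run on a control self-comparison
track (untethered Dam over itself) — stays below a ceiling (default 5%).

With 50-bp probe spacing a 200-probe window spans roughly 10 kb, so a
called domain marks at least ~10 kb of continuously associated DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nedomains.tracks import DomainSet, ProbeTrack, merge_intervals


@dataclass
class DomainCallingParams:
    """Window geometry and FDR calibration settings.

    window
        Window size in probes.
    offset
        Slide in probes between consecutive windows.
    theta
        Default binary-window threshold; kept when it satisfies the FDR
        ceiling, otherwise recalibrated.
    fdr_ceiling
        Upper bound on the empirical FDR at the selected threshold.
    theta_grid
        Candidate thresholds scanned during calibration.
    """

    window: int = 200
    offset: int = 1
    theta: float = 0.8
    fdr_ceiling: float = 0.05
    theta_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    )

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must span at least 2 probes")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        if not (0 < self.fdr_ceiling < 1):
            raise ValueError("FDR ceiling must be in (0, 1)")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")


def binarize(track: ProbeTrack) -> np.ndarray:
    """Sign vector of the (replicate-averaged) scores: > 0 -> +1, <= 0 -> -1.

    An exact zero counts as non-associated; this conservative convention
    avoids inflating domains with probes carrying no evidence either way.
    """
    values = track.values()
    return np.where(values > 0, 1, -1).astype(np.int8)


@dataclass
class WindowScores:
    """Per-window mean binary values, anchored at each window's first probe."""

    chrom: np.ndarray  # chromosome per window
    first_probe: np.ndarray  # index of the window's first probe (track row)
    value: np.ndarray  # mean of the window's signs, in [-1, 1]

    def __len__(self) -> int:
        return len(self.value)


def window_scores(
    track: ProbeTrack, signs: np.ndarray, params: DomainCallingParams
) -> WindowScores:
    """Mean binary value of every w-probe window, sliding ``offset`` probes.

    Windows never span chromosome boundaries; a chromosome with fewer
    probes than the window size contributes no windows.
    """
    w = params.window
    chroms: list[np.ndarray] = []
    firsts: list[np.ndarray] = []
    values: list[np.ndarray] = []
    for chrom, sl in track.chrom_slices():
        s = signs[sl].astype(float)
        n = len(s)
        if n < w:
            continue
        csum = np.concatenate(([0.0], np.cumsum(s)))
        means = (csum[w:] - csum[:-w]) / w  # n - w + 1 windows at offset 1
        idx = np.arange(0, n - w + 1, params.offset)
        chroms.append(np.full(len(idx), chrom, dtype=object))
        firsts.append(idx + sl.start)
        values.append(means[idx])
    if not values:
        empty = np.empty(0)
        return WindowScores(np.empty(0, dtype=object), empty.astype(int), empty)
    return WindowScores(
        np.concatenate(chroms), np.concatenate(firsts), np.concatenate(values)
    )


@dataclass
class FdrTable:
    """FDR as a function of the binary-window threshold."""

    table: pd.DataFrame  # theta, signal_frac, null_frac, fdr
    selected_theta: float
    default_theta_ok: bool  # True when the default threshold meets the ceiling


def calibrate_fdr(
    signal_windows: WindowScores,
    null_windows: WindowScores,
    params: DomainCallingParams,
) -> FdrTable:
    """Empirical-null FDR curve and threshold selection.

    FDR(theta) = fraction of null windows >= theta over fraction of signal
    windows >= theta, capped at 1.  The null windows must come from a
    control self-comparison track processed by the identical pipeline.
    The selected threshold is the smallest grid value whose FDR is below
    the ceiling (maximizing sensitivity subject to the bound); thresholds
    where no signal window qualifies leave the FDR undefined and are
    excluded.  When the default threshold itself satisfies the ceiling it
    is reported and preferred.
    """
    n_sig = len(signal_windows)
    n_null = len(null_windows)
    if n_sig == 0 or n_null == 0:
        raise ValueError("both signal and null windows are required")
    rows = []
    for theta in params.theta_grid:
        sig_frac = float(np.mean(signal_windows.value >= theta))
        null_frac = float(np.mean(null_windows.value >= theta))
        fdr = min(null_frac / sig_frac, 1.0) if sig_frac > 0 else np.nan
        rows.append((theta, sig_frac, null_frac, fdr))
    table = pd.DataFrame(rows, columns=["theta", "signal_frac", "null_frac", "fdr"])
    ok = table[(table["fdr"] < params.fdr_ceiling) & table["fdr"].notna()]
    default_ok = False
    default_rows = table[np.isclose(table["theta"], params.theta)]
    if len(default_rows) and np.isfinite(default_rows["fdr"].iloc[0]):
        default_ok = bool(default_rows["fdr"].iloc[0] < params.fdr_ceiling)
    if len(ok) == 0:
        raise ValueError(
            "no threshold on the grid achieves the requested FDR ceiling"
        )
    selected = float(params.theta) if default_ok else float(ok["theta"].iloc[0])
    return FdrTable(table=table, selected_theta=selected, default_theta_ok=default_ok)


def call_domains(
    track: ProbeTrack,
    windows: WindowScores,
    params: DomainCallingParams,
    theta: float | None = None,
    label: str = "domain",
) -> DomainSet:
    """Join positive windows (value >= theta) into disjoint domains.

    Each positive window is converted to the genomic span from its first
    probe's start to its last probe's end; spans sharing >= 1 bp are
    merged.  An empty result is legitimate.
    """
    theta = params.theta if theta is None else theta
    positive = windows.value >= theta
    starts_all = track.probes["start"].to_numpy()
    ends_all = track.probes["end"].to_numpy()
    first = windows.first_probe[positive]
    if len(first) == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_probes", "score"])
        return DomainSet(label, empty, _param_dict(params, theta))
    spans = pd.DataFrame(
        {
            "chrom": windows.chrom[positive],
            "start": starts_all[first],
            "end": ends_all[first + params.window - 1],
        }
    )
    merged = merge_intervals(spans)
    merged["n_probes"] = _probes_per_interval(track, merged)
    merged["score"] = _mean_window_value(track, windows, merged, positive)
    return DomainSet(label, merged, _param_dict(params, theta))


def _param_dict(params: DomainCallingParams, theta: float) -> dict:
    return {
        "window": params.window,
        "offset": params.offset,
        "theta": float(theta),
        "fdr_ceiling": params.fdr_ceiling,
    }


def _probes_per_interval(track: ProbeTrack, intervals: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(intervals), dtype=int)
    by_chrom = {c: sl for c, sl in track.chrom_slices()}
    starts = track.probes["start"].to_numpy()
    for i, (chrom, start, end) in enumerate(
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        sl = by_chrom.get(chrom)
        if sl is None:
            continue
        s = starts[sl]
        counts[i] = int(np.searchsorted(s, end, "left") - np.searchsorted(s, start, "left"))
    return counts


def _mean_window_value(
    track: ProbeTrack,
    windows: WindowScores,
    intervals: pd.DataFrame,
    positive: np.ndarray,
) -> np.ndarray:
    """Mean value of the positive windows whose spans seeded each merged domain.

    A positive window belongs to the (unique) merged interval containing
    its first probe's start, since merged intervals are disjoint unions of
    the contributing window spans.
    """
    starts_all = track.probes["start"].to_numpy()
    pos_chrom = windows.chrom[positive]
    pos_val = windows.value[positive]
    pos_start = starts_all[windows.first_probe[positive]]
    out = np.zeros(len(intervals))
    for i, (chrom, start, end) in enumerate(
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        mask = (pos_chrom == chrom) & (pos_start >= start) & (pos_start < end)
        if np.any(mask):
            out[i] = float(pos_val[mask].mean())
    return out


def gaps_and_stats(
    domains: DomainSet, chrom_lengths: dict[str, int]
) -> tuple[pd.DataFrame, dict]:
    """Gaps between consecutive domains plus size/coverage summaries.

    Chromosome termini are not gaps: only stretches strictly between two
    domains on the same chromosome qualify.  Coverage is domain bp over
    total genome bp.
    """
    iv = domains.intervals
    gap_rows = []
    for chrom in iv["chrom"].unique():
        sub = iv[iv["chrom"] == chrom]
        ends = sub["end"].to_numpy()[:-1]
        starts = sub["start"].to_numpy()[1:]
        for e, s in zip(ends, starts):
            if s > e:
                gap_rows.append((chrom, int(e), int(s)))
    gaps = pd.DataFrame(gap_rows, columns=["chrom", "start", "end"])
    genome_bp = sum(chrom_lengths.values())
    dom_sizes = domains.sizes()
    gap_sizes = (gaps["end"] - gaps["start"]).to_numpy() if len(gaps) else np.empty(0)
    summary = {
        "n_domains": len(domains),
        "n_gaps": len(gaps),
        "domain_bp": domains.total_bp(),
        "coverage_fraction": domains.total_bp() / genome_bp if genome_bp else np.nan,
        "domain_size_quartiles": (
            [float(q) for q in np.percentile(dom_sizes, [25, 50, 75])]
            if len(dom_sizes)
            else [np.nan] * 3
        ),
        "gap_size_quartiles": (
            [float(q) for q in np.percentile(gap_sizes, [25, 50, 75])]
            if len(gap_sizes)
            else [np.nan] * 3
        ),
        "median_domain_bp": float(np.median(dom_sizes)) if len(dom_sizes) else np.nan,
        "median_gap_bp": float(np.median(gap_sizes)) if len(gap_sizes) else np.nan,
    }
    return gaps, summary


def chromosome_occupancy(
    domains: DomainSet,
    chrom_lengths: dict[str, int],
    autosomes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Per-chromosome occupied fraction and its regression on chromosome size.

    The regression (fraction vs length) is fitted over autosomes only; the
    X chromosome's NE association follows a different spatial pattern, so
    it is reported but excluded from the fit.  Autosomes default to every
    chromosome whose name does not denote X.
    """
    iv = domains.intervals
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = iv[iv["chrom"] == chrom]
        occupied = int((sub["end"] - sub["start"]).sum()) if len(sub) else 0
        rows.append((chrom, length, occupied, occupied / length))
    frame = pd.DataFrame(rows, columns=["chrom", "length", "domain_bp", "fraction"])
    if autosomes is None:
        autosomes = [c for c in chrom_lengths if c.lstrip("chr").upper() != "X"]
    sub = frame[frame["chrom"].isin(autosomes)]
    if len(sub) < 2:
        return frame, None
    fit = stats.linregress(sub["length"], sub["fraction"])
    regression = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue),
        "n_chromosomes": int(len(sub)),
    }
    return frame, regression


def call_domains_pipeline(
    signal: ProbeTrack,
    null: ProbeTrack,
    params: DomainCallingParams | None = None,
    label: str = "domain",
) -> tuple[DomainSet, FdrTable]:
    """Binarize, window, calibrate against the control, and call domains."""
    params = params or DomainCallingParams()
    sig_windows = window_scores(signal, binarize(signal), params)
    null_windows = window_scores(null, binarize(null), params)
    fdr = calibrate_fdr(sig_windows, null_windows, params)
    domains = call_domains(signal, sig_windows, params, fdr.selected_theta, label)
    return domains, fdr
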