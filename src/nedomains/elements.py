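"""Factor-exclusive elements, difference tracks and detached regions.

An exclusive element ("A only") is a short region whose probes score
high for one nuclear-envelope factor while scoring negative for the
other: at least ``min_probes`` qualifying probes, consecutive qualifying
probes no more than ``max_separation_bp`` apart.  The same chaining
machinery, applied to a wild-type-minus-mutant difference track, yields
"detached regions" — loci whose envelope association is lost in a
mutant genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nedomains.tracks import ElementSet, ProbeTrack


@dataclass
class ElementParams:
    """Thresholds of the exclusive-element rule.

    own_min
        Minimum score on the factor's own track for a probe to qualify.
    other_max
        Qualifying probes must score strictly below this on the other
        factor's track (exclusive bound).
    min_probes
        Minimum number of qualifying probes per element.
    max_separation_bp
        Maximum start-to-start distance between consecutive qualifying
        probes within one element.
    """

    own_min: float = 1.0
    other_max: float = 0.0
    min_probes: int = 10
    max_separation_bp: int = 500

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.max_separation_bp <= 0:
            raise ValueError("max separation must be positive")


def _chain_probes(
    track: ProbeTrack, qualifying: np.ndarray, params: ElementParams, label: str
) -> ElementSet:
    """Maximal chains of qualifying probes under the spacing rule.

    Separation is measured start-to-start between consecutive qualifying
    probes (well defined even for overlapping probes); non-qualifying
    probes lying inside a chain do not break it — only excess spacing
    does.  Chains with fewer than ``min_probes`` members are dropped.
    """
    starts = track.probes["start"].to_numpy()
    ends = track.probes["end"].to_numpy()
    rows = []
    for chrom, sl in track.chrom_slices():
        q_idx = np.flatnonzero(qualifying[sl]) + sl.start
        if len(q_idx) == 0:
            continue
        q_starts = starts[q_idx]
        breaks = np.flatnonzero(np.diff(q_starts) > params.max_separation_bp) + 1
        for chunk in np.split(np.arange(len(q_idx)), breaks):
            if len(chunk) >= params.min_probes:
                first, last = q_idx[chunk[0]], q_idx[chunk[-1]]
                rows.append((chrom, int(starts[first]), int(ends[last]), len(chunk)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes"])
    return ElementSet(label, frame, vars(params).copy())


def call_exclusive_elements(
    track_own: ProbeTrack,
    track_other: ProbeTrack,
    params: ElementParams | None = None,
    label: str = "A-only",
) -> ElementSet:
    """Regions bound by one factor and shunned by the other.

    A probe qualifies when its own-factor score is >= ``own_min`` and its
    other-factor score is < ``other_max``; qualifying probes are chained
    by the spacing rule and chains meeting the probe-count minimum are
    emitted as elements spanning first probe start to last probe end.
    """
    params = params or ElementParams()
    track_own.require_same_probes(track_other)
    qualifying = (track_own.values() >= params.own_min) & (
        track_other.values() < params.other_max
    )
    return _chain_probes(track_own, qualifying, params, label)


def difference_track(track_a: ProbeTrack, track_b: ProbeTrack) -> ProbeTrack:
    """Per-probe a - b over an identical probe set."""
    track_a.require_same_probes(track_b)
    diff = track_a.values() - track_b.values()
    return track_a.with_scores(diff, sample=f"{track_a.sample}-{track_b.sample}")


def call_detached_regions(
    track_wt: ProbeTrack,
    track_mut: ProbeTrack,
    params: ElementParams | None = None,
    label: str = "detached",
) -> ElementSet:
    """Regions whose envelope association drops in a mutant genotype.

    The exclusive-element chaining rule is applied to the wild-type minus
    mutant difference track, with ``own_min`` acting as the detachment
    threshold and no condition on a second track.  Both inputs must have
    been normalized jointly for the difference to be meaningful.
    Swapping the arguments finds regions gained in the mutant instead.
    """
    params = params or ElementParams()
    diff = difference_track(track_wt, track_mut)
    qualifying = diff.values() >= params.own_min
    return _chain_probes(diff, qualifying, params, label)
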