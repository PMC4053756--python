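"""Shared fixtures: tiny probe tracks and a small simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nedomains.tracks import ProbeTrack
from nedomains import workflow_io as wio


def make_track(
    starts,
    scores,
    chrom: str = "chr1",
    probe_length: int = 50,
    gc=None,
    sample: str = "t",
) -> ProbeTrack:
    """Small single-chromosome track with given probe starts and scores."""
    starts = np.asarray(starts, dtype=int)
    gc = np.full(len(starts), 25) if gc is None else np.asarray(gc, dtype=int)
    probes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_length,
            "gc_count": gc,
        }
    )
    return ProbeTrack(probes, np.asarray(scores, dtype=float), sample=sample)


@pytest.fixture(scope="session")
def small_study():
    """One normalized synthetic study shared by read-only tests.

    Two chromosomes (2.0 and 1.5 Mb), noise sd 0.5, seed 7 — small enough
    to keep the suite fast, large enough to carry ~50 planted domains.
    """
    cfg = wio.RunConfig(
        seed=7,
        chrom_lengths={"chr1": 2_000_000, "chr2": 1_500_000},
        noise_sd=0.5,
        n_genes=200,
    )
    return wio.prepare_tracks(cfg), cfg
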