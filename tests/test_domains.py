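"""Domain caller: window arithmetic, FDR calibration and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nedomains import domains as dm
from nedomains.tracks import interval_jaccard
from tests.conftest import make_track


def brute_force_domains(track, window: int, theta: float) -> pd.DataFrame:
    """Independent reference caller: enumerate every window, merge pairwise.

    Walks each chromosome probe by probe, scores each window by an
    explicit mean of signs, collects positive spans, and merges them by
    repeated pairwise union until a fixed point.
    """
    values = track.values()
    spans = []
    for chrom, sl in track.chrom_slices():
        starts = track.probes["start"].to_numpy()[sl]
        ends = track.probes["end"].to_numpy()[sl]
        signs = [1 if v > 0 else -1 for v in values[sl]]
        n = len(signs)
        for i in range(n - window + 1):
            mean = sum(signs[i : i + window]) / window
            if mean >= theta:
                spans.append([chrom, int(starts[i]), int(ends[i + window - 1])])
    changed = True
    while changed:
        changed = False
        out = []
        for span in sorted(spans):
            if out and out[-1][0] == span[0] and span[1] <= out[-1][2]:
                out[-1][2] = max(out[-1][2], span[2])
                changed = True
            else:
                out.append(list(span))
        spans = out
    return pd.DataFrame(spans, columns=["chrom", "start", "end"])


class TestBinarize:
    def test_signs_with_zero_negative(self):
        track = make_track([0, 50, 100], [0.5, -0.2, 0.0])
        np.testing.assert_array_equal(dm.binarize(track), [1, -1, -1])

    def test_all_positive(self):
        track = make_track([0, 50], [0.1, 2.0])
        np.testing.assert_array_equal(dm.binarize(track), [1, 1])

    def test_antisymmetry_away_from_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        scores[scores == 0] = 0.1
        a = dm.binarize(make_track(np.arange(50) * 50, scores))
        b = dm.binarize(make_track(np.arange(50) * 50, -scores))
        np.testing.assert_array_equal(a, -b)


class TestWindowScores:
    def test_uniform_positive_single_window(self):
        track = make_track(np.arange(200) * 50, np.ones(200))
        params = dm.DomainCallingParams(window=200)
        ws = dm.window_scores(track, dm.binarize(track), params)
        assert len(ws) == 1 and ws.value[0] == 1.0

    def test_partial_positive_fraction(self):
        scores = np.concatenate([np.ones(180), -np.ones(20)])
        track = make_track(np.arange(200) * 50, scores)
        ws = dm.window_scores(track, dm.binarize(track), dm.DomainCallingParams())
        assert ws.value[0] == pytest.approx((180 - 20) / 200)

    def test_window_count_closed_form(self):
        track = make_track(np.arange(250) * 50, np.ones(250))
        ws = dm.window_scores(track, dm.binarize(track), dm.DomainCallingParams())
        assert len(ws) == 51

    def test_short_chromosome_contributes_no_windows(self):
        track = make_track(np.arange(100) * 50, np.ones(100))
        ws = dm.window_scores(track, dm.binarize(track), dm.DomainCallingParams(window=200))
        assert len(ws) == 0


class TestCalibrateFdr:
    def test_fdr_definition(self):
        # signal positive fraction 0.5, null 0.02 at theta=0.8 -> FDR 0.04
        params = dm.DomainCallingParams(theta_grid=(0.8,))
        sig = dm.WindowScores(
            np.full(100, "chr1", dtype=object),
            np.arange(100),
            np.concatenate([np.full(50, 0.9), np.full(50, 0.0)]),
        )
        null = dm.WindowScores(
            np.full(100, "chr1", dtype=object),
            np.arange(100),
            np.concatenate([np.full(2, 0.9), np.full(98, 0.0)]),
        )
        table = dm.calibrate_fdr(sig, null, params)
        assert table.table["fdr"].iloc[0] == pytest.approx(0.04)
        assert table.selected_theta == 0.8

    def test_iid_null_matches_binomial_tail(self):
        """I.i.d. fair-coin signs essentially never reach theta=0.8.

        P(window mean >= 0.8) = P(X >= 180 | n=200, p=1/2) ~ 1e-33, so
        zero positives are expected among a million windows.
        """
        tail = stats.binom.sf(179, 200, 0.5)
        assert tail < 1e-30
        rng = np.random.default_rng(0)
        signs = rng.choice([-1, 1], size=1_000_199).astype(np.int8)
        track = make_track(np.arange(len(signs)) * 50, signs.astype(float))
        ws = dm.window_scores(track, signs, dm.DomainCallingParams())
        assert len(ws) == 1_000_000
        assert np.count_nonzero(ws.value >= 0.8) == 0

    def test_undefined_fdr_excluded(self):
        params = dm.DomainCallingParams(theta_grid=(0.5, 1.0), theta=0.5)
        sig = dm.WindowScores(
            np.full(10, "chr1", dtype=object), np.arange(10), np.full(10, 0.6)
        )
        null = dm.WindowScores(
            np.full(10, "chr1", dtype=object), np.arange(10), np.full(10, -1.0)
        )
        table = dm.calibrate_fdr(sig, null, params)
        # no signal window reaches 1.0 -> FDR undefined there
        assert np.isnan(table.table.set_index("theta").loc[1.0, "fdr"])
        assert table.selected_theta == 0.5


class TestCallDomains:
    def test_overlapping_windows_merge(self):
        scores = np.concatenate([np.ones(201), -np.ones(50)])
        track = make_track(np.arange(len(scores)) * 50, scores)
        params = dm.DomainCallingParams()
        ws = dm.window_scores(track, dm.binarize(track), params)
        domains = dm.call_domains(track, ws, params, theta=0.8)
        assert len(domains) == 1
        assert domains.intervals["start"].iloc[0] == 0

    def test_no_positive_windows_empty_set(self):
        track = make_track(np.arange(300) * 50, -np.ones(300))
        params = dm.DomainCallingParams()
        ws = dm.window_scores(track, dm.binarize(track), params)
        domains = dm.call_domains(track, ws, params, theta=0.8)
        assert len(domains) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 2000))
        scores = rng.normal(loc=rng.uniform(-0.5, 0.8), size=n)
        track = make_track(np.arange(n) * 50, scores)
        params = dm.DomainCallingParams(window=int(rng.integers(20, 100)))
        theta = float(rng.uniform(0.3, 0.9))
        ws = dm.window_scores(track, dm.binarize(track), params)
        ours = dm.call_domains(track, ws, params, theta=theta).intervals
        ref = brute_force_domains(track, params.window, theta)
        pd.testing.assert_frame_equal(
            ours[["chrom", "start", "end"]].reset_index(drop=True), ref, check_dtype=False
        )

    def test_theta_monotonicity(self):
        rng = np.random.default_rng(3)
        track = make_track(np.arange(3000) * 50, rng.normal(0.4, 1.0, size=3000))
        params = dm.DomainCallingParams(window=50)
        ws = dm.window_scores(track, dm.binarize(track), params)
        prev_bp = None
        for theta in (0.3, 0.5, 0.7, 0.9):
            bp = dm.call_domains(track, ws, params, theta=theta).total_bp()
            if prev_bp is not None:
                assert bp <= prev_bp
            prev_bp = bp


class TestGapsAndOccupancy:
    def test_gap_between_two_domains(self):
        domains = dm.DomainSet(
            "LAD",
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 20_000], "end": [10_000, 30_000]}
            ),
        )
        gaps, summary = dm.gaps_and_stats(domains, {"chr1": 40_000})
        assert len(gaps) == 1
        assert (gaps.iloc[0]["start"], gaps.iloc[0]["end"]) == (10_000, 20_000)
        assert summary["coverage_fraction"] == pytest.approx(0.5)
        assert summary["median_domain_bp"] == pytest.approx(10_000)

    def test_single_domain_no_gaps(self):
        domains = dm.DomainSet(
            "LAD", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        )
        gaps, _ = dm.gaps_and_stats(domains, {"chr1": 40_000})
        assert len(gaps) == 0

    def test_conservation_of_chromosome_length(self, small_study):
        """Domain bp + gap bp + terminal flanks tile each chromosome."""
        prep, cfg = small_study
        tracks = prep["tracks"]
        ds, _ = dm.call_domains_pipeline(
            tracks["A"], tracks["control"], dm.DomainCallingParams(), label="LAD"
        )
        gaps, _ = dm.gaps_and_stats(ds, cfg.chrom_lengths)
        for chrom, length in cfg.chrom_lengths.items():
            d = ds.intervals[ds.intervals["chrom"] == chrom]
            g = gaps[gaps["chrom"] == chrom]
            dom_bp = int((d["end"] - d["start"]).sum())
            gap_bp = int((g["end"] - g["start"]).sum())
            flank = int(d["start"].min()) + (length - int(d["end"].max()))
            assert dom_bp + gap_bp + flank == length

    def test_occupancy_fraction_arithmetic(self):
        domains = dm.DomainSet(
            "LAD",
            pd.DataFrame(
                {"chrom": ["chrI", "chrII"], "start": [0, 0], "end": [5_000_000, 1]}
            ),
        )
        frame, _ = dm.chromosome_occupancy(
            domains, {"chrI": 15_072_421, "chrII": 15_279_323}
        )
        assert frame.set_index("chrom").loc["chrI", "fraction"] == pytest.approx(
            0.33172, abs=1e-4
        )

    def test_linear_fractions_regress_perfectly(self):
        # occupied fraction exactly linear in length -> r = 1
        lengths = {"c1": 10_000_000, "c2": 12_000_000, "c3": 14_000_000}
        rows = []
        for chrom, length in lengths.items():
            frac = 0.1 + 0.02 * (length / 1e6)
            rows.append({"chrom": chrom, "start": 0, "end": int(frac * length)})
        domains = dm.DomainSet("LAD", pd.DataFrame(rows))
        _, regression = dm.chromosome_occupancy(domains, lengths)
        assert regression["pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_x_excluded_from_regression(self):
        lengths = {"c1": 10_000_000, "c2": 12_000_000, "chrX": 17_000_000}
        domains = dm.DomainSet(
            "LAD", pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [1_000_000]})
        )
        frame, regression = dm.chromosome_occupancy(domains, lengths)
        assert regression["n_chromosomes"] == 2
        assert "chrX" in set(frame["chrom"])

    def test_no_domains_zero_fractions(self):
        domains = dm.DomainSet(
            "LAD", pd.DataFrame(columns=["chrom", "start", "end"])
        )
        frame, _ = dm.chromosome_occupancy(domains, {"c1": 1_000, "c2": 2_000})
        assert (frame["fraction"] == 0).all()
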