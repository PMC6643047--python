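"""Measurement pipeline: encounters, arrest calls, curves, rates, folds."""

import math

import numpy as np
import pandas as pd
import pytest

from synprop.arena import build_spot_grid
from synprop.metrics import (
    AnalysisParams,
    ArrestCall,
    AttachmentCurve,
    analyze_tracks,
    arrest_efficiency,
    attachment_curve,
    bootstrap_fold,
    classify_arrests,
    decompose_on_rate,
    detect_encounters,
    encounter_rate,
    exclude_encounters_during_arrest,
    fold_change,
    initial_slope,
    on_rate,
    sp_fraction_uniform,
)
from synprop.simulate import MEMORY_CD8, CellPhenotype, SimConfig, Track, simulate_arena


def make_track(points, dt=0.5, cell_id=0, label="naive"):
    pts = np.asarray(points, dtype=float)
    return Track(cell_id=cell_id, label=label,
                 t=np.arange(len(pts)) * dt, x=pts[:, 0], y=pts[:, 1])


@pytest.fixture(scope="module")
def grid():
    return build_spot_grid(50_625.0, 10.0, 30.0)  # centers at 5, 35, 65, ...


class TestDetectEncounters:
    def test_straight_crossing_single_event(self, grid):
        # crosses the spot centered at (35, 35) once, left to right
        xs = np.arange(20.0, 50.0, 1.0)
        track = make_track([(x, 35.0) for x in xs])
        enc = detect_encounters(track, grid)
        assert len(enc) == 1
        # brute-force first in-footprint frame
        inside = np.abs(xs - 35.0) <= 5.0
        assert enc.frame_entry.iloc[0] == inside.argmax()

    def test_track_outside_all_footprints(self, grid):
        track = make_track([(20.0, 20.0), (21.0, 20.0), (22.0, 20.0)])
        assert len(detect_encounters(track, grid)) == 0

    def test_reentry_after_gap_counts_twice(self, grid):
        # 12-frame hand-built path: in spot (35,35), out for 3 frames, back in
        pts = [(35, 35), (36, 35), (37, 35), (45, 35), (46, 35), (47, 35),
               (45, 35), (36, 35), (35, 35), (34, 35), (35, 35), (35, 36)]
        enc = detect_encounters(make_track(pts), grid)
        assert len(enc) == 2
        assert list(enc.frame_entry) == [0, 7]

    def test_short_track_warns_and_returns_empty(self, grid):
        track = make_track([(20.0, 20.0)])
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert len(detect_encounters(track, grid)) == 0


class TestClassifyArrests:
    def test_stationary_cell_inside_spot(self, grid):
        pts = [(35.0, 35.0)] * 40
        calls = classify_arrests(make_track(pts), grid)
        assert len(calls) == 1
        assert calls[0].onset == 0.0
        assert calls[0].end is None  # never leaves

    def test_fast_traversal_not_called(self, grid):
        xs = np.arange(20.0, 60.0, 6.0)  # 12 um/min at dt 0.5
        calls = classify_arrests(make_track([(x, 35.0) for x in xs]), grid)
        assert calls == []

    def test_window_smaller_than_two_frames_rejected(self, grid):
        track = make_track([(35.0, 35.0)] * 20)
        with pytest.raises(ValueError, match="window"):
            classify_arrests(track, grid, window=0.5)

    def test_synthetic_arrest_recovered_within_one_frame(self):
        g = build_spot_grid(50_625.0, 10.0, 30.0, capacity=50)
        phen = CellPhenotype(label="m", speed_mean=16.0, arrest_prob=1.0,
                             dwell_half_life=math.inf)
        tracks, log = simulate_arena(g, [phen], SimConfig(duration=30.0, n_cells=40, seed=4))
        gt = {r.cell_id: r.time_min for r in log.arrests.itertuples()}
        for tr in tracks:
            calls = classify_arrests(tr, g)
            if tr.cell_id in gt:
                assert len(calls) == 1
                assert abs(calls[0].onset - gt[tr.cell_id]) <= tr.dt
            else:
                assert calls == []


def test_pipeline_matches_ground_truth_events(memory_run):
    """Arrest calls vs generator log: >= 95% sensitivity and precision."""
    g, cfg, tracks, log = memory_run
    calls = []
    for tr in tracks:
        if len(tr) >= 2:
            calls.extend(classify_arrests(tr, g))
    callset = {(c.cell_id, c.spot_id, round(c.onset, 6)) for c in calls}
    gt = list(log.arrests.itertuples())
    releases = {}
    for r in log.releases.itertuples():
        releases.setdefault((r.cell_id, r.spot_id), []).append(r.time_min)
    detectable = hits = 0
    for a in gt:
        later = [t for t in releases.get((a.cell_id, a.spot_id), []) if t > a.time_min]
        dwell = (min(later) if later else cfg.duration) - a.time_min
        if dwell < 5.0:  # below min_duration: undetectable by construction
            continue
        detectable += 1
        hits += (a.cell_id, a.spot_id, round(a.time_min, 6)) in callset
    gtset = {(a.cell_id, a.spot_id, round(a.time_min, 6)) for a in gt}
    precision = np.mean([
        (c.cell_id, c.spot_id, round(c.onset, 6)) in gtset for c in calls
    ])
    assert hits / detectable >= 0.95
    assert precision >= 0.95


class TestAttachmentCurveAndOnRate:
    def test_no_calls_flat_zero(self, grid):
        curve = attachment_curve([], np.arange(0, 10.5, 0.5))
        assert curve.counts.sum() == 0
        assert on_rate(curve, grid) == 0.0

    def test_step_counting(self, grid):
        calls = [ArrestCall(i, 0, t, None, 0.5) for i, t in enumerate([1.0, 5.0, 5.0])]
        curve = attachment_curve(calls, np.array([0.0, 1.0, 2.0, 5.0, 6.0]))
        assert list(curve.counts) == [0, 1, 1, 3, 3]

    def test_repeat_arrests_of_same_cell_counted_once(self, grid):
        calls = [ArrestCall(7, 0, 2.0, 10.0, 0.5), ArrestCall(7, 3, 20.0, None, 0.5)]
        curve = attachment_curve(calls, np.array([0.0, 5.0, 30.0]))
        assert list(curve.counts) == [0, 1, 1]

    def test_exact_linear_curve_recovers_slope(self, grid):
        t = np.arange(0, 30.5, 0.5)
        curve = AttachmentCurve(times=t, counts=0.4 * t)
        assert on_rate(curve, grid) == pytest.approx(0.4)

    def test_saturating_curve_initial_derivative(self, grid):
        """72 (1 - exp(-t/20)) has initial derivative 3.6; the windowed
        slope must land within 10% despite curvature."""
        t = np.arange(0, 90.5, 0.5)
        counts = 72.0 * (1 - np.exp(-t / 20.0))
        curve = AttachmentCurve(times=t, counts=counts)
        slope, w = initial_slope(curve, grid)
        assert w < 30.0  # capacity rule truncates (64 sites, 15% ~ 9.6 cells)
        assert abs(slope - 3.6) / 3.6 < 0.10

    def test_sparse_curve_widens_window_with_warning(self, grid):
        # only 3 points fall inside the 30-min cap; the rule widens to 5
        t = np.arange(0.0, 100.0, 12.0)
        curve = AttachmentCurve(times=t, counts=np.arange(len(t), dtype=float))
        with pytest.warns(UserWarning, match="widened"):
            slope, w = initial_slope(curve, grid)
        assert w == 60.0  # fifth positive time point

    def test_decreasing_curve_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            AttachmentCurve(times=np.array([0.0, 1.0]), counts=np.array([2.0, 1.0]))


def test_encounter_rate_arithmetic():
    enc = pd.DataFrame({"cell_id": range(90)})
    assert encounter_rate(enc, 90.0, 1) == 1.0
    assert encounter_rate(enc.iloc[:0], 90.0, 1) == 0.0
    with pytest.raises(ValueError):
        encounter_rate(enc, 0.0)


class TestArrestEfficiency:
    def _enc(self, n):
        return pd.DataFrame(
            {"cell_id": range(n), "spot_id": [0] * n,
             "t_entry": np.arange(n, dtype=float), "frame_entry": range(n),
             "t_exit": np.arange(n, dtype=float) + 1}
        )

    def test_one_in_ten(self):
        enc = self._enc(100)
        calls = [ArrestCall(i, 0, float(i), None, 0.5) for i in range(10)]
        assert arrest_efficiency(calls, enc) == pytest.approx(0.10)

    def test_no_arrests(self):
        assert arrest_efficiency([], self._enc(50)) == 0.0

    def test_zero_encounters_warns_nan(self):
        with pytest.warns(UserWarning, match="zero encounters"):
            assert math.isnan(arrest_efficiency([], self._enc(0)))

    def test_excludes_flicker_entries_during_arrest(self):
        enc = self._enc(3)  # entries at t = 0, 1, 2
        calls = [ArrestCall(1, 0, 1.0, 10.0, 0.5)]  # cell 1 arrested on [1, 10)
        enc.loc[2, "cell_id"] = 1
        enc.loc[2, "t_entry"] = 5.0  # flicker entry while arrested
        kept = exclude_encounters_during_arrest(enc, calls, movie_end=20.0)
        assert len(kept) == 2
        assert 5.0 not in kept.t_entry.values


def test_decompose_on_rate_arithmetic():
    assert decompose_on_rate(2.0, 0.4)[0] == pytest.approx(0.8)
    assert decompose_on_rate(3.0, 0.0)[0] == 0.0
    pred, res = decompose_on_rate(2.0, 0.4, measured_on_rate=1.0)
    assert res == pytest.approx(0.2)
    with pytest.raises(ValueError):
        decompose_on_rate(-1.0, 0.5)


def test_sp_fraction_uniform_counting():
    calls = [ArrestCall(i, -1, 1.0, None, 0.5) for i in range(12)]
    assert sp_fraction_uniform(calls, 30) == pytest.approx(0.4)
    assert sp_fraction_uniform([], 30) == 0.0
    with pytest.raises(ValueError):
        sp_fraction_uniform(calls, 0)


class TestFoldChange:
    def test_printed_ten_micron_fold(self):
        assert fold_change(0.71, 0.10) == pytest.approx(7.1)

    def test_identity(self):
        assert fold_change(1.234, 1.234) == pytest.approx(1.0)

    def test_zero_naive_warns_nan(self):
        with pytest.warns(UserWarning, match="zero"):
            assert math.isnan(fold_change(1.0, 0.0))

    def test_bootstrap_interval_covers_true_fold(self):
        """Coverage >= 90% over 50 seeded replicates of cell-level
        IS/IK indicators (memory p = 0.6, naive p = 0.3, true fold 2)."""
        rng = np.random.default_rng(99)
        covered = 0
        for rep in range(50):
            mem = rng.binomial(1, 0.6, size=200).astype(float)
            nai = rng.binomial(1, 0.3, size=200).astype(float)
            est = bootstrap_fold(mem, nai, n_boot=500, seed=rep)
            covered += est.ci_low <= 2.0 <= est.ci_high
        assert covered >= 45


def test_analyze_tracks_empty_input_warns():
    g = build_spot_grid(50_625.0, 10.0, 30.0)
    with pytest.warns(UserWarning, match="no tracks"):
        report = analyze_tracks([], g)
    assert report.phenotypes == {}


def test_report_serialization_round_trip(tmp_path, memory_run):
    import json

    g, _, tracks, _ = memory_run
    report = analyze_tracks(tracks[:80], g)
    path = tmp_path / "report.json"
    report.to_json(path)
    loaded = json.loads(path.read_text())
    assert "memory" in loaded["phenotypes"]
    assert loaded["phenotypes"]["memory"]["on_rate"] >= 0.0
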