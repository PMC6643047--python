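"""From track tables to synapse-propensity correlates.

The pipeline mirrors how spot-arrest assays are scored: detect encounters
(footprint entries), call arrests from sustained deceleration plus
confinement, build the per-field attachment curve, take its initial slope
as the on-rate of arrest, and decompose the on-rate bimolecularly as

    on_rate = encounter_rate x arrest_efficiency.

All per-field quantities are normalized to the reference imaging field of
50,625 um^2 so runs on larger (tiled) arenas remain comparable.

Encounter rate and arrest efficiency for the decomposition are estimated
inside the same initial pre-saturation window used for the on-rate slope:
the bimolecular identity holds instantaneously, so the three correlates
must be measured over a common early epoch for the self-consistency check
to be meaningful once spots fill or the free pool turns over.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from synprop.arena import SpotGrid, spots_containing_points
from synprop.simulate import Track

__all__ = [
    "ArrestCall",
    "AttachmentCurve",
    "AnalysisParams",
    "PhenotypeSP",
    "SPReport",
    "FoldEstimate",
    "REFERENCE_FIELD_AREA",
    "detect_encounters",
    "classify_arrests",
    "classify_arrests_uniform",
    "attachment_curve",
    "on_rate",
    "initial_slope",
    "encounter_rate",
    "arrest_efficiency",
    "fit_dwell_half_life",
    "censoring_corrected_efficiency",
    "exclude_encounters_during_arrest",
    "decompose_on_rate",
    "sp_fraction_uniform",
    "fold_change",
    "bootstrap_fold",
    "analyze_tracks",
]

#: Area of the reference imaging field, um^2 (the per-field unit).
REFERENCE_FIELD_AREA = 50_625.0

ENCOUNTER_COLUMNS = ["cell_id", "spot_id", "t_entry", "frame_entry", "t_exit"]


@dataclass(frozen=True)
class ArrestCall:
    """One called arrest: sustained deceleration confined to a footprint."""

    cell_id: int
    spot_id: int
    onset: float  # min
    end: float | None  # min; None = still arrested at movie end
    mean_speed: float  # um/min while arrested

    def duration(self, movie_end: float) -> float:
        return (self.end if self.end is not None else movie_end) - self.onset

    @property
    def censored(self) -> bool:
        return self.end is None


@dataclass
class AttachmentCurve:
    """Cumulative count of cells arresting over time, per reference field."""

    times: np.ndarray  # min
    counts: np.ndarray  # raw cumulative first arrests (whole arena)
    field_count: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("attachment curve must be non-decreasing")

    @property
    def per_field(self) -> np.ndarray:
        return self.counts / self.field_count


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the arrest caller and windowing rules.

    The arrest caller requires the rolling mean speed (over ``window`` min)
    to stay below ``speed_threshold`` while the centroid remains within the
    footprint (plus ``confine_margin`` to tolerate arrest-point jitter) for
    at least ``min_duration`` min.
    """

    speed_threshold: float = 2.0  # um/min
    window: float = 5.0  # min
    min_duration: float = 5.0  # min
    confine_margin: float = 1.5  # um
    encounter_margin: float = 0.0  # um
    slope_t_max: float = 30.0  # min, hard cap of the initial window
    slope_capacity_fraction: float = 0.15
    slope_min_points: int = 5


def detect_encounters(track: Track, grid: SpotGrid, margin: float = 0.0) -> pd.DataFrame:
    """Detect footprint entries of one track.

    One event per maximal run of consecutive in-footprint frames; a cell
    must spend at least one full frame outside a spot before re-entry of
    the same spot counts again. Moving directly into a different spot's
    footprint also opens a new event.
    """
    if len(track) < 2:
        warnings.warn(f"track {track.cell_id} has fewer than 2 frames; no encounters")
        return pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    sid = spots_containing_points(track.xy, grid, margin)
    prev = np.concatenate([[-1], sid[:-1]])
    entries = (sid >= 0) & (sid != prev)
    rows = []
    for e in entries.nonzero()[0]:
        s = sid[e]
        j = e
        while j + 1 < len(sid) and sid[j + 1] == s:
            j += 1
        rows.append(
            (track.cell_id, int(s), float(track.t[e]), int(e), float(track.t[j]))
        )
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def _trailing_mean_from(v: np.ndarray, k: int) -> np.ndarray:
    """Trailing k-frame mean of ``v``, with the window truncated at index 0.

    ``out[i] = mean(v[max(0, i-k+1) : i+1])``: the window never reaches
    before the start of the segment, so a candidate arrest is judged only
    on frames from its own onset, and the first fast post-release frame
    marks the end within one frame.
    """
    c = np.concatenate([[0.0], np.cumsum(v)])
    i = np.arange(len(v))
    lo = np.maximum(0, i - k + 1)
    return (c[i + 1] - c[lo]) / (i + 1 - lo)


def classify_arrests(
    track: Track,
    grid: SpotGrid,
    speed_threshold: float = 2.0,
    window: float = 5.0,
    min_duration: float = 5.0,
    confine_margin: float = 1.5,
    encounter_margin: float = 0.0,
    encounters: pd.DataFrame | None = None,
) -> list[ArrestCall]:
    """Call arrests on one track from deceleration plus confinement.

    Starting at each detected encounter, an arrest is called if the
    trailing mean speed (over a ``window``-min span truncated at the
    onset) stays below ``speed_threshold`` and the centroid stays inside
    the footprint (with ``confine_margin`` slack) for at least
    ``min_duration``. The end time is the first frame violating either
    condition (``None`` while unreleased at movie end). Precomputed
    ``encounters`` for this track may be passed to avoid re-detection.
    """
    if speed_threshold <= 0 or window <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    if len(track) < 2:
        return []
    dt = track.dt
    if window < 2 * dt:
        raise ValueError(f"window ({window} min) must be at least 2*dt ({2 * dt} min)")
    v = np.linalg.norm(np.diff(track.xy, axis=0), axis=1) / dt
    v = np.concatenate([v, [v[-1]]])
    k = max(2, int(round(window / dt)))
    if encounters is None:
        encounters = detect_encounters(track, grid, encounter_margin)
    calls: list[ArrestCall] = []
    busy_until = -np.inf
    for row in encounters.itertuples():
        e = int(row.frame_entry)
        if track.t[e] < busy_until:
            continue  # entry within an ongoing call (cannot double-count)
        s = int(row.spot_id)
        center = grid.centers[s]
        r = grid.spot_radius + confine_margin
        confined = np.linalg.norm(track.xy[e:] - center, axis=1) <= r
        m = _trailing_mean_from(v[e:], k)
        ok = confined & (m <= speed_threshold)
        if not ok[0]:
            continue
        viol = (~ok).nonzero()[0]
        L = int(viol[0]) if len(viol) else None
        dur = (L * dt) if L is not None else (track.t[-1] - track.t[e] + dt)
        if dur < min_duration:
            continue
        end = float(track.t[e + L]) if L is not None else None
        span = slice(e, e + L if L is not None else len(track))
        calls.append(
            ArrestCall(
                cell_id=track.cell_id,
                spot_id=s,
                onset=float(track.t[e]),
                end=end,
                mean_speed=float(np.mean(v[span])),
            )
        )
        busy_until = end if end is not None else np.inf
    return calls


def classify_arrests_uniform(
    track: Track,
    speed_threshold: float = 2.0,
    window: float = 5.0,
    min_duration: float = 5.0,
) -> list[ArrestCall]:
    """Call arrests on a uniformly stimulatory surface (deceleration only).

    Without discrete spots there is no confinement criterion: an arrest is
    a maximal span where the trailing mean speed stays below
    ``speed_threshold`` for at least ``min_duration``. ``spot_id`` is -1.
    """
    if len(track) < 2:
        return []
    dt = track.dt
    if window < 2 * dt:
        raise ValueError(f"window ({window} min) must be at least 2*dt ({2 * dt} min)")
    v = np.linalg.norm(np.diff(track.xy, axis=0), axis=1) / dt
    v = np.concatenate([v, [v[-1]]])
    k = max(2, int(round(window / dt)))
    slow = v <= speed_threshold
    calls: list[ArrestCall] = []
    i = 0
    n = len(v)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        m = _trailing_mean_from(v[i:], k)
        viol = (m > speed_threshold).nonzero()[0]
        L = int(viol[0]) if len(viol) else None
        dur = (L * dt) if L is not None else (track.t[-1] - track.t[i] + dt)
        if dur >= min_duration:
            end = float(track.t[i + L]) if L is not None else None
            span = slice(i, i + L if L is not None else n)
            calls.append(
                ArrestCall(
                    cell_id=track.cell_id,
                    spot_id=-1,
                    onset=float(track.t[i]),
                    end=end,
                    mean_speed=float(np.mean(v[span])),
                )
            )
            i = (i + L) if L is not None else n
        else:
            i += max(1, L if L is not None else 1)
    return calls


def exclude_encounters_during_arrest(
    encounters: pd.DataFrame,
    calls: list[ArrestCall],
    movie_end: float,
) -> pd.DataFrame:
    """Drop encounters occurring while the same cell is already arrested.

    An entry strictly inside an arrest call's [onset, end) offers no new
    chance to arrest (e.g. jitter of an arrested cell flickering across
    the footprint edge) and must not inflate the efficiency denominator.
    The entry that starts the call itself is kept.
    """
    if len(encounters) == 0:
        return encounters
    by_cell: dict[int, list[tuple[float, float]]] = {}
    for c in calls:
        end = c.end if c.end is not None else movie_end + 1.0
        by_cell.setdefault(c.cell_id, []).append((c.onset, end))
    keep = np.ones(len(encounters), dtype=bool)
    for j, row in enumerate(encounters.itertuples()):
        for onset, end in by_cell.get(int(row.cell_id), ()):
            if onset < row.t_entry < end:
                keep[j] = False
                break
    return encounters[keep].reset_index(drop=True)


def attachment_curve(
    calls: list[ArrestCall],
    times: np.ndarray,
    field_count: float = 1.0,
) -> AttachmentCurve:
    """Cumulative count of first arrests per cell on a time grid."""
    times = np.asarray(times, dtype=float)
    first: dict[int, float] = {}
    for c in calls:
        if c.cell_id not in first or c.onset < first[c.cell_id]:
            first[c.cell_id] = c.onset
    onsets = np.sort(np.array(list(first.values())))
    counts = np.searchsorted(onsets, times, side="right").astype(float)
    return AttachmentCurve(times=times, counts=counts, field_count=field_count)


def initial_slope(
    curve: AttachmentCurve,
    grid: SpotGrid,
    t_max: float = 30.0,
    capacity_fraction: float = 0.15,
    min_points: int = 5,
) -> tuple[float, float]:
    """Least-squares slope through the origin over the initial window.

    The window runs from t = 0 to the earlier of (a) the time cumulative
    arrests reach ``capacity_fraction`` of the arena's total site capacity
    and (b) ``t_max``, and always contains at least ``min_points`` positive
    time points. Returns ``(slope per field per min, window end)``.
    """
    t, y = curve.times, curve.per_field
    if len(t) == 0:
        raise ValueError("attachment curve is empty")
    if curve.counts[-1] == 0:
        return 0.0, float(min(t[-1], t_max))
    cap = capacity_fraction * grid.total_capacity
    reached = curve.counts >= cap
    t_sat = float(t[reached.argmax()]) if reached.any() else float(t[-1])
    w = min(t_sat, t_max)
    sel = (t > 0) & (t <= w)
    if sel.sum() < min_points:
        pos = (t > 0).nonzero()[0]
        if len(pos) < min_points:
            warnings.warn("fewer points than requested; using all positive times")
            sel = t > 0
        else:
            warnings.warn(
                f"initial window held {int(sel.sum())} points; widened to {min_points}"
            )
            sel = np.zeros_like(sel)
            sel[pos[:min_points]] = True
        w = float(t[sel.nonzero()[0][-1]])
    ts, ys = t[sel], y[sel]
    slope = float(np.sum(ts * ys) / np.sum(ts * ts))
    return slope, w


def on_rate(curve: AttachmentCurve, grid: SpotGrid, **kwargs) -> float:
    """On-rate of arrest: initial attachment-curve slope, cells/field/min."""
    return initial_slope(curve, grid, **kwargs)[0]


def encounter_rate(
    encounters: pd.DataFrame,
    duration: float,
    field_count: float = 1.0,
) -> float:
    """Encounters per reference field per minute."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(encounters) / duration / field_count


def _matched_mask(encounters: pd.DataFrame, calls: list[ArrestCall]) -> np.ndarray:
    """Which encounters start an arrest call (same cell, spot and onset)."""
    keyset = {(c.cell_id, c.spot_id, round(c.onset, 6)) for c in calls}
    return np.array(
        [
            (int(r.cell_id), int(r.spot_id), round(float(r.t_entry), 6)) in keyset
            for r in encounters.itertuples()
        ],
        dtype=bool,
    ) if len(encounters) else np.zeros(0, dtype=bool)


def arrest_efficiency(calls: list[ArrestCall], encounters: pd.DataFrame) -> float:
    """Fraction of encounters that culminate in an arrest call."""
    if len(encounters) == 0:
        warnings.warn("zero encounters; arrest efficiency undefined")
        return math.nan
    matched = _matched_mask(encounters, calls)
    return float(matched.mean())


def fit_dwell_half_life(
    calls: list[ArrestCall],
    movie_end: float,
    min_duration: float,
) -> float:
    """MLE of the exponential dwell half-life from arrest-call durations.

    Durations are left-truncated at ``min_duration`` (shorter dwells are
    undetectable by construction) and right-censored at the movie end for
    calls without an observed release.
    """
    durs = np.array([c.duration(movie_end) for c in calls])
    cens = np.array([c.censored for c in calls])
    if len(durs) == 0 or (~cens).sum() == 0:
        warnings.warn("no released arrests; dwell half-life not identifiable")
        return math.nan
    excess = np.clip(durs - min_duration, 0.0, None)
    rate = (~cens).sum() / excess.sum()
    return math.log(2) / rate


def censoring_corrected_efficiency(
    raw_efficiency: float,
    dwell_half_life: float,
    min_duration: float,
) -> float:
    """Correct the efficiency for dwells too short for the arrest caller.

    Divides by the exponential survival at ``min_duration``, the detectable
    fraction of true arrests.
    """
    if not math.isfinite(dwell_half_life):
        return raw_efficiency
    survival = 0.5 ** (min_duration / dwell_half_life)
    return min(1.0, raw_efficiency / survival)


def decompose_on_rate(
    encounter_rate_value: float,
    arrest_efficiency_value: float,
    measured_on_rate: float | None = None,
) -> tuple[float, float | None]:
    """Bimolecular decomposition: predicted on-rate and relative residual.

    Returns ``(encounter_rate * efficiency, |predicted - measured| /
    measured)``; the residual is None when no measured value is given or
    the measured value is zero.
    """
    if encounter_rate_value < 0 or arrest_efficiency_value < 0:
        raise ValueError("inputs must be non-negative")
    predicted = encounter_rate_value * arrest_efficiency_value
    residual = None
    if measured_on_rate is not None and measured_on_rate > 0:
        residual = abs(predicted - measured_on_rate) / measured_on_rate
    return predicted, residual


def sp_fraction_uniform(
    calls: list[ArrestCall],
    expected_cells_per_field: int,
    field_count: float = 1.0,
) -> float:
    """Fraction of cells forming IS/IK on a uniform surface.

    Denominator is the expected number of cells per field (typically 30),
    as used for uniform-surface scoring.
    """
    if expected_cells_per_field <= 0:
        raise ValueError("expected_cells_per_field must be positive")
    n_cells = len({c.cell_id for c in calls})
    return n_cells / field_count / expected_cells_per_field


@dataclass(frozen=True)
class FoldEstimate:
    fold: float
    ci_low: float | None = None
    ci_high: float | None = None


def fold_change(memory_value: float, naive_value: float) -> float:
    """Memory/naive ratio; NaN (with warning) when the naive value is 0."""
    if naive_value == 0:
        warnings.warn("naive value is zero; fold change undefined")
        return math.nan
    return memory_value / naive_value


def bootstrap_fold(
    memory_samples: np.ndarray,
    naive_samples: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    stat=np.mean,
) -> FoldEstimate:
    """Percentile-bootstrap fold of ``stat`` over cell-level samples.

    ``memory_samples``/``naive_samples`` hold one value per cell whose
    ``stat`` (default mean) defines the compared quantity; cells are
    resampled with replacement, 1,000 reps by default, seeded.
    """
    memory_samples = np.asarray(memory_samples, dtype=float)
    naive_samples = np.asarray(naive_samples, dtype=float)
    point = fold_change(stat(memory_samples), stat(naive_samples))
    rng = np.random.default_rng(seed)
    folds = np.empty(n_boot)
    for b in range(n_boot):
        ms = rng.choice(memory_samples, size=len(memory_samples), replace=True)
        ns = rng.choice(naive_samples, size=len(naive_samples), replace=True)
        denom = stat(ns)
        folds[b] = stat(ms) / denom if denom != 0 else np.nan
    lo, hi = np.nanpercentile(folds, [2.5, 97.5])
    return FoldEstimate(fold=point, ci_low=float(lo), ci_high=float(hi))


@dataclass
class PhenotypeSP:
    """Synapse-propensity correlates of one subset on a patterned arena."""

    label: str
    on_rate: float  # cells/field/min
    encounter_rate: float  # encounters/field/min (initial window)
    arrest_efficiency: float
    arrest_efficiency_corrected: float
    predicted_on_rate: float
    residual: float | None
    dwell_half_life: float
    window: float  # min, initial-slope window
    n_encounters_window: int
    n_arrests: int
    n_cells: int


@dataclass
class SPReport:
    """Per-subset SP correlates plus memory/naive fold-changes."""

    phenotypes: dict[str, PhenotypeSP] = field(default_factory=dict)
    folds: dict[str, FoldEstimate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phenotypes": {k: asdict(v) for k, v in self.phenotypes.items()},
            "folds": {k: asdict(v) for k, v in self.folds.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def analyze_tracks(
    tracks: list[Track],
    grid: SpotGrid,
    params: AnalysisParams = AnalysisParams(),
    naive_label: str = "naive",
    memory_label: str = "memory",
    bootstrap_seed: int = 0,
) -> SPReport:
    """End-to-end SP measurement on a patterned arena.

    Groups tracks by phenotype label, calls arrests, fits the on-rate from
    the initial attachment-curve slope, estimates encounter rate and
    arrest efficiency within the same initial window, and reports the
    bimolecular decomposition residual plus memory/naive fold-changes.
    """
    report = SPReport()
    if not tracks:
        warnings.warn("no tracks; returning empty report")
        return report
    field_count = grid.field_area / REFERENCE_FIELD_AREA
    by_label: dict[str, list[Track]] = {}
    for tr in tracks:
        by_label.setdefault(tr.label, []).append(tr)

    window_arrest_cells: dict[str, np.ndarray] = {}
    for label, trs in by_label.items():
        movie_end = max(float(tr.t[-1]) for tr in trs)
        dt = trs[0].dt
        times = np.arange(0.0, movie_end + dt / 2, dt)
        enc_parts, calls = [], []
        for tr in trs:
            if len(tr) < 2:
                continue  # e.g. a cell entering the field on the last frame
            enc = detect_encounters(tr, grid, params.encounter_margin)
            if len(enc):
                enc_parts.append(enc)
            calls.extend(
                classify_arrests(
                    tr,
                    grid,
                    speed_threshold=params.speed_threshold,
                    window=params.window,
                    min_duration=params.min_duration,
                    confine_margin=params.confine_margin,
                    encounter_margin=params.encounter_margin,
                    encounters=enc,
                )
            )
        encounters = (
            pd.concat(enc_parts, ignore_index=True)
            if enc_parts
            else pd.DataFrame(columns=ENCOUNTER_COLUMNS)
        )
        encounters = exclude_encounters_during_arrest(encounters, calls, movie_end)
        curve = attachment_curve(calls, times, field_count)
        slope, w = initial_slope(
            curve,
            grid,
            t_max=params.slope_t_max,
            capacity_fraction=params.slope_capacity_fraction,
            min_points=params.slope_min_points,
        )
        enc_w = encounters[encounters["t_entry"] <= w].reset_index(drop=True)
        calls_w = [c for c in calls if c.onset <= w]
        eff = arrest_efficiency(calls_w, enc_w) if len(enc_w) else math.nan
        t_half = fit_dwell_half_life(calls, movie_end, params.min_duration)
        eff_corr = (
            censoring_corrected_efficiency(eff, t_half, params.min_duration)
            if math.isfinite(eff) and math.isfinite(t_half)
            else eff
        )
        er = encounter_rate(enc_w, w, field_count) if w > 0 else 0.0
        predicted, residual = (
            decompose_on_rate(er, eff, slope)
            if math.isfinite(eff)
            else (math.nan, None)
        )
        report.phenotypes[label] = PhenotypeSP(
            label=label,
            on_rate=slope,
            encounter_rate=er,
            arrest_efficiency=eff,
            arrest_efficiency_corrected=eff_corr,
            predicted_on_rate=predicted,
            residual=residual,
            dwell_half_life=t_half,
            window=w,
            n_encounters_window=len(enc_w),
            n_arrests=len(calls),
            n_cells=len(trs),
        )
        arrested_cells = {c.cell_id for c in calls_w}
        window_arrest_cells[label] = np.array(
            [1.0 if tr.cell_id in arrested_cells else 0.0 for tr in trs]
        )

    if naive_label in report.phenotypes and memory_label in report.phenotypes:
        nv, mm = report.phenotypes[naive_label], report.phenotypes[memory_label]
        # cell-level bootstrap of in-window first-arrest indicators; the
        # interval is re-centered on the measured slope ratio
        boot = bootstrap_fold(
            window_arrest_cells[memory_label],
            window_arrest_cells[naive_label],
            seed=bootstrap_seed,
        )
        point = fold_change(mm.on_rate, nv.on_rate)
        shift = point / boot.fold if boot.fold and math.isfinite(boot.fold) else 1.0
        report.folds["on_rate"] = FoldEstimate(
            fold=point,
            ci_low=boot.ci_low * shift if boot.ci_low is not None else None,
            ci_high=boot.ci_high * shift if boot.ci_high is not None else None,
        )
        report.folds["encounter_rate"] = FoldEstimate(
            fold=fold_change(mm.encounter_rate, nv.encounter_rate)
        )
        report.folds["arrest_efficiency"] = FoldEstimate(
            fold=fold_change(mm.arrest_efficiency, nv.arrest_efficiency)
        )
    return report
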