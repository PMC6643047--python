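"""Canonical synthetic studies: fixed designs exercising the full pipeline.

Each function wires generator, pipeline and models together under the
study conditions used throughout the package's validation: the reference
spot geometry (10-um spots, 30-um pitch), the default naive/memory
phenotypes, and problem sizes chosen so statistical oracles are sharp
while runs stay fast on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from synprop.arena import SpotGrid, build_spot_grid
from synprop.competition import (
    CompetitionParams,
    printed_regime_params,
    steady_state_ratio,
)
from synprop.metrics import (
    AnalysisParams,
    SPReport,
    analyze_tracks,
    arrest_efficiency,
    censoring_corrected_efficiency,
    classify_arrests,
    classify_arrests_uniform,
    detect_encounters,
    exclude_encounters_during_arrest,
    fit_dwell_half_life,
    sp_fraction_uniform,
)
from synprop.simulate import (
    MEMORY_CD8,
    NAIVE_CD8,
    CellPhenotype,
    SimConfig,
    simulate_arena,
    simulate_uniform_surface,
)

__all__ = [
    "reference_arena",
    "decomposition_study",
    "recovery_study",
    "dwell_recovery_study",
    "speed_ladder_study",
    "arrest_prob_ladder_study",
    "uniform_dose_response_study",
    "steady_state_fold_prediction",
    "encounter_fold_from_decomposition",
]


def reference_arena(tiles: int = 1, capacity: int = 1) -> SpotGrid:
    """The reference 10-um/30-um spot field, optionally tiled ``tiles x tiles``."""
    return build_spot_grid(
        field_area=50_625.0 * tiles * tiles,
        spot_diameter=10.0,
        pitch=30.0,
        capacity=capacity,
    )


def decomposition_study(
    seed: int,
    n_cells: int = 600,
    duration: float = 90.0,
    tiles: int = 5,
    capacity: int = 2,
) -> SPReport:
    """On-rate decomposition under the standard conditions.

    Each phenotype migrates over its own tiled reference arena for a
    90-min movie in open-field (replenished) mode; the report carries
    on-rate, encounter rate, arrest efficiency, the bimolecular residual
    and memory/naive folds.
    """
    grid = reference_arena(tiles=tiles, capacity=capacity)
    cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed,
                    replenish=True)
    all_tracks = []
    for phen in (NAIVE_CD8, MEMORY_CD8):
        tracks, _ = simulate_arena(grid, [phen], cfg)
        all_tracks.extend(tracks)
    return analyze_tracks(all_tracks, grid, bootstrap_seed=seed)


def recovery_study(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_cells: int = 400,
    params: AnalysisParams = AnalysisParams(),
) -> dict[str, dict]:
    """Recover the generator's arrest probabilities from the pipeline.

    Runs each phenotype on an ample-capacity arena (site competition off
    the table), pools encounters over the seeds, and reports the
    censoring-corrected arrest efficiency with the 95% binomial
    half-width at the pooled realized encounter count. Only encounters
    with a full ``min_duration`` observation window before movie end
    enter the estimate (later ones offer no detectable chance).
    """
    grid = reference_arena(tiles=5, capacity=50)
    out: dict[str, dict] = {}
    for phen, duration in ((NAIVE_CD8, 90.0), (MEMORY_CD8, 240.0)):
        n_enc = 0
        n_matched = 0
        all_calls = []
        for seed in seeds:
            cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed)
            tracks, _ = simulate_arena(grid, [phen], cfg)
            encs, calls = [], []
            for tr in tracks:
                if len(tr) < 2:
                    continue
                enc = detect_encounters(tr, grid, params.encounter_margin)
                if len(enc):
                    encs.append(enc)
                calls.extend(
                    classify_arrests(
                        tr, grid,
                        speed_threshold=params.speed_threshold,
                        window=params.window,
                        min_duration=params.min_duration,
                        confine_margin=params.confine_margin,
                        encounters=enc,
                    )
                )
            enc = pd.concat(encs, ignore_index=True)
            enc = exclude_encounters_during_arrest(enc, calls, duration)
            enc = enc[enc["t_entry"] <= duration - params.min_duration]
            calls_obs = [c for c in calls if c.onset <= duration - params.min_duration]
            eff = arrest_efficiency(calls_obs, enc)
            n_enc += len(enc)
            n_matched += int(round(eff * len(enc)))
            all_calls.append((calls, duration))
        raw = n_matched / n_enc
        t12 = np.mean(
            [fit_dwell_half_life(c, d, params.min_duration) for c, d in all_calls]
        )
        corrected = censoring_corrected_efficiency(raw, float(t12), params.min_duration)
        p = phen.arrest_prob
        out[phen.label] = {
            "arrest_prob_true": p,
            "efficiency": corrected,
            "n_encounters": n_enc,
            "ci_halfwidth": 1.96 * math.sqrt(p * (1 - p) / n_enc),
            "dwell_half_life": float(t12),
            "dwell_half_life_true": phen.dwell_half_life,
        }
    return out


def dwell_recovery_study(seed: int = 1, n_cells: int = 600,
                         duration: float = 240.0) -> dict:
    """Recover the memory dwell half-life from arrest-call durations."""
    grid = reference_arena(tiles=5, capacity=50)
    cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed)
    tracks, log = simulate_arena(grid, [MEMORY_CD8], cfg)
    calls = []
    for tr in tracks:
        if len(tr) >= 2:
            calls.extend(classify_arrests(tr, grid))
    t12 = fit_dwell_half_life(calls, duration, 5.0)
    return {
        "dwell_half_life": t12,
        "dwell_half_life_true": MEMORY_CD8.dwell_half_life,
        "n_releases": len(log.releases),
        "n_calls": len(calls),
    }


def speed_ladder_study(
    seed: int = 1,
    speeds: tuple[float, ...] = (6.0, 9.0, 12.0, 16.0, 20.0),
    n_cells: int = 200,
    duration: float = 30.0,
) -> list[float]:
    """Measured encounter rate per field per minute along a speed ladder.

    Arrest is switched off so the ladder isolates the search process.
    """
    grid = reference_arena(tiles=2)
    rates = []
    for s in speeds:
        phen = CellPhenotype(label="probe", speed_mean=s, arrest_prob=0.0)
        cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed)
        tracks, _ = simulate_arena(grid, [phen], cfg)
        n_enc = sum(
            len(detect_encounters(tr, grid)) for tr in tracks if len(tr) >= 2
        )
        rates.append(n_enc / duration / (grid.field_area / 50_625.0))
    return rates


def arrest_prob_ladder_study(
    seed: int = 1,
    probs: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8),
    n_cells: int = 300,
    duration: float = 60.0,
) -> list[float]:
    """Measured on-rate along an arrest-probability ladder, fixed seed."""
    grid = reference_arena(tiles=3, capacity=2)
    rates = []
    for p in probs:
        phen = CellPhenotype(label="probe", speed_mean=12.0, arrest_prob=p,
                             dwell_half_life=120.0)
        cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed,
                        replenish=True)
        tracks, _ = simulate_arena(grid, [phen], cfg)
        report = analyze_tracks(tracks, grid)
        rates.append(report.phenotypes["probe"].on_rate)
    return rates


def uniform_dose_response_study(
    seed: int = 1,
    hazards: tuple[float, ...] = (0.005, 0.01, 0.02, 0.04),
    n_cells: int = 400,
    duration: float = 60.0,
) -> list[float]:
    """IS/IK fraction on uniform surfaces along an arrest-hazard ladder.

    The hazard ladder surrogates a stimulatory ligand-density dose
    response; dwell is effectively permanent over the movie.
    """
    fracs = []
    for h in hazards:
        phen = CellPhenotype(label="probe", speed_mean=12.0,
                             uniform_arrest_hazard=h,
                             dwell_half_life=math.inf)
        cfg = SimConfig(dt=0.5, duration=duration, n_cells=n_cells, seed=seed)
        tracks, _ = simulate_uniform_surface([phen], cfg)
        calls = []
        for tr in tracks:
            if len(tr) >= 2:
                calls.extend(classify_arrests_uniform(tr))
        fracs.append(sp_fraction_uniform(calls, expected_cells_per_field=n_cells))
    return fracs


def steady_state_fold_prediction(
    kon_fold: float = 7.0,
    t_half_fold: float = 3.5,
) -> float:
    """Steady-state memory:naive occupancy fold from the printed folds.

    Memory on-rate ``kon_fold``-fold higher, dwell half-life
    ``t_half_fold``-fold shorter; equal non-depleting free pools.
    """
    params = printed_regime_params(kon_fold=kon_fold, t_half_fold=t_half_fold)
    return steady_state_ratio(params)


def encounter_fold_from_decomposition(
    on_rate_fold: float,
    efficiency_fold: float,
) -> float:
    """Encounter-rate fold implied by on_rate = encounter_rate x efficiency."""
    return on_rate_fold / efficiency_fold
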