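"""Multi-recording experiments: the pooled analyses the single-recording
pipeline feeds into.

These runners mirror the study design: many ~2-minute recordings of ~60
OHCs per condition, waves pooled across recordings, then (a) the
rsavg-vs-extension regression with per-wave significance calls, (b) the
small- vs large-wave comparison of OHC integral increases, and (c) the
wild-type vs knockout comparison of detected wave rates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import detrend_poly, moving_average
from .config import SimulationConfig, WaveSpec
from .containers import CellMap, TraceMatrix
from .extraction import compute_dff, movie_dff
from .simulate import (distance_to_rect, render_movie, simulate_recording,
                       wave_footprint_rect)
from . import sync
from .sync import (AnalysisWindow, activity_increase_by_distance,
                   fisher_average, make_wave_window, pick_background_window,
                   spearman_matrix, test_sync_increase)
from .waves import detect_waves


def derive_seed(seed: int, index: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return (seed * 100003 + 7919 * index + 1) % (2**31 - 1)


def condition_for_correlation(dff: np.ndarray) -> np.ndarray:
    """Smooth (MA-3) and polynomial-detrend every trace before ranking.

    Removes the shared photobleaching trend that would otherwise inflate
    all pairwise correlations; no normalization (Spearman is rank-based).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    out = np.empty_like(dff)
    for k in range(dff.shape[0]):
        out[k] = detrend_poly(moving_average(dff[k]), 5)
    return out


def wave_frame_span(wave: WaveSpec, frame_rate_hz: float,
                    n_frames: int) -> tuple[int, int]:
    """Half-open frame interval a scheduled wave occupies."""
    a = int(np.floor(wave.onset_s * frame_rate_hz))
    b = int(np.ceil((wave.onset_s + wave.duration_s) * frame_rate_hz))
    return max(a, 0), min(b, n_frames)


def wave_peak_frame(wave: WaveSpec, frame_rate_hz: float) -> int:
    """Frame of the wave's peak intensity (onset + duration/5)."""
    return int(round((wave.onset_s + wave.duration_s / 5.0) * frame_rate_hz))


def analyze_recording_sync(dff: TraceMatrix, cell_map: CellMap,
                           waves: Sequence[WaveSpec],
                           config: SimulationConfig,
                           use_conditioned: bool = True) -> pd.DataFrame:
    """Per-wave synchronization and activity-increase statistics for one
    recording whose wave schedule is known.

    Returns one row per analysable wave: extension, rsavg in the wave and
    background windows, the one-sided Mann-Whitney p for the increase of
    pairwise coefficients, the P < 0.001 significance call, and the mean
    fractional integral increase over OHCs. Waves whose 400-frame window
    leaves the recording are dropped; recordings without a wave-free
    background window yield an empty frame.
    """
    n_frames = dff.n_frames
    fr = dff.frame_rate_hz
    spans = [wave_frame_span(w, fr, n_frames) for w in waves]
    background = pick_background_window(spans, n_frames)
    if background is None:
        return pd.DataFrame()
    vals = condition_for_correlation(dff.values) if use_conditioned else dff.values
    bg_corr = spearman_matrix(vals, background, window_detrend=True)
    rows = []
    for i, w in enumerate(waves):
        window = make_wave_window(wave_peak_frame(w, fr), n_frames)
        if window is None:
            continue
        overlapping = any(not (window.end_frame <= a or window.start_frame >= b)
                          for j, (a, b) in enumerate(spans) if j != i)
        wave_corr = spearman_matrix(vals, window, window_detrend=True)
        try:
            rsavg_w = fisher_average(wave_corr.r_matrix)
            rsavg_b = fisher_average(bg_corr.r_matrix)
            p, significant = test_sync_increase(wave_corr, bg_corr)
        except ValueError:
            continue
        rect = wave_footprint_rect(w, config.ger_band_um)
        distances = np.array([distance_to_rect(x, y, rect)
                              for x, y in cell_map.positions()])
        # integrate the detrended traces: the photobleaching trend would
        # otherwise bias any late wave window against an early background
        increases, _ = activity_increase_by_distance(
            vals, cell_map.cells["id"].tolist(), distances,
            window, background, fr)
        # per-wave summary: mean increase of the trace integral across OHCs
        # (dF/F0 * s); the per-cell fractional version is unstable when a
        # quiet cell's background integral is near zero
        mean_increase = float(np.mean([a.integral_wave - a.integral_background
                                       for a in increases]))
        rows.append({
            "wave_index": i,
            "extension_um": w.extent_um,
            "rsavg_wave": rsavg_w,
            "rsavg_background": rsavg_b,
            "p_increase": p,
            "significant": significant,
            "overlapping": overlapping,
            "mean_integral_increase": mean_increase,
        })
    return pd.DataFrame(rows)


def run_sync_extension_study(config: SimulationConfig, n_recordings: int,
                             seed: int) -> pd.DataFrame:
    """Simulate ``n_recordings`` recordings and pool per-wave sync rows."""
    frames = []
    for r in range(n_recordings):
        cfg = config.with_(seed=derive_seed(seed, r), wave_schedule=None)
        traces, cell_map, gt = simulate_recording(cfg)
        if not gt.wave_events_true:
            continue
        dff = compute_dff(traces)
        df = analyze_recording_sync(dff, cell_map, gt.wave_events_true, cfg)
        if not df.empty:
            df.insert(0, "recording", r)
            frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def regression_from_study(study: pd.DataFrame) -> "sync.RegressionResult":
    """rsavg-vs-extension OLS over the pooled per-wave rows."""
    return sync.regress_sync_vs_extension(
        study["extension_um"].to_numpy(), study["rsavg_wave"].to_numpy())


def size_class_comparison_from_study(study: pd.DataFrame) -> dict:
    """Welch t-test of per-wave mean OHC integral increases, small (< 75 um)
    vs large (> 150 um) waves."""
    ok = study.dropna(subset=["mean_integral_increase"])
    small = ok.loc[ok["extension_um"] < sync.SMALL_WAVE_MAX_UM,
                   "mean_integral_increase"]
    large = ok.loc[ok["extension_um"] > sync.LARGE_WAVE_MIN_UM,
                   "mean_integral_increase"]
    return sync.compare_wave_size_classes(small, large)


def detected_wave_rate(config: SimulationConfig, seed: int,
                       shape_px: tuple[int, int] = (70, 128),
                       y_range_um: tuple[float, float] = (60.0, 160.0),
                       pixel_noise_sd: float = 0.1) -> float:
    """Render the GER strip of one recording, detect waves, return
    events/min."""
    cfg = config.with_(seed=seed, wave_schedule=None)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    from .simulate import sample_wave_schedule
    waves = sample_wave_schedule(cfg, rng)
    movie = render_movie(None, None, waves, cfg, shape_px=shape_px,
                         y_range_um=y_range_um,
                         pixel_noise_sd=pixel_noise_sd)
    dff = movie_dff(movie)
    catalog = detect_waves(dff, ger_band_um=None)
    return catalog.events_per_min


def run_wave_rate_study(config_a: SimulationConfig, config_b: SimulationConfig,
                        n_recordings: int, seed: int) -> dict:
    """Detected wave rates under two presets plus a one-sided rank test
    (condition A > condition B)."""
    rates_a = [detected_wave_rate(config_a, derive_seed(seed, r))
               for r in range(n_recordings)]
    rates_b = [detected_wave_rate(config_b, derive_seed(seed, n_recordings + r))
               for r in range(n_recordings)]
    res = stats.mannwhitneyu(rates_a, rates_b, alternative="greater")
    return {"rates_a": rates_a, "rates_b": rates_b,
            "mean_a": float(np.mean(rates_a)), "mean_b": float(np.mean(rates_b)),
            "p": float(res.pvalue)}
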