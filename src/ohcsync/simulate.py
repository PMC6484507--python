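"""Ground-truth-annotated synthetic recordings.

The generator emulates the statistical structure the downstream analysis
assumes: OHCs fire bursts of action potentials; each spike adds a
mono-exponential indicator transient (decay ~300 ms) to the cell's dF/F0;
traces decay slowly through photobleaching and carry additive Gaussian
noise; and scheduled GER Ca2+ waves transiently multiply OHC firing rates
with a coupling that decays with distance from the wave footprint and grows
with the wave's longitudinal extension.

Spike -> fluorescence is a linear convolution with the AR(1)-sampled
exponential kernel; coupling is a rate modulation, not a direct
fluorescence addition, because OHC increases during waves are attributed to
depolarization-driven firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimulationConfig, WaveSpec
from .containers import CellMap, FluorescenceMovie, TraceMatrix
from .geometry import pixel_size_um, roi_side_px


@dataclass
class GroundTruth:
    """What the generator actually realized, for parameter-recovery tests."""

    spike_times: list[np.ndarray]            # per cell, seconds
    wave_events_true: list[WaveSpec]
    noiseless_traces: np.ndarray             # cells x frames dF/F0, >= 0


def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-stream generator: changing n_cells never reshuffles
    the streams of existing cells."""
    return np.random.default_rng(np.random.SeedSequence((seed, *stream)))


def make_cell_map(config: SimulationConfig) -> CellMap:
    """Lay OHCs out in up to ``n_rows`` rows along the tonotopic axis.

    Cells fill row-major: cell k sits in row ``k % n_rows`` at column
    ``k // n_rows``. A single cell is placed at the field centre, row 1.
    """
    n = config.n_cells
    if n == 1:
        cells = pd.DataFrame(
            {"id": [0], "x_um": [config.field_um / 2],
             "y_um": [config.field_um / 2], "row": [1]}
        )
        return CellMap(cells, config.field_um, ger_band_um=config.ger_band_um)

    n_rows = config.n_rows
    n_cols = int(np.ceil(n / n_rows))
    span_x = (n_cols - 1) * config.cell_spacing_um
    if span_x > config.field_um:
        raise ValueError(
            f"field of {config.field_um} um too small for {n} cells at "
            f"{config.cell_spacing_um} um spacing ({n_cols} columns)"
        )
    x0 = (config.field_um - span_x) / 2.0
    ids, xs, ys, rows = [], [], [], []
    for k in range(n):
        row = k % n_rows
        col = k // n_rows
        ids.append(k)
        xs.append(x0 + col * config.cell_spacing_um)
        ys.append(config.ohc_row_y_um + row * config.row_spacing_um)
        rows.append(row + 1)
    cells = pd.DataFrame({"id": ids, "x_um": xs, "y_um": ys, "row": rows})
    return CellMap(cells, config.field_um, ger_band_um=config.ger_band_um)


def sample_wave_schedule(config: SimulationConfig,
                         rng: np.random.Generator) -> list[WaveSpec]:
    """Poisson wave schedule at ``wave_rate_per_min``.

    Onsets are drawn uniformly but kept >= 5 s from the recording start (so
    a wave-free baseline prefix exists) and early enough for the wave to
    complete; extents are uniform over ``wave_extent_range_um``; centres are
    uniform subject to the footprint staying inside the field.
    """
    duration = config.duration_s
    lo_t = 5.0
    hi_t = max(lo_t, duration - config.wave_duration_s - 2.0)
    n = rng.poisson(config.wave_rate_per_min * duration / 60.0)
    waves = []
    for _ in range(n):
        onset = rng.uniform(lo_t, hi_t)
        e_lo, e_hi = config.wave_extent_range_um
        extent = rng.uniform(e_lo, min(e_hi, config.field_um))
        half = extent / 2.0
        if half >= config.field_um / 2.0:
            center = config.field_um / 2.0
        else:
            center = rng.uniform(half, config.field_um - half)
        waves.append(WaveSpec(onset_s=onset, extent_um=extent, center_um=center,
                              amplitude=config.wave_amplitude,
                              duration_s=config.wave_duration_s))
    waves.sort(key=lambda w: w.onset_s)
    return waves


def wave_time_course(wave: WaveSpec, t: np.ndarray) -> np.ndarray:
    """Normalized wave intensity over time: half-Gaussian rise to the peak,
    exponential fall. Peak at onset + duration/5; fall constant duration/3."""
    rise = wave.duration_s / 5.0
    t_peak = wave.onset_s + rise
    sigma = max(rise / 2.0, 1e-9)
    tau_fall = wave.duration_s / 3.0
    m = np.where(
        t < t_peak,
        np.exp(-0.5 * ((t - t_peak) / sigma) ** 2),
        np.exp(-(t - t_peak) / tau_fall),
    )
    m[t < wave.onset_s - 3 * sigma] = 0.0
    return m


def wave_footprint_rect(wave: WaveSpec,
                        ger_band_um: tuple[float, float]) -> tuple[float, float, float, float]:
    """(x_min, x_max, y_min, y_max) of the wave footprint in um."""
    return (wave.center_um - wave.extent_um / 2.0,
            wave.center_um + wave.extent_um / 2.0,
            ger_band_um[0], ger_band_um[1])


def distance_to_rect(x: float, y: float,
                     rect: tuple[float, float, float, float]) -> float:
    """Euclidean distance from a point to an axis-aligned rectangle
    (0 inside)."""
    x0, x1, y0, y1 = rect
    dx = max(x0 - x, 0.0, x - x1)
    dy = max(y0 - y, 0.0, y - y1)
    return float(np.hypot(dx, dy))


def coupling_multiplier(config: SimulationConfig, cell_xy: tuple[float, float],
                        waves: Sequence[WaveSpec], t: np.ndarray) -> np.ndarray:
    """Firing-rate multiplier 1 + gain * g(extent) * exp(-d / L) * m(t).

    g(extent) = min(extent / coupling_extent_max_um, 1) is the monotone
    link between wave extension and coupling strength; m(t) is the wave's
    normalized time course restricted to its active interval
    [onset, onset + duration], so the depolarization-driven rate increase
    follows the wave's Ca2+ level rather than switching on and off.
    """
    mult = np.ones_like(t)
    if not config.coupling_enabled or not waves:
        return mult
    for w in waves:
        g = min(w.extent_um / config.coupling_extent_max_um, 1.0)
        d = distance_to_rect(cell_xy[0], cell_xy[1],
                             wave_footprint_rect(w, config.ger_band_um))
        boost = config.coupling_gain * g * np.exp(-d / max(config.coupling_length_um, 1e-9))
        active = (t >= w.onset_s) & (t < w.onset_s + w.duration_s)
        mult = mult + boost * wave_time_course(w, t) * active
    return mult


def _spikes_from_rate(rate_per_frame: np.ndarray, dt: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Realize an inhomogeneous Poisson process from a piecewise-constant
    per-frame rate (Hz); spike times uniform within their frame."""
    counts = rng.poisson(rate_per_frame * dt)
    frames = np.repeat(np.arange(counts.size), counts)
    if frames.size == 0:
        return np.empty(0)
    times = (frames + rng.uniform(0.0, 1.0, size=frames.size)) * dt
    return np.sort(times)


def sample_spike_trains(cell_map: CellMap, config: SimulationConfig,
                        waves: Optional[Sequence[WaveSpec]] = None,
                        ) -> list[np.ndarray]:
    """Per-cell spike times.

    In non-burst mode each cell is an inhomogeneous Poisson process with
    rate baseline_rate_hz * multiplier(t). In burst mode the *burst
    initiations* form that Poisson process (rate 1/interval_mean_s *
    multiplier), each burst lasting Exp(duration_mean_s) with homogeneous
    spiking at the within-burst rate.
    """
    if waves is None:
        waves = list(config.wave_schedule or ())
    dt = 1.0 / config.frame_rate_hz
    t = (np.arange(config.n_frames) + 0.5) * dt
    duration = config.duration_s
    out: list[np.ndarray] = []
    for k, (x, y) in enumerate(cell_map.positions()):
        rng = _rng_for(config.seed, 1, int(cell_map.cells["id"].iloc[k]))
        mult = coupling_multiplier(config, (x, y), waves, t)
        if not config.burst_mode:
            spikes = _spikes_from_rate(config.baseline_rate_hz * mult, dt, rng)
        else:
            bp = config.burst_params
            init_rate = (1.0 / bp.interval_mean_s) if bp.interval_mean_s > 0 else 0.0
            starts = _spikes_from_rate(init_rate * mult, dt, rng)
            spikes_list = []
            for t0 in starts:
                b_dur = rng.exponential(bp.duration_mean_s)
                n_sp = rng.poisson(bp.within_rate_hz * b_dur)
                if n_sp:
                    sp = t0 + rng.uniform(0.0, b_dur, size=n_sp)
                    spikes_list.append(sp[sp < duration])
            spikes = (np.sort(np.concatenate(spikes_list))
                      if spikes_list else np.empty(0))
        out.append(spikes[spikes < duration])
    return out


def render_traces(spike_times: Sequence[np.ndarray], config: SimulationConfig,
                  cell_map: Optional[CellMap] = None,
                  ) -> tuple[TraceMatrix, GroundTruth]:
    """Render raw fluorescence traces from spike trains.

    F(t) = F0 * exp(-t / bleach_tau) * (1 + sum_spikes amp * exp(-(t - ts)/tau))
           + F0 * noise_sd * eps,
    sampled at the frame rate. The noiseless dF/F0 component is returned in
    the ground truth.
    """
    n_cells = len(spike_times)
    nf = config.n_frames
    dt = 1.0 / config.frame_rate_hz
    t = np.arange(nf) * dt
    gamma = np.exp(-dt / config.kernel_tau_s)
    dff = np.zeros((n_cells, nf))
    for k, spikes in enumerate(spike_times):
        if len(spikes) == 0:
            continue
        impulses = np.zeros(nf)
        first = np.ceil(spikes / dt - 1e-12).astype(int)   # first frame at/after spike
        keep = first < nf
        first = first[keep]
        amp_at_frame = config.kernel_amp * np.exp(-(first * dt - spikes[keep])
                                                  / config.kernel_tau_s)
        np.add.at(impulses, first, amp_at_frame)
        dff[k] = lfilter([1.0], [1.0, -gamma], impulses)
    bleach = np.exp(-t / config.bleach_tau_s) if config.bleach_tau_s > 0 else np.ones(nf)
    f = config.f0 * bleach[None, :] * (1.0 + dff)
    if config.noise_sd > 0:
        # per-cell noise streams: adding cells never reshuffles existing ones
        for k in range(n_cells):
            rng = _rng_for(config.seed, 2, k)
            f[k] += config.f0 * config.noise_sd * rng.standard_normal(nf)
    cells = cell_map.cells if cell_map is not None else None
    traces = TraceMatrix(f, config.frame_rate_hz, units="raw", cells=cells)
    gt = GroundTruth(spike_times=list(spike_times),
                     wave_events_true=list(config.wave_schedule or ()),
                     noiseless_traces=dff)
    return traces, gt


def simulate_recording(config: SimulationConfig,
                       ) -> tuple[TraceMatrix, CellMap, GroundTruth]:
    """One full synthetic recording: cell map, realized wave schedule,
    spike trains and raw traces. Deterministic given (config, seed)."""
    cell_map = make_cell_map(config)
    if config.wave_schedule is None:
        waves = sample_wave_schedule(config, _rng_for(config.seed, 0))
        config = config.with_(wave_schedule=tuple(waves))
    spikes = sample_spike_trains(cell_map, config)
    traces, gt = render_traces(spikes, config, cell_map)
    return traces, cell_map, gt


def render_movie(traces: Optional[TraceMatrix], cell_map: Optional[CellMap],
                 waves: Sequence[WaveSpec], config: SimulationConfig,
                 shape_px: tuple[int, int] = (512, 512),
                 y_range_um: Optional[tuple[float, float]] = None,
                 roi_side_um: float = 3.7,
                 background_f0: float = 50.0,
                 pixel_noise_sd: float = 0.0,
                 wave_edge_softness_um: float = 0.0,
                 ) -> FluorescenceMovie:
    """Rasterize a recording into a movie stack.

    Cells are painted as filled squares (ROI-sized) carrying their raw
    trace value; waves as time-modulated elliptical intensity fields in the
    GER band on top of a constant background. ``y_range_um`` restricts the
    rendered strip (e.g. the GER band only); the full square field is
    rendered by default.
    """
    h, w = shape_px
    px = pixel_size_um(config.field_um, w)
    y0_um = 0.0 if y_range_um is None else y_range_um[0]
    if y_range_um is not None and y_range_um[1] <= y_range_um[0]:
        raise ValueError("y_range_um must be increasing")
    n_frames = traces.n_frames if traces is not None else config.n_frames
    dt = 1.0 / config.frame_rate_hz
    t = (np.arange(n_frames)) * dt

    # pixel-centre coordinate grids (um)
    ys_um = y0_um + (np.arange(h) + 0.5) * px
    xs_um = (np.arange(w) + 0.5) * px

    movie = np.full((n_frames, h, w), background_f0, dtype=np.float32)

    # waves: elliptical footprint in the GER band
    gy0, gy1 = config.ger_band_um
    cy = 0.5 * (gy0 + gy1)
    ry = 0.5 * (gy1 - gy0)
    for wv in waves:
        rx = max(wv.extent_um / 2.0, px / 2.0)
        dx = (xs_um[None, :] - wv.center_um) / rx
        dy = (ys_um[:, None] - cy) / max(ry, 1e-9)
        r2 = dx ** 2 + dy ** 2
        if wave_edge_softness_um > 0:
            s = wave_edge_softness_um / rx
            footprint = np.clip((1.0 - np.sqrt(r2)) / s, 0.0, 1.0)
        else:
            footprint = (r2 <= 1.0).astype(np.float32)
        if not footprint.any():
            continue
        m = wave_time_course(wv, t).astype(np.float32)
        sel = np.nonzero(m > 1e-4)[0]
        fy, fx = np.nonzero(footprint)
        add = (background_f0 * wv.amplitude) * footprint[fy, fx]
        for i in sel:
            movie[i, fy, fx] += m[i] * add

    # cells: filled squares carrying the raw trace value
    if traces is not None and cell_map is not None:
        side = roi_side_px(roi_side_um, px)
        half = side // 2
        vals = traces.values.astype(np.float32)
        for k, (x_um, y_um) in enumerate(cell_map.positions()):
            cx_px = int(round(x_um / px - 0.5))
            cy_px = int(round((y_um - y0_um) / px - 0.5))
            if not (0 <= cx_px < w and 0 <= cy_px < h):
                raise ValueError(f"cell {k} falls outside the rendered frame")
            x_lo, x_hi = max(cx_px - half, 0), min(cx_px + half + 1, w)
            y_lo, y_hi = max(cy_px - half, 0), min(cy_px + half + 1, h)
            movie[:, y_lo:y_hi, x_lo:x_hi] = vals[k][:, None, None]

    if pixel_noise_sd > 0:
        rng = _rng_for(config.seed, 3)
        noise = rng.standard_normal(movie.shape, dtype=np.float32)
        movie += (background_f0 * pixel_noise_sd) * noise

    return FluorescenceMovie(movie, config.frame_rate_hz, px, y_offset_um=y0_um)
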