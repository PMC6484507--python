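"""Synchronization of OHC activity around GER Ca2+ waves.

Per wave: pairwise Spearman rank-correlation matrices over a 400-frame
(13.2 s at 30.3 fps) window centred on the wave peak and over a wave-free
background window; Fisher-z-averaged mean coefficient rsavg = tanh(<z>),
z = arctanh(rs); a one-sided Mann-Whitney test for the increase of the
pairwise coefficients during the wave (significant at P < 0.001);
Savitzky-Golay-smoothed trace integrals and their fractional increase with
distance from the wave; and the ordinary-least-squares regression of rsavg
on wave longitudinal extension with its f-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter
import statsmodels.api as sm

WINDOW_FRAMES = 400
ARCTANH_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open [start, end) frame window; always exactly 400 frames
    (shorter recordings reject the window rather than shrinking it)."""

    start_frame: int
    end_frame: int
    kind: str = "wave"               # 'wave' | 'background'

    def __post_init__(self) -> None:
        if self.end_frame - self.start_frame != WINDOW_FRAMES:
            raise ValueError("analysis windows are exactly 400 frames")
        if self.start_frame < 0:
            raise ValueError("window starts before the recording")

    def duration_s(self, frame_rate_hz: float) -> float:
        return (self.end_frame - self.start_frame) / frame_rate_hz

    @property
    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame)


@dataclass
class CorrelationResult:
    r_matrix: np.ndarray             # symmetric, unit diagonal, NaN = undefined
    n_pairs_valid: int
    excluded_pairs: int
    rsavg: Optional[float] = None

    def defined_coefficients(self) -> np.ndarray:
        """Defined upper-triangle coefficients."""
        iu = np.triu_indices_from(self.r_matrix, k=1)
        vals = self.r_matrix[iu]
        return vals[~np.isnan(vals)]


@dataclass
class SyncResult:
    wave_id: int
    correlation: CorrelationResult
    correlation_background: CorrelationResult
    p_increase: float
    significant: bool
    extension_um: Optional[float] = None
    overlapping: bool = False


@dataclass
class ActivityIncrease:
    cell_id: object
    distance_um: float
    integral_wave: float
    integral_background: float
    fractional_increase: Optional[float]


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    p_slope: float                   # regression f-test
    pearson_r: float
    n_points: int


def make_wave_window(peak_frame: int, n_frames_total: int) -> Optional[AnalysisWindow]:
    """400-frame window centred on the wave peak, or None when it would
    leave the recording (the wave is then excluded from the sync analysis)."""
    start = peak_frame - WINDOW_FRAMES // 2
    end = peak_frame + WINDOW_FRAMES // 2
    if start < 0 or end > n_frames_total:
        return None
    return AnalysisWindow(start, end, kind="wave")


def pick_background_window(wave_spans: Sequence[tuple[int, int]],
                           n_frames_total: int) -> Optional[AnalysisWindow]:
    """Earliest 400-frame window free of every wave's [onset, offset] span.

    ``wave_spans`` are half-open frame intervals occupied by detected
    waves. Returns None when no wave-free window exists.
    """
    occupied = np.zeros(n_frames_total, dtype=bool)
    for a, b in wave_spans:
        occupied[max(a, 0):min(b, n_frames_total)] = True
    free = ~occupied
    run = 0
    for i, ok in enumerate(free):
        run = run + 1 if ok else 0
        if run == WINDOW_FRAMES:
            start = i - WINDOW_FRAMES + 1
            return AnalysisWindow(start, start + WINDOW_FRAMES,
                                  kind="background")
    return None


def spearman_matrix(values: np.ndarray, window: Optional[AnalysisWindow] = None,
                    window_detrend: bool = False) -> CorrelationResult:
    """Pairwise Spearman matrix over the window (whole input when None).

    Ties get average ranks. Pairs involving a trace that is constant
    in-window are undefined (NaN) and counted in ``excluded_pairs``. The
    diagonal is 1. With ``window_detrend`` a per-trace least-squares line
    is removed inside the window before ranking, so slow shared trends
    (residual bleaching, detrending leakage) do not inflate every pair.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    seg = values if window is None else values[:, window.slice]
    if window_detrend:
        x = np.arange(seg.shape[1], dtype=float)
        x = x - x.mean()
        slope = (seg @ x) / (x @ x)
        seg = seg - slope[:, None] * x[None, :] - seg.mean(axis=1, keepdims=True)
    n = seg.shape[0]
    constant = np.ptp(seg, axis=1) == 0
    ranks = np.apply_along_axis(stats.rankdata, 1, seg)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(ranks)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    iu = np.triu_indices(n, k=1)
    upper = r[iu]
    excluded = int(np.isnan(upper).sum())
    return CorrelationResult(r_matrix=r, n_pairs_valid=upper.size - excluded,
                             excluded_pairs=excluded)


def fisher_average(r_matrix: np.ndarray) -> float:
    """rsavg = tanh(mean arctanh(rs)) over defined upper-triangle pairs.

    |rs| is clipped to 1 - 1e-7 before arctanh. Raises when no pair is
    defined.
    """
    r_matrix = np.asarray(r_matrix, dtype=float)
    iu = np.triu_indices_from(r_matrix, k=1)
    vals = r_matrix[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("rsavg undefined: no valid pairs")
    z = np.arctanh(np.clip(vals, -ARCTANH_CLIP, ARCTANH_CLIP))
    return float(np.tanh(z.mean()))


def test_sync_increase(wave_result: CorrelationResult,
                       background_result: CorrelationResult,
                       alpha: float = 0.001) -> tuple[float, bool]:
    """One-sided Mann-Whitney U: are wave-window coefficients greater than
    background-window coefficients? Returns (p, significant at alpha)."""
    a = wave_result.defined_coefficients()
    b = background_result.defined_coefficients()
    if a.size == 0 or b.size == 0:
        raise ValueError("sync test undefined: a window has no valid pairs")
    res = stats.mannwhitneyu(a, b, alternative="greater")
    return float(res.pvalue), bool(res.pvalue < alpha)


def trace_integral(trace: np.ndarray, window: AnalysisWindow,
                   frame_rate_hz: float,
                   savgol_window: int = 11, savgol_order: int = 1) -> float:
    """Integral of the smoothed dF/F0 trace over the window (dF/F0 * s).

    The trace is Savitzky-Golay smoothed (length 11, order 1, i.e. an
    11-point moving average) before summation / frame rate.
    """
    trace = np.asarray(trace, dtype=float)
    if window.end_frame > trace.size:
        raise ValueError("window longer than the trace")
    smoothed = savgol_filter(trace, savgol_window, savgol_order)
    return float(smoothed[window.slice].sum() / frame_rate_hz)


def distance_to_mask_um(cell_xy_um: tuple[float, float], mask: np.ndarray,
                        pixel_size_um: float, y_offset_um: float = 0.0) -> float:
    """Euclidean distance (um) from a cell centre to the nearest wave-mask
    pixel centre; 0 if the centre falls inside the mask."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise ValueError("empty mask")
    px_x = (xs + 0.5) * pixel_size_um
    px_y = y_offset_um + (ys + 0.5) * pixel_size_um
    d = np.hypot(px_x - cell_xy_um[0], px_y - cell_xy_um[1])
    dmin = float(d.min())
    return 0.0 if dmin <= pixel_size_um * np.sqrt(0.5) else dmin


DEFAULT_DISTANCE_BINS = (0.0, 50.0, 100.0, 150.0, np.inf)


def activity_increase_by_distance(dff: np.ndarray, cell_ids: Sequence,
                                  distances_um: np.ndarray,
                                  wave_window: AnalysisWindow,
                                  background_window: AnalysisWindow,
                                  frame_rate_hz: float,
                                  bin_edges_um: Sequence[float] = DEFAULT_DISTANCE_BINS,
                                  ) -> tuple[list[ActivityIncrease], pd.DataFrame]:
    """Per-cell fractional integral increase and distance-binned means.

    fractional_increase = (I_wave - I_background) / |I_background|; cells
    with a zero background integral are excluded (fraction None) and do not
    enter the binned means.
    """
    dff = np.asarray(dff, dtype=float)
    increases: list[ActivityIncrease] = []
    for k, cid in enumerate(cell_ids):
        iw = trace_integral(dff[k], wave_window, frame_rate_hz)
        ib = trace_integral(dff[k], background_window, frame_rate_hz)
        frac = (iw - ib) / abs(ib) if ib != 0 else None
        increases.append(ActivityIncrease(cid, float(distances_um[k]), iw, ib, frac))
    rows = []
    edges = list(bin_edges_um)
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals = [a.fractional_increase for a in increases
                if a.fractional_increase is not None and lo <= a.distance_um < hi]
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "bin_lo_um": lo, "bin_hi_um": hi, "n": vals.size,
            "mean": vals.mean() if vals.size else np.nan,
            "se": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
        })
    return increases, pd.DataFrame(rows)


def regress_sync_vs_extension(extensions_um: np.ndarray,
                              rsavg: np.ndarray) -> RegressionResult:
    """OLS of rsavg on longitudinal wave extension; p from the regression
    f-test; slope in um^-1."""
    x = np.asarray(extensions_um, dtype=float)
    y = np.asarray(rsavg, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: all extensions equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    pearson = float(stats.pearsonr(x, y).statistic)
    return RegressionResult(slope=float(model.params[1]),
                            slope_se=float(model.bse[1]),
                            intercept=float(model.params[0]),
                            p_slope=float(model.f_pvalue),
                            pearson_r=pearson,
                            n_points=int(x.size))


def compare_wave_size_classes(increases_small: Sequence[float],
                              increases_large: Sequence[float],
                              ) -> dict:
    """Welch t-test of per-wave mean OHC integral increases: small (< 75 um)
    vs large (> 150 um) waves. A 75 um wave belongs to neither class."""
    a = np.asarray(list(increases_small), dtype=float)
    b = np.asarray(list(increases_large), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both wave-size classes must be nonempty")
    t = stats.ttest_ind(b, a, equal_var=False)
    return {"mean_small": float(a.mean()), "mean_large": float(b.mean()),
            "t": float(t.statistic), "p": float(t.pvalue),
            "n_small": int(a.size), "n_large": int(b.size)}


SMALL_WAVE_MAX_UM = 75.0
LARGE_WAVE_MIN_UM = 150.0


def wave_size_class(extension_um: float) -> Optional[str]:
    """'small' (< 75 um), 'large' (> 150 um) or None (strict inequalities)."""
    if extension_um < SMALL_WAVE_MAX_UM:
        return "small"
    if extension_um > LARGE_WAVE_MIN_UM:
        return "large"
    return None
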