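"""Movie -> per-cell dF/F0 traces.

Stages: integer-pixel translation registration against the first frame,
drift-based rejection, ROI pixel averaging over 3.7 um squares centred on
each OHC, and dF/F0 normalization against the fluorescence at the onset of
the recording.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .containers import CellMap, FluorescenceMovie, TraceMatrix
from .geometry import roi_side_px


def register_translation(movie: FluorescenceMovie, max_shift_px: int = 20,
                         ) -> tuple[FluorescenceMovie, np.ndarray]:
    """Align every frame to the first by integer-pixel cross-correlation.

    Returns the registered movie and the per-frame (dx, dy) *corrective*
    shifts that were applied (a frame whose content drifted +3 px in x is
    reported as (-3, 0)). The peak search is restricted to ``max_shift_px``
    in each direction, so pure-noise movies return bounded shifts instead
    of arbitrary ones.
    """
    frames = np.asarray(movie.frames, dtype=float)
    n, h, w = frames.shape
    if n < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = frames[0] - frames[0].mean()
    f_ref = np.conj(np.fft.rfft2(ref))
    shifts = np.zeros((n, 2), dtype=int)
    out = frames.copy()
    r = int(max_shift_px)
    lags = np.arange(-r, r + 1)
    for i in range(1, n):
        cur = frames[i] - frames[i].mean()
        corr = np.fft.irfft2(np.fft.rfft2(cur) * f_ref, s=(h, w))
        # admissible circular lags: dy, dx in [-r, r]
        block = corr[np.ix_(lags % h, lags % w)]
        iy, ix = np.unravel_index(np.argmax(block), block.shape)
        dy, dx = -int(lags[iy]), -int(lags[ix])   # corrective shift
        shifts[i] = (dx, dy)
        if dx or dy:
            out[i] = ndimage.shift(frames[i], shift=(dy, dx), order=0,
                                   mode="nearest")
    reg = FluorescenceMovie(out, movie.frame_rate_hz, movie.pixel_size_um,
                            movie.y_offset_um)
    return reg, shifts


def flag_drift(shifts: np.ndarray, max_drift_px: float = 8.0) -> bool:
    """True (discard the recording) iff any |shift component| exceeds
    ``max_drift_px`` (strict inequality; default 8 px ~ 2 um)."""
    shifts = np.asarray(shifts)
    if shifts.size == 0:
        return False
    return bool(np.abs(shifts).max() > max_drift_px)


def extract_roi_traces(movie: FluorescenceMovie, cell_map: CellMap,
                       roi_side_um: float = 3.7) -> TraceMatrix:
    """Per-cell traces as unweighted pixel means over square ROIs.

    The ROI side is converted to pixels by rounding half-up; ROIs are
    clipped (not rejected) at frame edges. A cell whose centre falls
    outside the frame raises an error naming the cell.
    """
    px = movie.pixel_size_um
    h, w = movie.shape_px
    side = roi_side_px(roi_side_um, px)
    half = side // 2
    frames = np.asarray(movie.frames, dtype=float)
    n_cells = cell_map.n_cells
    values = np.empty((n_cells, movie.n_frames))
    ids = cell_map.cells["id"].tolist()
    for k, (x_um, y_um) in enumerate(cell_map.positions()):
        cx = int(round(x_um / px - 0.5))
        cy = int(round((y_um - movie.y_offset_um) / px - 0.5))
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"cell {ids[k]!r} centre lies outside the frame")
        x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, w)
        y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, h)
        values[k] = frames[:, y_lo:y_hi, x_lo:x_hi].mean(axis=(1, 2))
    return TraceMatrix(values, movie.frame_rate_hz, units="raw",
                       cells=cell_map.cells.reset_index(drop=True))


def compute_dff(traces: TraceMatrix, f0_n_frames: int = 10) -> TraceMatrix:
    """dF/F0 with F0 = per-cell mean of the first ``f0_n_frames`` frames.

    ``f0_n_frames=1`` reproduces the literal "fluorescence at the onset of
    the recording"; the default of 10 trades that for noise robustness.
    """
    if traces.units != "raw":
        raise ValueError("compute_dff expects raw traces")
    if f0_n_frames < 1:
        raise ValueError("f0_n_frames must be >= 1")
    if f0_n_frames > traces.n_frames:
        raise ValueError("f0 window longer than the recording")
    f = traces.values
    f0 = f[:, :f0_n_frames].mean(axis=1)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        ids = (traces.cells["id"].iloc[bad].tolist()
               if traces.cells is not None else bad.tolist())
        raise ValueError(f"nonpositive F0 for cells {ids}")
    dff = (f - f0[:, None]) / f0[:, None]
    return TraceMatrix(dff, traces.frame_rate_hz, units="dff", cells=traces.cells)


def movie_dff(movie: FluorescenceMovie, f0_n_frames: int = 10) -> FluorescenceMovie:
    """Per-pixel dF/F0 movie with F0 = mean of the first ``f0_n_frames``
    frames. Pixels with nonpositive F0 raise."""
    if f0_n_frames < 1 or f0_n_frames > movie.n_frames:
        raise ValueError("invalid f0_n_frames")
    frames = np.asarray(movie.frames)
    if frames.dtype not in (np.float32, np.float64):
        frames = frames.astype(np.float32)
    f0 = frames[:f0_n_frames].mean(axis=0, dtype=np.float64).astype(frames.dtype)
    if (f0 <= 0).any():
        raise ValueError("nonpositive per-pixel F0")
    dff = (frames - f0[None]) / f0[None]
    return FluorescenceMovie(dff, movie.frame_rate_hz, movie.pixel_size_um,
                             movie.y_offset_um)
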