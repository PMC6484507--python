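"""Detection and measurement of GER Ca2+ waves in dF/F0 movies.

A wave is a spatiotemporal connected component of pixels whose dF/F0
exceeds k standard deviations of the per-pixel baseline noise (k = 5,
matching the onset rule used for wave timing), restricted to the GER band,
with a peak footprint of at least ``min_area_um2``. Events whose first
suprathreshold footprint touches the field edge are excluded (waves must
initiate inside the field of view); events whose maximal footprint touches
the longitudinal edges are kept but marked extension-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .containers import FluorescenceMovie


@dataclass
class WaveEvent:
    onset_frame: int
    peak_frame: int
    mask: np.ndarray                 # 2-D boolean footprint at maximal extension
    extension_um: float              # longitudinal extent of the mask
    mean_trace: np.ndarray           # mask-averaged dF/F0 per frame
    amplitude: float                 # max of mean_trace
    extension_censored: bool = False
    mask_bbox_px: tuple[int, int, int, int] = (0, 0, 0, 0)  # x0, x1, y0, y1 (incl.)

    def __post_init__(self) -> None:
        if self.onset_frame > self.peak_frame:
            raise ValueError("onset_frame must be <= peak_frame")
        if not np.asarray(self.mask).any():
            raise ValueError("wave mask must be nonempty")


@dataclass
class WaveCatalog:
    events: list[WaveEvent]
    duration_s: float

    @property
    def events_per_min(self) -> float:
        return 60.0 * len(self.events) / self.duration_s


def measure_extension(mask: np.ndarray, pixel_size_um: float) -> float:
    """Longitudinal (x) extent of a footprint: bounding-box width in um.

    A single-pixel mask spans one pixel: (max_x - min_x + 1) * pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    xs = np.nonzero(mask.any(axis=0))[0]
    if xs.size == 0:
        raise ValueError("empty mask")
    return float((xs.max() - xs.min() + 1) * pixel_size_um)


def detect_waves(movie_dff: FluorescenceMovie,
                 ger_band_um: Optional[tuple[float, float]] = None,
                 k_sigma: float = 5.0,
                 min_area_um2: float = 100.0,
                 baseline_n_frames: int = 100,
                 smooth_sigma_px: float = 1.0,
                 edge_margin_px: int = 3) -> WaveCatalog:
    """Segment wave events from a dF/F0 movie.

    The per-pixel baseline mean and SD come from a wave-free prefix of
    ``baseline_n_frames`` frames. Candidate pixels are spatially smoothed
    dF/F0 above ``k_sigma`` baseline SDs within the GER band; events are
    8-connected in space with 1-frame temporal adjacency.
    """
    frames = np.asarray(movie_dff.frames)
    if frames.dtype not in (np.float32, np.float64):
        frames = frames.astype(np.float32)
    n, h, w = frames.shape
    px = movie_dff.pixel_size_um
    if baseline_n_frames < 2 or baseline_n_frames >= n:
        raise ValueError("baseline_n_frames must be in [2, n_frames)")

    # GER-band row selection in this movie's coordinates
    if ger_band_um is not None:
        y_lo, y_hi = ger_band_um
        rows_um = movie_dff.y_offset_um + (np.arange(h) + 0.5) * px
        band = (rows_um >= y_lo) & (rows_um <= y_hi)
        if not band.any():
            raise ValueError("GER band does not intersect the movie")
    else:
        band = np.ones(h, dtype=bool)

    base = frames[:baseline_n_frames]
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-12)

    z = (frames - mu[None]) / sd[None]
    if smooth_sigma_px > 0:
        z = ndimage.gaussian_filter(z, (0.0, smooth_sigma_px, smooth_sigma_px))

    above = z > k_sigma
    above[:, ~band, :] = False

    structure = np.ones((3, 3, 3), dtype=bool)   # 8-connected + 1-frame adjacency
    labels, n_lab = ndimage.label(above, structure=structure)
    events: list[WaveEvent] = []
    min_area_px = min_area_um2 / (px * px)
    voxel_counts = np.bincount(labels.ravel(), minlength=n_lab + 1)
    objects = ndimage.find_objects(labels)
    for lab in range(1, n_lab + 1):
        if voxel_counts[lab] < min_area_px:      # cannot reach the peak area
            continue
        sl = objects[lab - 1]
        comp = labels[sl] == lab
        area_per_frame = comp.sum(axis=(1, 2))
        if area_per_frame.max() < min_area_px:
            continue
        t_off = sl[0].start
        y_off, x_off = sl[1].start, sl[2].start
        active = np.nonzero(area_per_frame)[0]
        onset_frame = int(active[0] + t_off)
        # initiation inside the field: a wave entering from outside first
        # appears as a sliver hugging an edge, so reject events whose first
        # footprint centroid lies within edge_margin_px of a frame border
        fy, fx = np.nonzero(comp[active[0]])
        cx, cy = fx.mean() + x_off, fy.mean() + y_off
        if (cx < edge_margin_px or cx > w - 1 - edge_margin_px
                or cy < edge_margin_px or cy > h - 1 - edge_margin_px):
            continue
        peak_area_frame = int(np.argmax(area_per_frame))
        mask = np.zeros((h, w), dtype=bool)
        mask[sl[1], sl[2]] = comp[peak_area_frame]
        censored = bool(mask[:, 0].any() or mask[:, -1].any())
        mean_trace = frames[:, mask].mean(axis=1)
        span = active + t_off                         # frames the event occupies
        peak_frame = int(span[np.argmax(mean_trace[span])])
        ys, xs = np.nonzero(mask)
        events.append(WaveEvent(
            onset_frame=onset_frame,
            peak_frame=peak_frame,
            mask=mask,
            extension_um=measure_extension(mask, px),
            mean_trace=mean_trace,
            amplitude=float(mean_trace.max()),
            extension_censored=censored,
            mask_bbox_px=(int(xs.min()), int(xs.max()),
                          int(ys.min()), int(ys.max())),
        ))
    events.sort(key=lambda e: e.onset_frame)
    return WaveCatalog(events=events, duration_s=n / movie_dff.frame_rate_hz)


def wave_onset(mean_trace: np.ndarray,
               baseline_window: tuple[int, int],
               event_start_frame: Optional[int] = None,
               k: float = 5.0) -> Optional[int]:
    """First frame whose value exceeds baseline mean + k * baseline SD.

    ``baseline_window`` is a half-open [start, stop) frame range that must
    be wave-free; if ``event_start_frame`` is given and the baseline window
    reaches into it, an error is raised. Returns None if the trace never
    crosses the threshold.
    """
    trace = np.asarray(mean_trace, dtype=float)
    b0, b1 = baseline_window
    if not (0 <= b0 < b1 <= trace.size):
        raise ValueError("invalid baseline window")
    if event_start_frame is not None and b1 > event_start_frame:
        raise ValueError("baseline window overlaps the event")
    mu = trace[b0:b1].mean()
    sd = trace[b0:b1].std(ddof=1)
    crossing = np.nonzero(trace > mu + k * sd)[0]
    after = crossing[crossing >= b1]
    return int(after[0]) if after.size else None


def propagation_delay(onset_source_frame: Optional[int],
                      onset_target_frame: Optional[int],
                      frame_rate_hz: float) -> float:
    """Radial propagation delay in seconds (may be negative; reported as-is).

    Raises if either onset is undefined.
    """
    if onset_source_frame is None or onset_target_frame is None:
        raise ValueError("propagation delay undefined: missing onset")
    return (onset_target_frame - onset_source_frame) / frame_rate_hz
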