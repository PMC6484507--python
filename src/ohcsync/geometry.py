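"""Small geometric conversions shared across the pipeline.

All physical lengths are micrometres; pixel coordinates are 0-based with
pixel (0, 0) at the top-left, x = column = tonotopic (longitudinal) axis.
"""

from __future__ import annotations

import math


def pixel_size_um(field_um: float, n_pixels: int) -> float:
    """Side of one pixel for a square field of view.

    A 125 um field imaged at 512 px gives 0.2441 um/px; the 182 um
    wave-mode field gives 0.3555 um/px.
    """
    if field_um <= 0 or n_pixels < 1:
        raise ValueError("field_um must be > 0 and n_pixels >= 1")
    return field_um / n_pixels


def roi_side_px(roi_side_um: float, pixel_size: float) -> int:
    """Convert an ROI side length to pixels, rounding half-up.

    3.7 um at 0.2441 um/px -> 15 px.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return int(math.floor(roi_side_um / pixel_size + 0.5))


def window_duration_s(n_frames: int, frame_rate_hz: float) -> float:
    """Duration of an analysis window (400 frames at 30.3 fps -> 13.2 s)."""
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    return n_frames / frame_rate_hz


def rect_area_um2(width_um: float, height_um: float) -> float:
    """Area of an axis-aligned rectangle (e.g. a photo-damage target region)."""
    if width_um < 0 or height_um < 0:
        raise ValueError("lengths must be nonnegative")
    return width_um * height_um
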