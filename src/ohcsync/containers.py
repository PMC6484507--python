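"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CellMap:
    """Positions of the outer hair cells in the field of view.

    ``cells`` is a DataFrame with columns ``id`` (unique), ``x_um``
    (tonotopic position), ``y_um`` (radial position) and ``row`` (1-based
    OHC row index). ``ger_band_um`` is the (y_min, y_max) extent of the
    greater epithelial ridge band, when known.
    """

    cells: pd.DataFrame
    field_um: float
    ger_band_um: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        required = {"id", "x_um", "y_um", "row"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell map missing columns: {sorted(missing)}")
        if self.cells["id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if (xy < 0).any() or (xy > self.field_um).any():
            raise ValueError("cell centers must lie inside the field")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def positions(self) -> np.ndarray:
        """(n_cells, 2) array of (x_um, y_um)."""
        return self.cells[["x_um", "y_um"]].to_numpy(float)


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence with acquisition metadata.

    ``units`` is either ``"raw"`` (fluorescence counts) or ``"dff"``
    (dF/F0). ``cells`` carries per-cell metadata aligned with rows of
    ``values``.
    """

    values: np.ndarray
    frame_rate_hz: float
    units: str = "raw"
    cells: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x frames)")
        if not np.isfinite(self.values).all():
            raise ValueError("trace matrix contains non-finite entries")
        if self.units not in ("raw", "dff"):
            raise ValueError("units must be 'raw' or 'dff'")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.cells is not None and len(self.cells) != self.values.shape[0]:
            raise ValueError("cell metadata does not match number of traces")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class FluorescenceMovie:
    """Time x height x width intensity stack.

    Pixel (0, 0) is top-left; x = column index = tonotopic axis. The
    optional ``y_offset_um`` records the physical y of pixel row 0, so a
    movie can cover a horizontal strip of the field (e.g. the GER band).
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    y_offset_um: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a 3-D stack with all dims >= 1")
        if self.pixel_size_um <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixel_size_um and frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
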