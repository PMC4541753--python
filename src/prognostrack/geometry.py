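"""Electrode-grid geometry for high-density surface EMG.

The recording montage is a rectangular adhesive matrix placed over the
lumbar erector spinae, 13 rows (cranio-caudal) by 5 columns (medio-lateral)
with 12.5 mm inter-electrode distance.  Channel (1, 1) sits at the cranial,
medial corner and defines the coordinate origin; positions are expressed in
centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular electrode grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions.  Default 13 x 5.
    inter_electrode_distance : float
        Electrode pitch in cm (default 1.25 cm = 12.5 mm).
    """

    n_rows: int = 13
    n_cols: int = 5
    inter_electrode_distance: float = 1.25

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.inter_electrode_distance > 0:
            raise ValueError("inter-electrode distance must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def row_extent_cm(self) -> float:
        return (self.n_rows - 1) * self.inter_electrode_distance

    @property
    def col_extent_cm(self) -> float:
        return (self.n_cols - 1) * self.inter_electrode_distance

    def channel_coordinates(self) -> np.ndarray:
        """(n_channels, 2) array of (row_cm, col_cm), channel-major by row.

        Channel index k = (i - 1) * n_cols + (j - 1) for grid position
        (i, j), 1-based; coordinate of (i, j) is ((i-1)*d, (j-1)*d).
        """
        d = self.inter_electrode_distance
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return np.column_stack([rows.ravel() * d, cols.ravel() * d]).astype(float)

    def contains(self, row_cm: float, col_cm: float, margin: float = 0.0) -> bool:
        """Whether a point lies inside the grid bounding box (with margin)."""
        return (
            margin - 1e-12 <= row_cm <= self.row_extent_cm - margin + 1e-12
            and margin - 1e-12 <= col_cm <= self.col_extent_cm - margin + 1e-12
        )
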