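"""Cross-cell intensity normalization.

Detected CCP intensities vary between cells (expression level, illumination).
Each cell's intensity distribution is matched to a reference distribution —
the median cumulative distribution across cells — by a single multiplicative
scale factor that minimizes the mean squared error between the scaled cell
distribution and the reference.

"Distribution" is operationalized as the empirical quantile table on a fixed
percentile grid (default 1..99), so the MSE is computed over matched
quantiles and the optimal scale has the closed form

    s* = sum_q Q_ref(q) Q_cell(q) / sum_q Q_cell(q)^2.

Normalization is per channel, independently, unless a caller reuses the
master-channel factor explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellIntensitySet",
    "DEFAULT_QUANTILE_GRID",
    "build_reference",
    "fit_scale",
    "normalize_cells",
]

DEFAULT_QUANTILE_GRID = np.arange(1, 100)  # percentiles 1..99

MIN_INTENSITIES = 20


@dataclass
class CellIntensitySet:
    """One cell's detection amplitudes for a single channel."""

    cell_id: str
    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, float)
        if self.intensities.size < MIN_INTENSITIES:
            raise ValueError(
                f"cell {self.cell_id!r}: need >= {MIN_INTENSITIES} intensities, "
                f"got {self.intensities.size}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite intensities")

    def quantiles(self, grid=DEFAULT_QUANTILE_GRID) -> np.ndarray:
        return np.percentile(self.intensities, grid)


def build_reference(cells: list[CellIntensitySet],
                    grid=DEFAULT_QUANTILE_GRID) -> np.ndarray:
    """Median-across-cells quantile table on the fixed percentile grid.

    At each grid percentile the reference value is the median over cells of
    that cell's empirical quantile; the result is non-decreasing because each
    per-cell quantile table is.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells to build a reference")
    q = np.stack([c.quantiles(grid) for c in cells])
    return np.median(q, axis=0)


def fit_scale(cell: CellIntensitySet, reference: np.ndarray,
              grid=DEFAULT_QUANTILE_GRID) -> float:
    """MSE-optimal multiplicative scale matching a cell to the reference.

    Closed form of argmin_{s>0} sum_q (s Q_cell(q) - Q_ref(q))^2.
    """
    qc = cell.quantiles(grid)
    reference = np.asarray(reference, float)
    if reference.shape != qc.shape:
        raise ValueError("reference built on a different quantile grid")
    denom = float(qc @ qc)
    if denom == 0:
        raise ValueError(f"cell {cell.cell_id!r}: all-zero intensities")
    return float(reference @ qc) / denom


def normalize_cells(cells: list[CellIntensitySet],
                    grid=DEFAULT_QUANTILE_GRID) -> pd.DataFrame:
    """Build the reference and scale every cell onto it.

    Returns a table (cell_id, scale, n) where ``scale`` multiplies that
    cell's intensities to place them on the reference distribution.
    """
    ref = build_reference(cells, grid)
    rows = [
        {"cell_id": c.cell_id, "scale": fit_scale(c, ref, grid),
         "n": c.intensities.size}
        for c in cells
    ]
    return pd.DataFrame(rows, columns=["cell_id", "scale", "n"])
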