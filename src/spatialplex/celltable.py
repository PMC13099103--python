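"""Per-sample cell table: coordinates, marker intensities, and labels.

The canonical in-memory container for one tissue sample is a thin wrapper
around a :class:`pandas.DataFrame` with one row per segmented cell.  Required
columns are ``cell_id``, ``x_px``, ``y_px`` and one column per marker; optional
annotation columns (``true_type``, ``zone``, cluster labels, ...) ride along
untouched.  Coordinates are 0-based pixel centroids; the physical scale is
carried by ``pixel_size`` (µm per pixel, default 0.45).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_PIXEL_SIZE = 0.45

#: columns that are never interpreted as markers
RESERVED_COLUMNS = (
    "cell_id",
    "x_px",
    "y_px",
    "true_type",
    "zone",
    "sample_id",
    "planted",
    "global_label",
    "broad_type",
    "subclass_label",
    "subtype",
    "excluded",
    "cell_type",
)


@dataclass
class CellTable:
    """One sample's cells with coordinates, marker intensities and labels."""

    data: pd.DataFrame
    markers: list[str]
    pixel_size: float = DEFAULT_PIXEL_SIZE
    sample_id: str = "sample"
    field_shape: tuple[int, int] | None = None  # (width, height) in pixels

    def __post_init__(self) -> None:
        missing = [c for c in ("cell_id", "x_px", "y_px") if c not in self.data.columns]
        if missing:
            raise ValueError(f"cell table is missing required columns: {missing}")
        absent = [m for m in self.markers if m not in self.data.columns]
        if absent:
            raise ValueError(f"marker columns absent from table: {absent}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel coordinates."""
        return self.data[["x_px", "y_px"]].to_numpy(dtype=float)

    @property
    def intensities(self) -> pd.DataFrame:
        """Marker intensity matrix (cells x markers)."""
        return self.data[self.markers]

    def coords_of(self, cell_type: str, type_col: str = "true_type") -> np.ndarray:
        mask = self.data[type_col] == cell_type
        return self.data.loc[mask, ["x_px", "y_px"]].to_numpy(dtype=float)

    def types(self, type_col: str = "true_type") -> list[str]:
        return sorted(self.data[type_col].dropna().unique().tolist())

    def copy(self) -> "CellTable":
        return CellTable(
            data=self.data.copy(),
            markers=list(self.markers),
            pixel_size=self.pixel_size,
            sample_id=self.sample_id,
            field_shape=self.field_shape,
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        markers: Sequence[str] | None = None,
        pixel_size: float = DEFAULT_PIXEL_SIZE,
        sample_id: str = "sample",
        field_shape: tuple[int, int] | None = None,
    ) -> "CellTable":
        if markers is None:
            markers = [c for c in df.columns if c not in RESERVED_COLUMNS]
        return cls(df, list(markers), pixel_size, sample_id, field_shape)


def read_cell_table(
    path: str | Path,
    markers: Sequence[str] | None = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    panel: Sequence[str] | None = None,
) -> CellTable:
    """Read and validate a cell table CSV.

    Parameters
    ----------
    path:
        CSV with at least ``x_px``/``y_px`` (or ``x``/``y``) and one marker
        column.  ``cell_id`` is synthesized from the row index if absent.
    markers:
        Explicit marker list; inferred from non-reserved columns if omitted.
    panel:
        If given, marker names are checked against this panel and unknown
        markers rejected.

    Raises
    ------
    ValueError
        Missing coordinates, or non-numeric / NaN intensities (the offending
        row index is reported).
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns={"x": "x_px", "y": "y_px"})
    if "x_px" not in df.columns or "y_px" not in df.columns:
        raise ValueError(f"{path.name}: missing x/y coordinate columns")
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", np.arange(len(df)))
    if markers is None:
        markers = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if panel is not None:
        unknown = [m for m in markers if m not in set(panel)]
        if unknown:
            raise ValueError(f"{path.name}: markers not in panel: {unknown}")
    for m in list(markers) + ["x_px", "y_px"]:
        col = pd.to_numeric(df[m], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric or missing value in column {m!r} "
                f"at row(s) {bad[:5].tolist()}"
            )
        df[m] = col
    return CellTable.from_dataframe(
        df, markers=markers, pixel_size=pixel_size, sample_id=path.stem
    )
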