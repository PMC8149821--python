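"""Shared domain types and table/mask I/O.

Conventions
-----------
* Lateral coordinates (``x_um``, ``y_um``) are in micrometres, axial
  coordinates (``z_nm``) in nanometres, time in seconds.
* Frame indices are 0-based; the time of frame ``f`` is ``f * frame_interval``.
* Rasters (FA label images, cell masks) are row-major with row 0 at the
  *bottom*: a point ``(x, y)`` in µm maps to
  ``row = floor((y - origin_y) / pixel_size)``,
  ``col = floor((x - origin_x) / pixel_size)`` (pixel-center convention is
  irrelevant for membership because the mapping floors to the containing
  pixel).  TIFF files on disk follow the usual image convention (row 0 on
  top); :meth:`RegionMaskSet.to_tiff` / :meth:`RegionMaskSet.from_tiff`
  flip accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("sptfa")

MANDATORY_COLUMNS = ("track_id", "frame", "x_um", "y_um")
OPTIONAL_COLUMNS = ("z_nm", "photons")


class TableValidationError(ValueError):
    """Raised when a localization table violates its contract."""


@dataclass
class Trajectory:
    """One molecule's time-ordered positions.

    Frames are strictly increasing but not necessarily consecutive:
    blinking gaps are preserved and all lag computations use frame-index
    differences, never array positions.
    """

    id: object
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    frame_interval: float  # s
    z: Optional[np.ndarray] = None  # nm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("trajectory needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Span from first to last frame, in seconds."""
        return (self.frames[-1] - self.frames[0]) * self.frame_interval


@dataclass
class LocalizationTable:
    """Flat localization/track table plus acquisition metadata."""

    df: pd.DataFrame
    frame_interval: float = 0.02
    pixel_size: Optional[float] = None
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise TableValidationError(f"missing mandatory columns: {missing}")
        for col in ("x_um", "y_um"):
            if not np.issubdtype(self.df[col].dtype, np.number):
                raise TableValidationError(f"non-numeric column {col!r}")
            if not np.all(np.isfinite(self.df[col].to_numpy(dtype=float))):
                raise TableValidationError(f"non-finite values in {col!r}")
        if self.df.duplicated(subset=["track_id", "frame"]).any():
            raise TableValidationError("duplicate (track_id, frame) pairs")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_z(self) -> bool:
        return "z_nm" in self.df.columns

    def write(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def read_localizations(
    path,
    sep: str = ",",
    frame_interval: float = 0.02,
    pixel_size: Optional[float] = None,
) -> LocalizationTable:
    """Read a delimited localization table with a named header.

    Mandatory columns: ``track_id, frame, x_um, y_um``.  Unknown columns
    are preserved in the frame and listed under ``extra_metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    extra = [c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    table = LocalizationTable(
        df=df,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        extra_metadata={"extra_columns": extra},
    )
    return table


def write_localizations(table: LocalizationTable, path, sep: str = ",") -> None:
    table.write(path, sep=sep)


def build_trajectories(table: LocalizationTable) -> list[Trajectory]:
    """Group a table into frame-sorted trajectories, one per track id.

    Tracks with fewer than 2 localizations are dropped with a warning;
    blinking gaps are preserved as missing frame indices.
    """
    out: list[Trajectory] = []
    n_dropped = 0
    for tid, grp in table.df.groupby("track_id", sort=True):
        if len(grp) < 2:
            n_dropped += 1
            continue
        grp = grp.sort_values("frame")
        z = grp["z_nm"].to_numpy(dtype=float) if "z_nm" in grp.columns else None
        out.append(
            Trajectory(
                id=tid,
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                frame_interval=table.frame_interval,
                z=z,
            )
        )
    if n_dropped:
        logger.warning("dropped %d tracks with < 2 localizations", n_dropped)
    return out


@dataclass
class RegionMaskSet:
    """FA label raster + cell outline raster sharing one pixel grid."""

    fa_labels: np.ndarray  # int 2D, 0 = outside any FA
    cell_mask: np.ndarray  # bool 2D
    pixel_size: float  # µm
    origin: tuple[float, float] = (0.0, 0.0)  # µm, lower-left corner

    def __post_init__(self) -> None:
        self.fa_labels = np.asarray(self.fa_labels)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.fa_labels.shape != self.cell_mask.shape:
            raise ValueError("fa_labels and cell_mask must share shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.any((self.fa_labels > 0) & ~self.cell_mask):
            raise ValueError("labeled FA pixels must lie inside cell_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fa_labels.shape

    @property
    def field_size(self) -> tuple[float, float]:
        """(width, height) of the raster in µm."""
        ny, nx = self.shape
        return nx * self.pixel_size, ny * self.pixel_size

    def pixel_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map µm coordinates to (row, col); may be out of bounds."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def _lookup(self, raster: np.ndarray, x, y, fill=0):
        row, col = self.pixel_of(x, y)
        ny, nx = self.shape
        inb = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.full(np.shape(row), fill, dtype=raster.dtype)
        out[inb] = raster[row[inb], col[inb]]
        return out

    def fa_label_at(self, x, y) -> np.ndarray:
        """FA label under each point (0 outside any FA or out of bounds)."""
        return self._lookup(self.fa_labels, x, y, fill=0)

    def in_cell(self, x, y) -> np.ndarray:
        return self._lookup(self.cell_mask, x, y, fill=False)

    def to_tiff(self, fa_path, cell_path=None) -> None:
        tifffile.imwrite(fa_path, np.flipud(self.fa_labels).astype(np.uint16))
        if cell_path is not None:
            tifffile.imwrite(cell_path, np.flipud(self.cell_mask).astype(np.uint8))

    @classmethod
    def from_tiff(cls, fa_path, cell_path=None, pixel_size: float = 0.16,
                  origin=(0.0, 0.0)) -> "RegionMaskSet":
        fa = np.flipud(tifffile.imread(fa_path)).astype(int)
        if cell_path is not None:
            cell = np.flipud(tifffile.imread(cell_path)).astype(bool)
        else:
            cell = np.ones_like(fa, dtype=bool)
        return cls(fa_labels=fa, cell_mask=cell, pixel_size=pixel_size, origin=origin)


INSIDE_FA = "inside_fa"
OUTSIDE_FA = "outside_fa"


def sort_by_region(
    traj: Trajectory,
    masks: RegionMaskSet,
    inside_threshold: float = 0.5,
) -> Optional[str]:
    """Assign a trajectory to ``inside_fa`` or ``outside_fa``.

    Majority rule: the label is ``inside_fa`` iff the fraction of
    localizations falling on FA pixels is >= ``inside_threshold`` (ties go
    inside).  A trajectory entirely outside the cell mask is excluded and
    ``None`` is returned.
    """
    on_fa = masks.fa_label_at(traj.x, traj.y) > 0
    in_cell = masks.in_cell(traj.x, traj.y)
    if not np.any(in_cell):
        logger.warning("trajectory %s entirely outside cell mask; excluded", traj.id)
        return None
    frac = float(np.mean(on_fa))
    return INSIDE_FA if frac >= inside_threshold else OUTSIDE_FA


def sort_trajectories(
    trajectories: Iterable[Trajectory],
    masks: RegionMaskSet,
    inside_threshold: float = 0.5,
) -> dict[str, list[Trajectory]]:
    """Partition trajectories by region, dropping out-of-cell ones."""
    out = {INSIDE_FA: [], OUTSIDE_FA: []}
    for traj in trajectories:
        label = sort_by_region(traj, masks, inside_threshold)
        if label is not None:
            out[label].append(traj)
    return out
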