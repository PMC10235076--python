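"""Gel/membrane image I/O and lane intensity-profile extraction.

A Southern-blot (or ethidium-bromide gel) image is a single-channel
intensity matrix whose vertical axis is the DNA migration axis: row 0 is
the top of the image, i.e. the gel-well side, and fragment size decreases
down the rows.  Densitometry reduces a manually defined lane (a column
interval) to a one-dimensional profile by summing intensities laterally
across the lane width at every row.  All coordinates are 0-based and
intervals are half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "GelImage",
    "LaneROI",
    "LaneProfile",
    "LANE_ROLES",
    "PROBES",
    "read_gel_image",
    "write_gel_image",
    "extract_profile",
    "write_profiles",
    "read_profiles",
    "write_rois",
    "read_rois",
]

LANE_ROLES = ("ladder-left", "ladder-middle", "ladder-right", "sample")
PROBES = ("host", "symbiont", "none")

ROI_COLUMNS = [
    "lane_id", "membrane_id", "col_start", "col_end",
    "row_start", "row_end", "role", "probe",
]
PROFILE_COLUMNS = ["membrane_id", "lane_id", "role", "probe", "row", "intensity"]


@dataclass(frozen=True)
class GelImage:
    """Single-channel gel image; ``data[r, c]`` with row 0 at the well side."""

    data: np.ndarray
    bit_depth: int
    image_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError(
                f"gel image must be a 2-D single-channel matrix, got ndim={data.ndim}"
            )
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(f"gel image must be at least 2x2, got {data.shape}")
        if np.min(data) < 0:
            raise ValueError("gel image intensities must be non-negative")
        object.__setattr__(self, "data", data)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class LaneROI:
    """Manually drawn lane: a half-open column interval, optional row interval."""

    lane_id: str
    membrane_id: str
    col_start: int
    col_end: int
    row_start: Optional[int] = None
    row_end: Optional[int] = None
    role: str = "sample"
    probe: str = "none"

    def __post_init__(self) -> None:
        if self.col_end <= self.col_start:
            raise ValueError(
                f"lane {self.lane_id}: empty column interval "
                f"[{self.col_start}, {self.col_end})"
            )
        if (self.row_start is None) != (self.row_end is None):
            raise ValueError(f"lane {self.lane_id}: row_start/row_end must be given together")
        if self.row_start is not None and self.row_end <= self.row_start:
            raise ValueError(f"lane {self.lane_id}: empty row interval")
        if self.role not in LANE_ROLES:
            raise ValueError(f"lane {self.lane_id}: unknown role {self.role!r}")
        if self.probe not in PROBES:
            raise ValueError(f"lane {self.lane_id}: unknown probe {self.probe!r}")

    @property
    def center(self) -> float:
        """Lateral (column) center of the lane."""
        return 0.5 * (self.col_start + self.col_end - 1)

    def is_ladder(self) -> bool:
        return self.role.startswith("ladder")


@dataclass
class LaneProfile:
    """Per-row migration-axis intensity of one lane."""

    lane_id: str
    rows: np.ndarray
    intensity: np.ndarray
    role: str = "sample"
    probe: str = "none"
    membrane_id: str = ""

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=int)
        intensity = np.asarray(self.intensity, dtype=float)
        if rows.shape != intensity.shape or rows.ndim != 1:
            raise ValueError("rows and intensity must be 1-D vectors of equal length")
        if rows.size and np.any(np.diff(rows) <= 0):
            raise ValueError("row indices must be strictly increasing")
        if intensity.size and np.min(intensity) < 0:
            raise ValueError(f"lane {self.lane_id}: negative intensity in profile")
        self.rows = rows
        self.intensity = intensity

    def __len__(self) -> int:
        return self.rows.size

    def with_intensity(self, intensity: np.ndarray) -> "LaneProfile":
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def total(self) -> float:
        return float(self.intensity.sum())


def read_gel_image(path: str | Path) -> GelImage:
    """Read a grayscale 8/16-bit TIFF or PNG gel image.

    Multi-channel (color) images are rejected: phosphorimager/gel data is
    single-channel and silently picking a channel would be ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif suffix == ".png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "I;16B", "I;16L"):
                raise ValueError(
                    f"{path.name}: multi-channel image (mode {im.mode}); "
                    "supply a single-channel grayscale image"
                )
            data = np.asarray(im)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got shape {data.shape}"
        )
    bit_depth = data.dtype.itemsize * 8
    return GelImage(data=data, bit_depth=bit_depth, image_id=path.stem)


def write_gel_image(image: GelImage, path: str | Path) -> Path:
    """Write a GelImage as 16-bit (or 8-bit) grayscale TIFF/PNG."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    data = np.asarray(np.round(image.data), dtype=dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        mode = "L" if dtype == np.uint8 else "I;16"
        Image.fromarray(data, mode=mode).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def extract_profile(image: GelImage, roi: LaneROI) -> LaneProfile:
    """Sum image intensities laterally over the ROI's columns at every row."""
    if roi.col_start < 0 or roi.col_end > image.n_cols:
        raise ValueError(
            f"lane {roi.lane_id}: columns [{roi.col_start}, {roi.col_end}) outside "
            f"image width {image.n_cols}"
        )
    row_start = 0 if roi.row_start is None else roi.row_start
    row_end = image.n_rows if roi.row_end is None else roi.row_end
    if row_start < 0 or row_end > image.n_rows:
        raise ValueError(f"lane {roi.lane_id}: rows outside image height {image.n_rows}")
    block = image.data[row_start:row_end, roi.col_start:roi.col_end]
    intensity = block.sum(axis=1, dtype=float)
    return LaneProfile(
        lane_id=roi.lane_id,
        rows=np.arange(row_start, row_end),
        intensity=intensity,
        role=roi.role,
        probe=roi.probe,
        membrane_id=roi.membrane_id,
    )


def write_profiles(profiles: Sequence[LaneProfile], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "membrane_id": p.membrane_id,
            "lane_id": p.lane_id,
            "role": p.role,
            "probe": p.probe,
            "row": p.rows,
            "intensity": p.intensity,
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=PROFILE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> list[LaneProfile]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"membrane_id": str, "lane_id": str})
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: malformed header, missing columns {sorted(missing)}")
    if len(df) and (df["intensity"] < 0).any():
        bad = df.loc[df["intensity"] < 0].iloc[0]
        raise ValueError(
            f"{path.name}: negative intensity for lane {bad['lane_id']} row {bad['row']}"
        )
    profiles = []
    # preserve file order of lanes
    for (membrane_id, lane_id), grp in df.groupby(["membrane_id", "lane_id"], sort=False):
        grp = grp.sort_values("row")
        profiles.append(LaneProfile(
            lane_id=str(lane_id),
            rows=grp["row"].to_numpy(dtype=int),
            intensity=grp["intensity"].to_numpy(dtype=float),
            role=str(grp["role"].iloc[0]),
            probe=str(grp["probe"].iloc[0]),
            membrane_id=str(membrane_id),
        ))
    return profiles


def write_rois(rois: Sequence[LaneROI], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([
        {
            "lane_id": r.lane_id,
            "membrane_id": r.membrane_id,
            "col_start": r.col_start,
            "col_end": r.col_end,
            "row_start": "" if r.row_start is None else r.row_start,
            "row_end": "" if r.row_end is None else r.row_end,
            "role": r.role,
            "probe": r.probe,
        }
        for r in rois
    ], columns=ROI_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_rois(path: str | Path) -> list[LaneROI]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"lane_id": str, "membrane_id": str})
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: malformed header, missing columns {sorted(missing)}")
    rois = []
    for _, row in df.iterrows():
        def _opt(v):
            return None if pd.isna(v) or v == "" else int(v)
        rois.append(LaneROI(
            lane_id=str(row["lane_id"]),
            membrane_id=str(row["membrane_id"]),
            col_start=int(row["col_start"]),
            col_end=int(row["col_end"]),
            row_start=_opt(row["row_start"]),
            row_end=_opt(row["row_end"]),
            role=str(row["role"]),
            probe=str(row["probe"]),
        ))
    return rois
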