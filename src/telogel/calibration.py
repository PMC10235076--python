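"""Molecular-weight ladder calibration of gel migration distance to size.

DNA electrophoresis compresses the high-molecular-weight region of a gel,
so a single log-linear model ``log2(size kb) = a + b * row`` misfits the
whole run length.  The scale is therefore built from two linear segments:
one fitted on the high-MW ladder bands and one on the low-MW bands, glued
at a switch row chosen where the two segments agree best (scale
continuity), constrained to lie where the low segment predicts 8-10 kb.
Sample lanes are assigned to the laterally nearest ladder scale
(left / middle / right ladder lanes on the membrane).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .gelio import LaneProfile, LaneROI

__all__ = [
    "LadderSpec",
    "PeakEntry",
    "PeakSet",
    "PiecewiseScale",
    "BUILTIN_LADDERS",
    "get_ladder",
    "refine_peaks",
    "fit_segment",
    "build_scale",
    "size_at",
    "assign_scale",
    "read_seeds",
    "write_seeds",
]

SWITCH_WINDOW_KB = (8.0, 10.0)
DEFAULT_CONTINUITY_TOL = 0.15  # log2 units, ~11% in size


@dataclass(frozen=True)
class LadderSpec:
    """A ladder's band sizes and the subsets used to fit each scale segment.

    ``hi_fit`` may be empty (single-segment ladder such as the SmartLadder
    run on its own); non-empty fit subsets need at least two sizes.
    """

    name: str
    sizes_kb: tuple[float, ...]
    hi_fit: tuple[float, ...]
    lo_fit: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes_kb)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"ladder {self.name}: band sizes must be strictly decreasing")
        for label, subset in (("hi_fit", self.hi_fit), ("lo_fit", self.lo_fit)):
            if subset and len(subset) < 2:
                raise ValueError(f"ladder {self.name}: {label} needs >= 2 sizes")
            if not set(subset) <= set(sizes):
                raise ValueError(f"ladder {self.name}: {label} not a subset of band sizes")
        if not self.lo_fit:
            raise ValueError(f"ladder {self.name}: lo_fit subset required")
        if self.hi_fit and min(self.hi_fit) < max(self.lo_fit):
            raise ValueError(
                f"ladder {self.name}: hi_fit sizes must not lie below lo_fit sizes"
            )
        object.__setattr__(self, "sizes_kb", sizes)
        object.__setattr__(self, "hi_fit", tuple(float(s) for s in self.hi_fit))
        object.__setattr__(self, "lo_fit", tuple(float(s) for s in self.lo_fit))


# Vendor band lists are configurable data, not hard-coded truth; these are
# the usual catalogue values.  Fit subsets: the high-MW segment uses
# 48.5/20/15 kb, the low-MW segment 10..2 kb.
BUILTIN_LADDERS: dict[str, LadderSpec] = {
    "smartladder": LadderSpec(
        name="smartladder",
        sizes_kb=(10, 8, 6, 5, 4, 3, 2.5, 2, 1.5, 1, 0.8, 0.6, 0.4, 0.2),
        hi_fit=(),
        lo_fit=(10, 8, 6, 5, 4, 3, 2.5, 2),
    ),
    "quickload-1kb-extend": LadderSpec(
        name="quickload-1kb-extend",
        sizes_kb=(48.5, 20, 15, 10, 8, 6, 5, 4, 3, 2.5, 2, 1.5, 1, 0.5),
        hi_fit=(48.5, 20, 15),
        lo_fit=(10, 8, 6, 5, 4, 3, 2.5, 2),
    ),
}


def get_ladder(name_or_path: str | Path) -> LadderSpec:
    """Resolve a built-in ladder name or a JSON ladder-spec file."""
    key = str(name_or_path).lower()
    if key in BUILTIN_LADDERS:
        return BUILTIN_LADDERS[key]
    path = Path(name_or_path)
    if path.exists():
        spec = json.loads(path.read_text())
        return LadderSpec(
            name=spec.get("name", path.stem),
            sizes_kb=tuple(spec["sizes_kb"]),
            hi_fit=tuple(spec.get("hi_fit", ())),
            lo_fit=tuple(spec["lo_fit"]),
        )
    raise ValueError(f"unknown ladder {name_or_path!r} "
                     f"(built-ins: {sorted(BUILTIN_LADDERS)})")


@dataclass(frozen=True)
class PeakEntry:
    size_kb: float
    seed_row: float
    refined_row: float
    intensity: float


@dataclass
class PeakSet:
    """Refined ladder band positions for one ladder lane."""

    lane_id: str
    entries: list[PeakEntry]
    membrane_id: str = ""

    def rows_for(self, sizes: Iterable[float]) -> list[tuple[float, float]]:
        """(size, refined row) pairs for the requested sizes, largest first."""
        out = []
        for s in sorted(sizes, reverse=True):
            match = [e for e in self.entries if np.isclose(e.size_kb, s)]
            if match:
                out.append((s, match[0].refined_row))
        return out


@dataclass
class PiecewiseScale:
    """Two-segment model ``log2(size kb) = a + b * row`` with a switch row.

    Rows above (smaller than) the switch row use the high-MW coefficients,
    rows at/below use the low-MW ones.  ``b < 0`` in both segments: size
    strictly decreases down the gel.
    """

    a_hi: float
    b_hi: float
    a_lo: float
    b_lo: float
    switch_row: float
    switch_size_kb: float
    valid_min_kb: float
    valid_max_kb: float
    ladder_lane_id: str = ""
    continuity_gap_log2: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.b_hi < 0 and self.b_lo < 0):
            raise ValueError("scale slopes must be negative (size decreases down the gel)")
        if not (SWITCH_WINDOW_KB[0] <= self.switch_size_kb <= SWITCH_WINDOW_KB[1]):
            raise ValueError(
                f"switch size {self.switch_size_kb:.3f} kb outside "
                f"{SWITCH_WINDOW_KB} kb window"
            )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "a_hi": self.a_hi, "b_hi": self.b_hi,
            "a_lo": self.a_lo, "b_lo": self.b_lo,
            "switch_row": self.switch_row,
            "switch_size_kb": self.switch_size_kb,
            "valid_min_kb": self.valid_min_kb,
            "valid_max_kb": self.valid_max_kb,
            "ladder_lane_id": self.ladder_lane_id,
            "continuity_gap_log2": self.continuity_gap_log2,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseScale":
        return cls(**d)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PiecewiseScale":
        return cls.from_dict(json.loads(Path(path).read_text()))


def refine_peaks(
    profile: LaneProfile,
    seeds: Sequence[tuple[float, float]],
    window: int = 10,
) -> PeakSet:
    """Snap manually seeded ladder peaks to the local intensity maximum.

    For each (band size kb, seed row), the refined row is the argmax of the
    profile within ``window`` rows of the seed (clipped to the profile
    range).  Ties break toward the seed, then toward the smaller row.
    Refined rows must be strictly increasing as band size decreases.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rows = profile.rows
    lo_row, hi_row = int(rows[0]), int(rows[-1])
    entries = []
    for size_kb, seed in sorted(seeds, key=lambda t: -t[0]):
        seed = int(round(seed))
        if seed < lo_row or seed > hi_row:
            raise ValueError(
                f"lane {profile.lane_id}: seed row {seed} for {size_kb} kb outside "
                f"profile rows [{lo_row}, {hi_row}]"
            )
        w_lo = max(lo_row, seed - window)
        w_hi = min(hi_row, seed + window)
        sel = (rows >= w_lo) & (rows <= w_hi)
        cand_rows = rows[sel]
        cand_int = profile.intensity[sel]
        best = max(
            zip(cand_rows, cand_int),
            key=lambda rc: (rc[1], -abs(rc[0] - seed), -rc[0]),
        )
        entries.append(PeakEntry(
            size_kb=float(size_kb),
            seed_row=float(seed),
            refined_row=float(best[0]),
            intensity=float(best[1]),
        ))
    refined = [e.refined_row for e in entries]  # sorted by decreasing size
    if any(b <= a for a, b in zip(refined, refined[1:])):
        raise ValueError(
            f"lane {profile.lane_id}: refined peak rows not strictly increasing with "
            "decreasing band size — ladder appears mis-seeded"
        )
    return PeakSet(lane_id=profile.lane_id, entries=entries,
                   membrane_id=profile.membrane_id)


def fit_segment(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS fit of log2(size kb) on pixel row; returns (intercept a, slope b)."""
    if len(points) < 2:
        raise ValueError(f"need >= 2 ladder points to fit a segment, got {len(points)}")
    sizes = np.array([p[0] for p in points], dtype=float)
    rows = np.array([p[1] for p in points], dtype=float)
    if np.ptp(rows) == 0:
        raise ValueError("all ladder rows identical; cannot fit a segment")
    X = np.column_stack([np.ones_like(rows), rows])
    coef, *_ = np.linalg.lstsq(X, np.log2(sizes), rcond=None)
    return float(coef[0]), float(coef[1])


def _fit_points(peaks: PeakSet, subset: Sequence[float], label: str) -> list[tuple[float, float]]:
    points = peaks.rows_for(subset)
    if len(points) < len(subset):
        missing = sorted(set(subset) - {s for s, _ in points}, reverse=True)
        if len(points) < 2:
            raise ValueError(
                f"lane {peaks.lane_id}: only {len(points)} of the {label} fit bands "
                f"present (missing {missing}); need >= 2"
            )
        warnings.warn(
            f"lane {peaks.lane_id}: {label} fit bands missing {missing}; "
            f"fitting on the {len(points)} remaining",
            stacklevel=3,
        )
    return points


def build_scale(
    peaks: PeakSet,
    ladder: LadderSpec,
    continuity_tolerance: float = DEFAULT_CONTINUITY_TOL,
) -> PiecewiseScale:
    """Fit both segments and place the switch row where the scale is most continuous.

    The switch row is the integer row, among rows where the low segment
    predicts a size in the 8-10 kb window, that minimizes the absolute
    log2-size gap between the two segments (ties toward the smaller row).
    """
    flags: list[str] = []
    lo_points = _fit_points(peaks, ladder.lo_fit, "low-MW")
    a_lo, b_lo = fit_segment(lo_points)
    if ladder.hi_fit:
        hi_points = _fit_points(peaks, ladder.hi_fit, "high-MW")
        a_hi, b_hi = fit_segment(hi_points)
    else:
        a_hi, b_hi = a_lo, b_lo
        hi_points = []
        flags.append("single-segment")
    if b_lo >= 0 or b_hi >= 0:
        raise ValueError(
            f"lane {peaks.lane_id}: non-negative migration slope "
            f"(b_hi={b_hi:.4g}, b_lo={b_lo:.4g}); ladder geometry invalid"
        )

    all_rows = [r for _, r in lo_points + hi_points]
    row_lo, row_hi = int(np.floor(min(all_rows))), int(np.ceil(max(all_rows)))
    cand = np.arange(row_lo, row_hi + 1)
    lo_pred_kb = 2.0 ** (a_lo + b_lo * cand)
    in_window = (lo_pred_kb >= SWITCH_WINDOW_KB[0]) & (lo_pred_kb <= SWITCH_WINDOW_KB[1])
    if not np.any(in_window):
        raise ValueError(
            f"lane {peaks.lane_id}: no row where the low segment predicts "
            f"{SWITCH_WINDOW_KB} kb; bad ladder geometry"
        )
    cand = cand[in_window]
    gaps = np.abs((a_hi - a_lo) + (b_hi - b_lo) * cand)
    best = int(np.argmin(gaps))  # argmin returns the first (smallest-row) minimum
    switch_row = float(cand[best])
    gap = float(gaps[best])
    if gap > continuity_tolerance:
        warnings.warn(
            f"lane {peaks.lane_id}: continuity gap {gap:.3f} log2 units at switch row "
            f"{switch_row:.0f} exceeds tolerance {continuity_tolerance}",
            stacklevel=2,
        )
        flags.append("continuity-gap")

    fitted_sizes = [s for s, _ in lo_points + hi_points]
    return PiecewiseScale(
        a_hi=a_hi, b_hi=b_hi, a_lo=a_lo, b_lo=b_lo,
        switch_row=switch_row,
        switch_size_kb=float(2.0 ** (a_lo + b_lo * switch_row)),
        valid_min_kb=float(min(fitted_sizes)),
        valid_max_kb=float(max(fitted_sizes)),
        ladder_lane_id=peaks.lane_id,
        continuity_gap_log2=gap,
        flags=flags,
    )


def size_at(scale: PiecewiseScale, row):
    """Fragment size (kb) at a pixel row; high segment above the switch row."""
    row = np.asarray(row, dtype=float)
    log2_size = np.where(
        row < scale.switch_row,
        scale.a_hi + scale.b_hi * row,
        scale.a_lo + scale.b_lo * row,
    )
    out = 2.0 ** log2_size
    return float(out) if out.ndim == 0 else out


def assign_scale(
    sample_roi: LaneROI,
    scales: Sequence[tuple[PiecewiseScale, float]],
) -> PiecewiseScale:
    """Pick the scale whose ladder lane center is laterally nearest the sample.

    ``scales`` pairs each PiecewiseScale with its ladder lane's lateral
    (column) center.  Ties break toward the leftmost ladder.
    """
    if not scales:
        raise ValueError("no ladder scales available on this membrane")
    center = sample_roi.center
    return min(scales, key=lambda sc: (abs(sc[1] - center), sc[1]))[0]


# -- seed CSV helpers --------------------------------------------------

SEED_COLUMNS = ["membrane_id", "lane_id", "size_kb", "seed_row"]


def write_seeds(seeds: dict[str, Sequence[tuple[float, float]]], path: str | Path,
                membrane_id: str = "") -> Path:
    """Write per-lane (size kb, seed row) pairs as CSV."""
    import pandas as pd

    records = [
        {"membrane_id": membrane_id, "lane_id": lane, "size_kb": s, "seed_row": r}
        for lane, pairs in seeds.items() for s, r in pairs
    ]
    pd.DataFrame(records, columns=SEED_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_seeds(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"lane_id": str})
    missing = set(SEED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["lane_id"]), []).append(
            (float(row["size_kb"]), float(row["seed_row"]))
        )
    return out
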