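"""Telomere-length quantification of a calibrated TRF smear lane.

A probed telomere smear is a continuous intensity distribution along the
lane.  The hybridization signal of a fragment is proportional to the
number of telomeric repeats it carries, i.e. to its length, so raw
intensity over-weights long fragments ("probe number hybridization
bias").  Quantification therefore proceeds:

1. background subtraction (per-lane minimum),
2. pixel row -> fragment size via the piecewise ladder scale,
3. size normalization ``w = I / L`` removing the probe bias,
4. truncation below 2 kb (genomic / interstitial-repeat noise),
5. weighted summary statistics: mean, median, Q1, Q3 and the
   interquartile distance IQ = Q3 - Q1.

The mean telomere length is the classic TRF estimator
``sum(I) / sum(I / L)``, identically the w-weighted mean of L; quantiles
are step quantiles of the normalized weight distribution (the smallest
size whose cumulative weight reaches the quantile).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import PiecewiseScale, size_at
from .gelio import LaneProfile

__all__ = [
    "TLDistribution",
    "TLSummary",
    "QCReport",
    "QuantifyParams",
    "subtract_background",
    "profile_to_distribution",
    "normalize_by_size",
    "truncate_low",
    "summarize",
    "quantify_lane",
    "qc_lane",
    "summaries_to_frame",
]

DEFAULT_MIN_KB = 2.0
DEFAULT_STRIP_RESIDUAL_THRESHOLD = 0.1
DEFAULT_LOW_SIGNAL_FRACTION = 0.02

TL_SUMMARY_COLUMNS = [
    "membrane_id", "lane_id", "probe", "mean_kb", "med_kb", "q1_kb", "q3_kb",
    "iq_kb", "total_signal", "n_rows", "qc_flags",
]


@dataclass
class TLDistribution:
    """Size-indexed intensity distribution of one lane, sorted by size ascending."""

    size_kb: np.ndarray
    raw: np.ndarray
    weight: Optional[np.ndarray] = None  # raw / size after normalize_by_size
    probe: str = "none"
    lane_id: str = ""
    scale_id: str = ""
    n_truncated: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        size = np.asarray(self.size_kb, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        if size.shape != raw.shape or size.ndim != 1:
            raise ValueError("size_kb and raw must be equal-length 1-D vectors")
        if size.size == 0:
            raise ValueError(f"lane {self.lane_id}: empty distribution")
        if np.any(np.diff(size) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.min(raw) < 0:
            raise ValueError("raw intensities must be non-negative")
        self.size_kb = size
        self.raw = raw
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)

    def __len__(self) -> int:
        return self.size_kb.size


@dataclass(frozen=True)
class TLSummary:
    """The five TL distribution parameters of one lane plus bookkeeping."""

    mean_kb: float
    med_kb: float
    q1_kb: float
    q3_kb: float
    iq_kb: float
    total_signal: float
    total_weight: float
    n_rows: int
    lane_id: str = ""
    membrane_id: str = ""
    probe: str = "none"
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.q1_kb <= self.med_kb <= self.q3_kb):
            raise ValueError("quantile ordering violated: Q1 <= med <= Q3")


@dataclass(frozen=True)
class QCReport:
    """Lane quality control; exclusion is always the caller's decision."""

    stripping_residual: float
    signal_total: float
    low_signal: bool
    strip_threshold: float = DEFAULT_STRIP_RESIDUAL_THRESHOLD
    degraded: bool = False
    observer_override: str = ""

    @property
    def strip_pass(self) -> bool:
        return self.stripping_residual <= self.strip_threshold


@dataclass(frozen=True)
class QuantifyParams:
    min_kb: float = DEFAULT_MIN_KB
    low_signal_threshold: float = 0.0   # absolute background-subtracted total
    jacobian_reweight: bool = False     # optional d(size)/d(row) sensitivity switch


def subtract_background(profile: LaneProfile) -> LaneProfile:
    """Level the lane by subtracting its minimum intensity from every row."""
    if len(profile) == 0:
        raise ValueError(f"lane {profile.lane_id}: empty profile")
    return profile.with_intensity(profile.intensity - profile.intensity.min())


def profile_to_distribution(
    profile: LaneProfile,
    scale: PiecewiseScale,
    jacobian_reweight: bool = False,
) -> TLDistribution:
    """Map pixel rows to fragment sizes and re-sort size-ascending.

    Per-row intensities are carried over unchanged (per-pixel treatment, no
    bin-width correction).  With ``jacobian_reweight`` the intensities are
    multiplied by |d size / d row| instead, for sensitivity analysis.
    """
    if len(profile) == 0:
        raise ValueError(f"lane {profile.lane_id}: empty profile")
    sizes = size_at(scale, profile.rows)
    raw = profile.intensity.copy()
    if jacobian_reweight:
        b = np.where(profile.rows < scale.switch_row, scale.b_hi, scale.b_lo)
        raw = raw * np.abs(b) * np.log(2.0) * sizes
    order = np.argsort(sizes)
    flags = []
    if sizes.max() > scale.valid_max_kb or sizes.min() < scale.valid_min_kb:
        flags.append("extrapolated")
    return TLDistribution(
        size_kb=sizes[order],
        raw=raw[order],
        probe=profile.probe,
        lane_id=profile.lane_id,
        scale_id=scale.ladder_lane_id,
        flags=flags,
    )


def normalize_by_size(dist: TLDistribution) -> TLDistribution:
    """Divide raw intensity by fragment size: removes probe hybridization bias."""
    if np.min(dist.size_kb) <= 0:
        raise ValueError("non-positive fragment size; cannot normalize")
    return replace(dist, weight=dist.raw / dist.size_kb)


def truncate_low(dist: TLDistribution, min_kb: float = DEFAULT_MIN_KB) -> TLDistribution:
    """Discard entries below ``min_kb`` (boundary kept: size >= min_kb retained)."""
    keep = dist.size_kb >= min_kb
    n_removed = int((~keep).sum())
    if not np.any(keep):
        raise ValueError(
            f"lane {dist.lane_id}: no signal above the {min_kb} kb cutoff"
        )
    return replace(
        dist,
        size_kb=dist.size_kb[keep],
        raw=dist.raw[keep],
        weight=None if dist.weight is None else dist.weight[keep],
        n_truncated=dist.n_truncated + n_removed,
    )


def _step_quantile(sizes: np.ndarray, cum_frac: np.ndarray, q: float) -> float:
    """Smallest size whose cumulative normalized weight reaches q."""
    idx = int(np.searchsorted(cum_frac, q, side="left"))
    idx = min(idx, sizes.size - 1)
    return float(sizes[idx])


def summarize(dist: TLDistribution) -> TLSummary:
    """Compute mean/med/Q1/Q3/IQ of a normalized, truncated TL distribution."""
    if dist.weight is None:
        raise ValueError("distribution not size-normalized; call normalize_by_size first")
    w = dist.weight
    total_w = float(w.sum())
    total_raw = float(dist.raw.sum())
    if total_w <= 0:
        raise ValueError(f"lane {dist.lane_id}: zero total weight")
    # w-weighted mean of L; for w = I/L this is exactly sum(I) / sum(I/L)
    mean_kb = float(np.sum(w * dist.size_kb) / total_w)
    cum = np.cumsum(w) / total_w
    q1 = _step_quantile(dist.size_kb, cum, 0.25)
    med = _step_quantile(dist.size_kb, cum, 0.50)
    q3 = _step_quantile(dist.size_kb, cum, 0.75)
    return TLSummary(
        mean_kb=mean_kb,
        med_kb=med,
        q1_kb=q1,
        q3_kb=q3,
        iq_kb=q3 - q1,
        total_signal=total_raw,
        total_weight=total_w,
        n_rows=len(dist),
        lane_id=dist.lane_id,
        membrane_id="",
        probe=dist.probe,
        qc_flags=tuple(dist.flags),
    )


def quantify_lane(
    profile: LaneProfile,
    scale: PiecewiseScale,
    params: QuantifyParams = QuantifyParams(),
) -> TLSummary:
    """Full lane pipeline: background -> size -> normalize -> truncate -> summarize."""
    leveled = subtract_background(profile)
    flags = []
    if params.low_signal_threshold > 0 and leveled.total() < params.low_signal_threshold:
        flags.append("low-signal")
    dist = profile_to_distribution(leveled, scale, params.jacobian_reweight)
    dist = normalize_by_size(dist)
    dist = truncate_low(dist, params.min_kb)
    dist.flags.extend(flags)
    summary = summarize(dist)
    return replace(summary, membrane_id=profile.membrane_id)


def qc_lane(
    before: LaneProfile,
    after_strip: Optional[LaneProfile] = None,
    strip_threshold: float = DEFAULT_STRIP_RESIDUAL_THRESHOLD,
    low_signal_threshold: float = 0.0,
) -> QCReport:
    """Stripping-efficiency and signal-level QC for one lane.

    The residual ratio is total post-strip signal over total pre-strip
    signal (0 when no strip exposure is supplied).  The report never drops
    a lane itself.
    """
    if after_strip is not None and len(after_strip) != len(before):
        raise ValueError(
            f"lane {before.lane_id}: stripped profile length {len(after_strip)} "
            f"!= original {len(before)}"
        )
    total_before = before.total()
    residual = 0.0
    if after_strip is not None:
        residual = after_strip.total() / total_before if total_before > 0 else np.nan
    leveled_total = float(
        (before.intensity - before.intensity.min()).sum()
    )
    return QCReport(
        stripping_residual=float(residual),
        signal_total=leveled_total,
        low_signal=bool(low_signal_threshold > 0 and leveled_total < low_signal_threshold),
        strip_threshold=strip_threshold,
        degraded=False,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """TL summary table in the standard CSV column order."""
    rows = [
        {
            "membrane_id": s.membrane_id,
            "lane_id": s.lane_id,
            "probe": s.probe,
            "mean_kb": s.mean_kb,
            "med_kb": s.med_kb,
            "q1_kb": s.q1_kb,
            "q3_kb": s.q3_kb,
            "iq_kb": s.iq_kb,
            "total_signal": s.total_signal,
            "n_rows": s.n_rows,
            "qc_flags": ";".join(s.qc_flags),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=TL_SUMMARY_COLUMNS)
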