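"""Synthetic gels, lanes and cohorts with known ground truth.

The forward model is deliberately simple but captures what the analysis
must undo:

* **Migration**: a fragment of size L kb sits at row
  ``row(L) = r0 + s*u + kappa*u**2`` with ``u = log2(Lmax) - log2(L)``.
  ``kappa = 0`` gives a single exact log2-linear scale; ``kappa > 0``
  compresses the high-MW region, which is what motivates the two-segment
  calibration.
* **Ladder lanes**: Gaussian bands centred at row(L) for each catalogue
  size.
* **Smear lanes**: telomere fragment sizes follow a lognormal law g(L)
  (on ln-kb); probed signal density along the lane is
  ``amplitude * L * g(L) * |dL/drow|`` — the L factor is the probe-number
  hybridization bias that size normalization removes.
* **Cohorts**: ``ln(TL) = island effect + community effect +
  beta * diameter + noise`` with chosen variance fractions.

Every simulator is deterministic given its seed.  Ground-truth TL
summaries are computed by numeric integration of the truncated (>= 2 kb)
size law, so recovery tests compare like with like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .calibration import LadderSpec, write_seeds
from .gelio import GelImage, LaneProfile, LaneROI, write_gel_image, write_rois
from .quantify import DEFAULT_MIN_KB, TLSummary

__all__ = [
    "MigrationModel",
    "SmearSpec",
    "NoiseSpec",
    "CohortDesign",
    "MembraneLane",
    "simulate_ladder_lane",
    "simulate_smear_lane",
    "render_membrane",
    "simulate_cohort",
    "smear_truth",
]

DEFAULT_N_ROWS = 1024
DEFAULT_SNR = 20.0  # peak profile signal / additive noise sd; see docs/methods.md


@dataclass(frozen=True)
class MigrationModel:
    """Monotone row-vs-log2(size) migration law, optionally curved."""

    r0: float = 40.0
    stretch: float = 130.0       # rows per log2-kb
    curvature: float = 0.0       # rows per (log2-kb)^2
    lmax_kb: float = 64.0
    min_kb: float = 0.5          # smallest size the lane is expected to carry

    def __post_init__(self) -> None:
        u_max = math.log2(self.lmax_kb / self.min_kb)
        # strictly increasing row(u) over the simulated range
        if self.stretch <= 0 or self.stretch + 2 * self.curvature * u_max <= 0:
            raise ValueError("migration model not strictly increasing over the size range")

    def _u(self, size_kb) -> np.ndarray:
        return np.log2(self.lmax_kb) - np.log2(np.asarray(size_kb, dtype=float))

    def row_of(self, size_kb):
        """Pixel row (float) at which a fragment of ``size_kb`` migrates."""
        u = self._u(size_kb)
        out = self.r0 + self.stretch * u + self.curvature * u ** 2
        return float(out) if out.ndim == 0 else out

    def size_of(self, row):
        """Inverse migration: fragment size (kb) at a pixel row."""
        row = np.asarray(row, dtype=float)
        if self.curvature == 0:
            u = (row - self.r0) / self.stretch
        else:
            disc = self.stretch ** 2 + 4 * self.curvature * (row - self.r0)
            u = (-self.stretch + np.sqrt(np.maximum(disc, 0))) / (2 * self.curvature)
        out = self.lmax_kb * 2.0 ** (-u)
        return float(out) if out.ndim == 0 else out

    def dsize_drow(self, row):
        """|dL/drow| at a pixel row."""
        row = np.asarray(row, dtype=float)
        L = self.size_of(row)
        if self.curvature == 0:
            du_drow = 1.0 / self.stretch
        else:
            u = self._u(L)
            du_drow = 1.0 / (self.stretch + 2 * self.curvature * u)
        out = L * np.log(2.0) * du_drow
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SmearSpec:
    """Lognormal telomere-size law: ln(L/kb) ~ Normal(mu, sigma)."""

    mu: float = math.log(5.0)
    sigma: float = 0.3
    amplitude: float = 30000.0
    probe_bias: bool = True
    trunc_lo_kb: float = 0.0     # support truncation of the generative law
    trunc_hi_kb: float = math.inf

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValueError("sigma and amplitude must be positive")

    @property
    def median_kb(self) -> float:
        return math.exp(self.mu)

    def pdf(self, size_kb):
        p = stats.lognorm.pdf(size_kb, s=self.sigma, scale=math.exp(self.mu))
        lo, hi = self.trunc_lo_kb, self.trunc_hi_kb
        size_kb = np.asarray(size_kb, dtype=float)
        return np.where((size_kb >= lo) & (size_kb <= hi), p, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive lane noise: constant baseline offset plus Gaussian sd."""

    baseline: float = 0.0
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.baseline < 0:
            raise ValueError("baseline and sd must be >= 0")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noisy = signal + self.baseline + rng.normal(0.0, self.sd, size=signal.shape)
        return np.maximum(noisy, 0.0)

    @staticmethod
    def for_snr(peak_signal: float, snr: float = DEFAULT_SNR, seed: int = 0,
                baseline_frac: float = 0.05) -> "NoiseSpec":
        """Noise spec for a target peak-signal-to-noise ratio."""
        sd = peak_signal / snr if snr > 0 else 0.0
        return NoiseSpec(baseline=baseline_frac * peak_signal, sd=sd, seed=seed)


def simulate_ladder_lane(
    ladder: LadderSpec,
    model: MigrationModel,
    noise: NoiseSpec = NoiseSpec(),
    band_width: float = 3.0,
    n_rows: int = DEFAULT_N_ROWS,
    band_amplitude: float = 10000.0,
    lane_id: str = "ladder",
    seed_jitter: int = 0,
) -> tuple[LaneProfile, list[tuple[float, float]]]:
    """Gaussian bands at row(L) for every catalogue band of the ladder.

    Returns the lane profile and the (size kb, seed row) pairs for peak
    refinement; ``seed_jitter`` displaces the reported seeds by up to that
    many rows (deterministically) to exercise the refinement step.
    """
    rows = np.arange(n_rows)
    signal = np.zeros(n_rows)
    true_rows = []
    for size in ladder.sizes_kb:
        center = model.row_of(size)
        if not (0 <= center < n_rows):
            raise ValueError(
                f"band {size} kb migrates to row {center:.1f}, outside the "
                f"{n_rows}-row lane"
            )
        signal += band_amplitude * np.exp(-0.5 * ((rows - center) / band_width) ** 2)
        true_rows.append((float(size), float(center)))
    centers = sorted(r for _, r in true_rows)
    if any(b - a < 2 * band_width for a, b in zip(centers, centers[1:])):
        import warnings
        warnings.warn("adjacent ladder bands closer than 2 band widths; may be unresolvable",
                      stacklevel=2)
    seeds = []
    rng = np.random.default_rng(noise.seed + 1)
    for size, center in true_rows:
        jitter = rng.integers(-seed_jitter, seed_jitter + 1) if seed_jitter else 0
        seeds.append((size, float(np.clip(round(center) + jitter, 0, n_rows - 1))))
    profile = LaneProfile(
        lane_id=lane_id,
        rows=rows,
        intensity=noise.apply(signal),
        role="ladder-left",
    )
    return profile, seeds


def peak_signal(smear: SmearSpec, model: MigrationModel,
                n_rows: int = DEFAULT_N_ROWS) -> float:
    """Peak of the noiseless smear profile (for SNR-targeted noise specs)."""
    rows = np.arange(n_rows)
    L = model.size_of(rows)
    g = smear.pdf(L)
    dL = np.abs(model.dsize_drow(rows))
    bias = L if smear.probe_bias else 1.0
    return float((smear.amplitude * bias * g * dL).max())


def with_peak(smear: SmearSpec, model: MigrationModel, target_peak: float,
              n_rows: int = DEFAULT_N_ROWS) -> SmearSpec:
    """Rescale a smear's amplitude so its profile peaks at ``target_peak``."""
    from dataclasses import replace

    return replace(smear, amplitude=smear.amplitude * target_peak /
                   peak_signal(smear, model, n_rows))


def smear_truth(
    smear: SmearSpec,
    min_kb: float = DEFAULT_MIN_KB,
    max_kb: float = math.inf,
    lane_id: str = "",
    n_grid: int = 200_001,
) -> TLSummary:
    """Numeric-integration oracle for a smear lane's five TL parameters.

    Mean and quantiles of the lognormal size law g truncated to
    [min_kb, max_kb]; this is what a perfect pipeline should recover after
    the 2 kb cutoff.
    """
    lo = max(min_kb, smear.trunc_lo_kb, 1e-9)
    hi = min(smear.trunc_hi_kb, max_kb)
    if not math.isfinite(hi):
        hi = math.exp(smear.mu + 10 * smear.sigma)
    L = np.linspace(lo, hi, n_grid)
    g = smear.pdf(L)
    total = integrate.trapezoid(g, L)
    if total <= 0:
        raise ValueError("smear has no mass above the cutoff")
    mean = integrate.trapezoid(L * g, L) / total
    cdf = integrate.cumulative_trapezoid(g, L, initial=0.0) / total
    q1, med, q3 = np.interp([0.25, 0.5, 0.75], cdf, L)
    return TLSummary(
        mean_kb=float(mean),
        med_kb=float(med),
        q1_kb=float(q1),
        q3_kb=float(q3),
        iq_kb=float(q3 - q1),
        total_signal=float("nan"),
        total_weight=1.0,
        n_rows=n_grid,
        lane_id=lane_id,
        probe="host",
    )


def simulate_smear_lane(
    smear: SmearSpec,
    model: MigrationModel,
    noise: NoiseSpec = NoiseSpec(),
    n_rows: int = DEFAULT_N_ROWS,
    lane_id: str = "sample",
    probe: str = "host",
    min_kb: float = DEFAULT_MIN_KB,
) -> tuple[LaneProfile, TLSummary]:
    """Render a telomere smear lane and its ground-truth TL summary.

    Signal density: ``amplitude * L * g(L) * |dL/drow|`` (the L factor only
    when ``probe_bias``), plus baseline and Gaussian noise.
    """
    central_mass = (math.exp(smear.mu - 4 * smear.sigma),
                    math.exp(smear.mu + 4 * smear.sigma))
    row_hi = model.row_of(central_mass[0])
    row_lo = model.row_of(min(central_mass[1], model.lmax_kb))
    if row_lo < 0 or row_hi > n_rows - 1:
        raise ValueError("smear support extends outside the simulated lane")
    rows = np.arange(n_rows)
    L = model.size_of(rows)
    g = smear.pdf(L)
    dL = np.abs(model.dsize_drow(rows))
    bias = L if smear.probe_bias else 1.0
    signal = smear.amplitude * bias * g * dL
    profile = LaneProfile(
        lane_id=lane_id,
        rows=rows,
        intensity=noise.apply(signal),
        role="sample",
        probe=probe,
    )
    truth = smear_truth(smear, min_kb=min_kb, max_kb=model.lmax_kb, lane_id=lane_id)
    return profile, truth


# ---------------------------------------------------------------------------
# whole-membrane rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneLane:
    """One lane of a rendered membrane: a ladder or a smear sample."""

    lane_id: str
    kind: str                      # "ladder" | "sample"
    ladder: Optional[LadderSpec] = None
    smear: Optional[SmearSpec] = None
    role: str = "sample"
    probe: str = "none"

    def __post_init__(self) -> None:
        if self.kind == "ladder" and self.ladder is None:
            raise ValueError("ladder lane needs a LadderSpec")
        if self.kind == "sample" and self.smear is None:
            raise ValueError("sample lane needs a SmearSpec")


def render_membrane(
    layout: Sequence[MembraneLane],
    model: MigrationModel,
    noise: NoiseSpec = NoiseSpec(),
    lane_width: int = 20,
    lane_gap: int = 8,
    n_rows: int = DEFAULT_N_ROWS,
    membrane_id: str = "synthetic",
) -> tuple[GelImage, list[LaneROI], dict[str, list[tuple[float, float]]], dict[str, TLSummary]]:
    """Render lanes side by side into a 16-bit gel image.

    Returns the image, the lane ROIs, per-ladder-lane peak seeds, and the
    per-sample-lane ground-truth TL summaries.  Lateral extraction of an
    ROI reproduces each lane's 1-D profile up to rendering quantization.
    """
    n_cols = lane_gap + len(layout) * (lane_width + lane_gap)
    image = np.zeros((n_rows, n_cols))
    rois: list[LaneROI] = []
    seeds: dict[str, list[tuple[float, float]]] = {}
    truths: dict[str, TLSummary] = {}
    col = lane_gap
    for i, lane in enumerate(layout):
        lane_noise = NoiseSpec(baseline=noise.baseline, sd=noise.sd, seed=noise.seed + i)
        if lane.kind == "ladder":
            profile, lane_seeds = simulate_ladder_lane(
                lane.ladder, model, lane_noise, n_rows=n_rows, lane_id=lane.lane_id
            )
            seeds[lane.lane_id] = lane_seeds
            role = lane.role if lane.role.startswith("ladder") else "ladder-left"
        else:
            profile, truth = simulate_smear_lane(
                lane.smear, model, lane_noise, n_rows=n_rows,
                lane_id=lane.lane_id, probe=lane.probe,
            )
            truths[lane.lane_id] = truth
            role = "sample"
        image[:, col:col + lane_width] = (profile.intensity / lane_width)[:, None]
        rois.append(LaneROI(
            lane_id=lane.lane_id,
            membrane_id=membrane_id,
            col_start=col,
            col_end=col + lane_width,
            role=role,
            probe=lane.probe,
        ))
        col += lane_width + lane_gap
    peak = image.max()
    if peak <= 0:
        raise ValueError("membrane has no signal")
    scale = 60000.0 / peak  # keep a headroom margin below the 16-bit ceiling
    image = np.round(image * scale)
    return (
        GelImage(data=image.astype(np.uint16), bit_depth=16, image_id=membrane_id),
        rois,
        seeds,
        truths,
    )


def default_layout(
    ladder: LadderSpec,
    smears: Sequence[SmearSpec],
    middle_ladder: bool = False,
    probe: str = "host",
) -> list[MembraneLane]:
    """Ladders at the left and right gel ends (optionally middle), samples between."""
    lanes = [MembraneLane("ladder-L", "ladder", ladder=ladder, role="ladder-left")]
    half = (len(smears) + 1) // 2
    for i, sm in enumerate(smears[:half]):
        lanes.append(MembraneLane(f"S{i + 1}", "sample", smear=sm, probe=probe))
    if middle_ladder:
        lanes.append(MembraneLane("ladder-M", "ladder", ladder=ladder, role="ladder-middle"))
    for i, sm in enumerate(smears[half:], start=half):
        lanes.append(MembraneLane(f"S{i + 1}", "sample", smear=sm, probe=probe))
    lanes.append(MembraneLane("ladder-R", "ladder", ladder=ladder, role="ladder-right"))
    return lanes


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Generative design for a TL cohort with known variance structure."""

    n_islands: int = 30
    colonies_per_island: int = 27
    island_sd: float = math.sqrt(0.5)
    community_sd: float = math.sqrt(0.1)
    n_communities: int = 8
    diameter_slope: float = 0.0
    diameter_range: tuple[float, float] = (5.0, 100.0)
    residual_sd: float = math.sqrt(0.4)
    mean_ln_tl: float = math.log(5.0)
    genus: str = "Pocillopora"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.island_sd, self.community_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_islands < 1 or self.colonies_per_island < 1 or self.n_communities < 1:
            raise ValueError("counts must be >= 1")


def simulate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table plus its realized variance-fraction truth.

    ``ln(TL) = mean + island effect + community effect + beta * diameter +
    noise``.  The returned truth holds the variance fractions of the
    *realized* structural components (computed from the drawn effects and
    design matrix, not just the generative sds), on the total-variance
    scale used by commonality coefficients.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_islands * design.colonies_per_island
    island_labels = np.repeat(
        [f"I{i + 1:02d}" for i in range(design.n_islands)], design.colonies_per_island
    )
    island_effects = rng.normal(0, design.island_sd, design.n_islands)
    island_term = np.repeat(island_effects, design.colonies_per_island)

    community_labels = np.array(
        [f"C{c + 1}" for c in rng.integers(0, design.n_communities, n)]
    )
    community_effects = rng.normal(0, design.community_sd, design.n_communities)
    community_term = community_effects[
        np.array([int(c[1:]) - 1 for c in community_labels])
    ]

    diameter = rng.uniform(*design.diameter_range, n)
    diameter_term = design.diameter_slope * diameter
    noise = rng.normal(0, design.residual_sd, n)

    structural = island_term + community_term + diameter_term
    ln_tl = design.mean_ln_tl + structural + noise
    tl = np.exp(ln_tl)

    # realized variance fractions on the total-variance scale
    var_parts = {
        "island": float(np.var(island_term)),
        "community": float(np.var(community_term)),
        "diameter": float(np.var(diameter_term)),
    }
    total_var = float(np.var(structural)) + design.residual_sd ** 2
    truth = {
        "fractions": {k: v / total_var for k, v in var_parts.items()},
        "structural_r2": float(np.var(structural)) / total_var,
        "total_var": total_var,
        "design": {
            "n": n,
            "n_islands": design.n_islands,
            "island_sd": design.island_sd,
            "community_sd": design.community_sd,
            "residual_sd": design.residual_sd,
            "diameter_slope": design.diameter_slope,
        },
    }

    # plausible companion TL parameters derived from the mean
    table = pd.DataFrame({
        "colony_id": [f"{design.genus[:3].upper()}{i + 1:04d}" for i in range(n)],
        "island": island_labels,
        "genus": design.genus,
        "species": "",
        "symbiodiniaceae_profile": community_labels,
        "bacteria_profile": np.array(
            [f"B{b + 1}" for b in rng.integers(0, max(2, design.n_communities // 2), n)]
        ),
        "diameter_cm": diameter,
        "htl_mean_kb": tl,
        "htl_med_kb": tl * 0.95,
        "htl_q1_kb": tl * 0.75,
        "htl_q3_kb": tl * 1.25,
        "htl_iq_kb": tl * 0.50,
        "stl_mean_kb": tl * 2.0,
        "stl_med_kb": tl * 1.9,
        "stl_q1_kb": tl * 1.5,
        "stl_q3_kb": tl * 2.5,
        "stl_iq_kb": tl * 1.0,
    })
    return table, truth


# ---------------------------------------------------------------------------
# file emission used by the CLI
# ---------------------------------------------------------------------------

def emit_membrane(
    out_dir: str | Path,
    layout: Sequence[MembraneLane],
    model: MigrationModel,
    noise: NoiseSpec = NoiseSpec(),
    lane_width: int = 20,
    membrane_id: str = "synthetic",
) -> dict[str, Path]:
    """Write gel.tif, lanes.csv, seeds.csv and truth.csv for a rendered membrane."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image, rois, seeds, truths = render_membrane(
        layout, model, noise, lane_width=lane_width, membrane_id=membrane_id
    )
    paths = {
        "image": write_gel_image(image, out_dir / "gel.tif"),
        "lanes": write_rois(rois, out_dir / "lanes.csv"),
        "seeds": write_seeds(seeds, out_dir / "seeds.csv", membrane_id=membrane_id),
    }
    truth_df = pd.DataFrame([
        {
            "lane_id": t.lane_id, "probe": t.probe,
            "mean_kb": t.mean_kb, "med_kb": t.med_kb,
            "q1_kb": t.q1_kb, "q3_kb": t.q3_kb, "iq_kb": t.iq_kb,
        }
        for t in truths.values()
    ])
    truth_path = out_dir / "truth.csv"
    truth_df.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
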