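# Methods

## Scope and data model

`telogel` implements densitometric quantification of terminal restriction
fragment (TRF) telomere assays and the downstream cohort statistics. The
in-memory objects mirror the bench workflow: a `GelImage` (single-channel
matrix, row 0 at the gel-well side so size decreases down the rows), manual
`LaneROI`s (0-based half-open column intervals), 1-D `LaneProfile`s obtained
by *summing* intensity laterally across the lane width (densitometry
convention; all downstream statistics are invariant to that scale choice), a
`PiecewiseScale` calibration, per-lane `TLDistribution`/`TLSummary`, and a
per-colony cohort table. Multi-channel images are rejected rather than
converted: phosphorimager data is single-channel and channel selection would
be ambiguous.

## Ladder calibration

Manually seeded ladder peaks are refined to the intensity argmax within ±10
rows of the seed (ties toward the seed, then toward the smaller row);
refinement operates on the extracted 1-D profile. Gel migration is locally
log-linear but compressed at high molecular weight, so a single
`log2(L) = a + b·row` line misfits the full run. Two segments are fitted by
OLS of log2(size) on row: the high-MW segment on the 48.5/20/15 kb bands and
the low-MW segment on the 10, 8, 6, 5, 4, 3, 2.5, 2 kb bands. Bands present
in a ladder but not in a fit subset are carried for QC only. A ladder spec
with no high-MW subset (e.g. the 10–0.2 kb SmartLadder run alone) yields a
degenerate single-segment scale.

**Switch point.** The switch row is chosen deterministically as the integer
row — among rows where the low segment predicts 8–10 kb — that minimizes the
absolute log2-size gap between the two segments ("scale continuity"); ties
go to the smaller row. A gap above the continuity tolerance (default 0.15
log2 units ≈ 11% in size, configurable) warns but keeps the scale, flagged.
Above the switch row the high-MW coefficients apply, at/below it the low-MW
ones; extrapolation beyond the fitted band range is permitted but flagged
(`extrapolated`), since sub-2 kb rows are discarded later anyway. Sample
lanes are assigned to the laterally nearest ladder (left/middle/right; ties
toward the left ladder).

## Lane quantification

Stages, in order, on the raw profile:

1. **Background**: subtract the per-lane minimum intensity (output minimum
   exactly 0). This makes all TL parameters invariant to constant offsets.
2. **Size mapping**: each pixel row maps to `size_at(scale, row)`; per-row
   intensities are carried over unchanged (per-pixel treatment). An optional
   `jacobian_reweight` switch multiplies by |d size/d row| for sensitivity
   analysis; it is off by default.
3. **Probe-bias normalization**: `w = I/L`. Hybridization signal scales with
   the number of telomeric repeats, i.e. with fragment length; dividing by
   size converts signal density to fragment-count density. The mean TL is
   then `ΣI / Σ(I/L)`, identically the `w`-weighted mean of `L`.
4. **Truncation**: entries with size < 2.0 kb are discarded (genomic and
   interstitial-telomeric-repeat noise, normalization blow-up at small `L`);
   the boundary itself (exactly 2.0 kb) is retained. An empty result raises
   ("no signal above cutoff") so the caller decides about exclusion.
5. **Summary**: mean as above; med/Q1/Q3 as *step quantiles* of the
   normalized weights — the smallest size whose cumulative normalized
   weight, ascending in size, reaches the quantile — and IQ = Q3 − Q1. The
   step convention (no interpolation) is deterministic on discrete pixel
   grids. Quantiles are computed on the normalized distribution;
   consequently a point with 80% of the weight is simultaneously Q1, median
   and Q3.

QC mirrors the assay's human checks with explicit, configurable proxies: a
stripping-residual ratio (post-strip total / pre-strip total, default fail
threshold 0.1) and a low-signal flag (background-subtracted total below a
threshold, default expressed as a fraction, 0.02, of ladder signal when
driven from the CLI). Reports never drop lanes silently; the CLI logs every
exclusion. Host and symbiont lanes are processed identically — probe
identity is metadata.

## Cohort statistics

Predictors enter as atomic blocks (a categorical's dummy columns never
split), matching how island / Symbiodiniaceae / bacteria / diameter are
treated as single variables. OLS is computed directly (pivoted-QR detection
of aliased columns, which are dropped with a warning); R² = 1 − RSS/TSS with
R² ≡ 0 for a constant response. AIC uses the full Gaussian log-likelihood
with the error variance counted as a parameter
(`n·ln(2π) + n·ln(RSS/n) + n + 2(p+1)`), so values line up with common
statistical software; a numerically perfect fit receives a large negative
sentinel so it still orders first. Model selection takes the lowest AIC,
ties toward fewer parameters, and refuses fits computed on different data
subsets. For the TL-vs-colony-size family — ln(TL) on {diameter},
{diameter, diameter²}, {ln diameter} — rows with missing or non-positive
diameter are dropped listwise for *all three* models so the AICs stay
comparable (counts recorded). The response uses the natural logarithm;
selection statistics are base-invariant.

**Commonality analysis.** Given R² for every non-empty subset of `p`
blocks, coefficients `C(S)` solve the linear system
`R²(M) = Σ{C(S) : S ∩ M ≠ ∅}` over all non-empty models `M` (2^p − 1
equations, unique solution, solved exactly with `numpy.linalg.solve`; a
system residual above 1e-8 raises as an inconsistent input). The solver
formulation was chosen over closed-form inclusion–exclusion because its
correctness is checkable by construction at any `p`: coefficients must sum
to the full-model R² and `unique(X)` must equal `R²(full) − R²(full∖X)`,
both verified to 1e-10 in the tests. Percentages are reported relative to
the *non-adjusted* multiple R² of the full model. Negative coefficients are
legitimate (suppression).

Correlation matrices (Spearman or Pearson) use pairwise-complete
observations, require ≥3 pairs, record undefined cells (constant columns) as
missing rather than 0, and adjust the pooled upper-triangle p-values by
Benjamini–Hochberg.

## Synthetic ground truth

The generators exist so every stage is testable without real data.

- **Migration**: `row(L) = r0 + s·u + κ·u²`, `u = log2(Lmax/L)`; strictly
  monotone by construction (checked at instantiation). Defaults r0 = 40,
  s = 130 rows per log2-kb, κ = 0, Lmax = 64 kb on a 1024-row lane — a
  48.5–2 kb run occupying most of the lane, as on a real TRF gel. κ > 0
  compresses the high-MW region and is what makes a single-line fit
  measurably worse than the two-segment fit.
- **Ladder lanes**: Gaussian bands (width 3 rows) at `row(L)`; seeds may be
  jittered by up to the refine window (default jitter 5 ≤ window 10) so peak
  refinement is exercised but identifiable.
- **Smear lanes**: telomere sizes follow a lognormal law `g(L)` (right-
  skewed, positive support, closed-form moments — the family is pluggable);
  profile signal is `amplitude·L·g(L)·|dL/drow|`, the `L` factor being the
  probe bias (set `probe_bias=False` to generate bias-free lanes; the tests
  show normalization then biases the mean low, and skipping normalization on
  biased lanes biases it high — the pair is self-consistent).
  Noise is a constant baseline plus additive Gaussian noise, clipped at 0.
  Lane SNR is defined as peak profile signal over noise sd; the default is
  SNR 20 with baseline at 5% of peak. Study-condition smear parameters used
  by the simulators and drivers: median TL uniform in 4–9 kb, σ in 0.2–0.4
  ln-units.
- **Ground truth** for a smear lane is computed by numeric integration
  (trapezoid on a 200k grid) of `g` truncated at 2 kb, so recovery tests
  compare like with like.
- **Cohorts**: `ln(TL) = mean + island + community + β·diameter + ε` with
  island/community effects drawn per level. Default design: 30 islands × 27
  colonies (n = 810), variance fractions 50% island / 10% community / 40%
  residual, β = 0, diameter uniform 5–100 cm. The reported truth uses the
  *realized* effect variances, not just the generative sds, since a 30-draw
  island sample realizes a noticeably variable variance.

**What the simulators do not emulate** — and hence what passing tests do
not certify on real membranes: spatial gel distortions (smiles, bubbles),
flat-field and exposure gradients, partial DNA degradation smears,
correlated (non-white) background, and inter-membrane batch effects. The
minimum-subtraction background rule is exactly the one used on real data,
but it is sensitive to additive noise: the residual offset after subtracting
the minimum grows like ~3σ of the noise over a 1000-row lane, which inflates
low-size weight. At the default SNR 20 this contributes most of the ~3–4%
median error in mean-TL recovery; at phosphorimager-realistic SNRs (≥100)
the error drops below ~1.5%.

## Problem sizes and numerical choices

The bundled accuracy drivers use 25 exact two-segment ladders (275 bands),
1,000 random discrete distributions for the estimator identity, 100 noisy
smear lanes for end-to-end recovery, 50 simulated cohorts (n = 810 each) for
commonality recovery, and 200 null cohorts (n = 80) for the type-I error
rate — sizes chosen so the full run completes in seconds while keeping
Monte-Carlo error well below the tolerances checked. Determinism: every
simulator takes an explicit seed; scale JSONs are written with sorted keys
so reruns are byte-identical. Tie-breaks (peak refinement, switch row, AIC,
ladder assignment) are all specified and tested. Degenerate inputs (constant
response, rank-deficient designs, all-zero lanes, empty truncation results)
raise or flag explicitly rather than returning silent defaults.

## Known limitations

- No automatic lane or band detection: lanes and ladder seeds are manual
  inputs by design.
- The piecewise-linear migration model does not fit strongly curved gels;
  a spline scale is out of scope.
- Smear deconvolution and per-chromosome telomere lengths are not
  attempted; the TRF summary describes the bulk distribution only.
- Linear mixed-model variance partitioning (random-effect R²) is not
  implemented; the commonality analysis decomposes fixed-effect OLS R².
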