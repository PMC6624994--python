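# Methods

## Scope and geometry

`herbe` computes RBE-weighted dose for helium-ion beams in one-dimensional
water geometry (depth in mm along the beam axis).  Patient CT grids, lateral
beam models, nuclear fragmentation physics and Monte-Carlo transport are out
of scope; depth profiles of per-component dose and dose-averaged LET are
inputs (in practice scored by a transport code, here also producible by the
synthetic generator).  Depths measured in PMMA convert to water-equivalent
depth by the fixed factor 1.165.

## The LQ isoeffect framework

All biology is linear-quadratic: S = exp(−(αD + βD²)).  The isoeffect RBE at
particle dose D is D_x/D where D_x solves β_xD_x² + α_xD_x = αD + βD².  With
RBE_α = α/α_x and R_β = β/β_x this has the closed form quoted in the README.
Numerically the closed form is evaluated in its rationalized version

    RBE = (RBE_α(α/β)_x + R_β D) / ((α/β)_x/2 + √((α/β)_x²/4 + RBE_α(α/β)_x D + R_β D²))

which is algebraically identical but avoids the catastrophic cancellation of
the textbook form at small doses (the naive expression underflows to RBE = 0
for D ≲ 10⁻⁸ Gy, which matters in the far distal tail of a depth profile)
and yields the continuity limit RBE → RBE_α at D = 0 exactly.  Quadratic
inversions always take the positive root; β = 0 degenerates to the linear
case.

Tissues carry (α_x, β_x), optionally the LEM transition dose D_t above which
the photon curve is treated as exponential with slope s_max = α_x + 2β_x·D_t.
When an isoeffective photon dose exceeds D_t the LQ value is still returned
but an `LQValidityWarning` is emitted: the low-dose working range of the
engine is D_x < D_t, and the warning marks extrapolation rather than
silently refusing.

EUD is the uniform photon dose reproducing the mean target survival:
EUD = −(α/β)_x/2 + √((α/β)_x²/4 − ln S̄/β_x).

## RBE model parameterizations

**DDM.**  RBE_α = 1 + [k₀ + (α/β)_x⁻¹]·k₁L*·exp(−k₂L*²) with defaults
k₀ = 8.924×10⁻² Gy⁻¹, k₁ = 3.368×10⁻¹ µm/keV, k₂ = 2.858×10⁻⁵ µm²/keV²;
R_β = b₀·exp(−((L*−b₁)/b₂)²) with b₀ = 2.66, b₁ = 62.61 keV/µm,
b₂ = 48.12 keV/µm.  R_β is clamped to exactly zero above a configurable
cutoff (default 100 keV/µm): the model's stated behaviour is that R_β drops
to zero beyond that LET, whereas the bare Gaussian would still give ≈1.45 at
100 keV/µm, so the words, not the tail, carry the zeroing.  L* rescaling has
two modes: `track_segment` (L* = LET, the default, used for in-silico model
comparison) and `clinical` (L* = LET − LET_x + LET_Co60); the two reference
LET constants have no reliable published values here and must be configured
explicitly for clinical mode.

**Modified MKM.**  RBE_α = 1 + z*₁D/(α/β)_x and R_β = 1.  The
saturation-corrected dose-mean specific energy z*₁D enters only as tabulated
input (two-column table, linearly interpolated); its microdosimetric
derivation — amorphous track structure, overkill saturation — is upstream of
this package.  Domain and nucleus radii default to R_d = 0.3 µm,
R_n = 3.6 µm.

**LEM low-dose approximation.**  RBE_α = (1 − exp(−α_z d₁))/(α_x d₁), with
the analytic limit α_z/α_x taken below d₁ < 10⁻¹² Gy, and
R_β = (α/α_z)²·(β_z/β_x) with α = RBE_α·α_x.  Intrinsic α_z tables are
user-supplied; β_z, when absent, is approximated as (s_max − α_z)/(2D_t)
with negative values forced to zero.  The single-traversal dose is
d₁ = 0.1602·LET/(πR_n²) Gy (LET in keV/µm, R_n in µm, unit density) — the
standard fluence-to-dose conversion over the nucleus cross-section, kept
overridable through the table's `d1` column.

Biological tables (z*₁D, LEM) are linearly interpolated in their abscissa;
requests outside the tabulated range raise instead of clamping, because
silent extrapolation of biological inputs is unsafe.

## Mixed fields and forward calculation

Z=2 (primary + fragments) and Z=1 (fragment) components are scored
separately and combined per depth with the dose-weighted rule
α_mix = Σd_iα_i/Σd_i and √β_mix = Σd_i√β_i/Σd_i — the standard
particle-TPS (Zaider–Rossi) convention.  Forward calculation then applies
the closed-form RBE at the local total dose.  Dose-averaged LET is reported
only where total dose exceeds 5% of the maximum Z=2 dose, mirroring the
scoring threshold used for MC-derived LET distributions; other depths are
masked NaN.

When kernels are superposed, LET_d and optional per-depth model inputs of
same-named components combine dose-weighted.  For α_z this is an
approximation (the exact mixture would mix event spectra, not coefficients);
it is consistent with how LET_d itself is dose-averaged and is the standard
table-based engine compromise.

## SOBP optimization

Physical mode solves the bounded least-squares problem A·w = p over the
target grid with w ≥ 0 (`scipy.optimize.lsq_linear`), A being the kernel
dose matrix.  Biological mode iterates a Newton-type fixed point: freeze
RBE(z) from the current field, re-solve the bounded least-squares system at
the kernel Bragg-peak positions for physical peak doses p/RBE(z_peak),
repeat until every in-target peak's D_RBE matches the prescription to 10⁻⁴
relative (default cap 200 iterations).  Because RBE responds only weakly to
the weight vector, this converges in 5–10 iterations on the packaged kernel
sets.  A simpler per-kernel multiplicative relaxation
w ← w·(p/D_RBE(z_peak))^0.7 was evaluated first and converges to the same
fixed point, but needs ~450 iterations here: with a peak-to-plateau ratio of
~2 and 2-mm peak spacing, most of the dose at a mid-target peak comes from
*other* kernels, so a per-kernel multiplicative step barely moves its own
residual.  Target coverage is validated up front (kernel peaks must span the
interval) with the uncovered subinterval named in the error.

## DVH and EUD conventions

The cumulative DVH uses the "≥ threshold" convention: D_x% is the largest
sample dose received by at least x% of the volume, evaluated on the
descending-sorted sample with cumulative volume weights.  This makes D_50%
of two equal bins {1, 3} Gy equal to 3 Gy and converges to the continuum
quantile (e.g. D_5% → 9.5 Gy for a uniform 0–10 Gy ramp) as the sample
grows; it is documented because D_5%/D_95% are convention-sensitive.
I_5% = (D_5% − D_95%)/prescription.  Target EUD computes per-voxel survival
from the mixed-field LQ pair at the local dose, averages survival (not
dose), and applies the EUD closed form — by convexity this sits below the
arithmetic mean of per-voxel photon-equivalent doses.

## Survival fitting

Fitting is weighted least squares on log survival, where the LQ model is
linear in (α, β): minimize Σw_i(ln SF_i + αD_i + βD_i²)².  Weights are
w_i = n_i/(sd_i/SF_i)² when a standard deviation is given — the delta-method
inverse variance of ln SF for a mean of n_i replicates — and n_i (default 1)
otherwise; records lacking a usable sd fall back to the median relative
variance.  β is constrained nonnegative by an active-set refit on the linear
model.  Parameter covariance comes from the weighted normal equations scaled
by the residual variance; an optional seeded case-resampling bootstrap
(suggested 2000 resamples) covers heteroscedastic data.  Records with
SF ≤ 0 are excluded with a warning; SF in (1, 1.5] is kept with a warning
(low-dose counting noise), above 1.5 rejected.  At least three distinct dose
levels are required.

The packaged table of measured photon/helium LQ parameters stores the
printed numbers verbatim, including uncertainties whose statistical meaning
(SE vs SD vs CI) the source does not state.  One internal inconsistency is
preserved and flagged rather than resolved: the pristine-peak experiment
prints (α/β)_x = 1.79 Gy while its coefficients 0.034/0.018 give 1.89 Gy;
the loader adds an `alpha_beta_consistent` flag.

## Synthetic generator

The generator emulates the *shapes and anchor values* of measured helium
data, not the physics.

* **Bragg curve**: gently rising plateau (default +15% over the range) times
  a sigmoid distal edge, plus a Gaussian peak (default FWHM 2.5 mm) at the
  nominal range; amplitude chosen so the peak-to-plateau dose ratio is the
  spec value (default 2, typical for helium beams).  The dose argmax lands
  within one 0.1-mm grid step of the nominal range.  An optional Z=1
  fragment component carries a configurable entrance fraction and decays
  exponentially beyond the peak.
* **LET_d(z)**: a saturating residual-range power law, strictly rising from
  the entrance value and saturating at the peak value near the Bragg peak.
  Its two shape parameters can be solved from (depth, LET) anchors;
  `BeamSpec.experiment_a()` does so for the reference monoenergetic beam
  (56.66 MeV/u, peak at 25.9 mm, ~6 keV/µm at 6 mm, ~15 keV/µm at 12 mm).
* **Kernel libraries**: peaks every 2 mm (the energy-slice separation used
  for SOBP plans) on a shared grid, with mild width growth for deeper peaks.
* **Model-input fixtures**: a z*₁D table z* = z_sat·tanh(LET/35) (zero at
  zero, monotone, saturating — the overkill-correction shape) and a smooth
  intrinsic LEM table with α_z rising from α_x toward s_max; both are
  machinery fixtures, explicitly not reproductions of LEM-IV or
  microdosimetric calculations.
* **Well plates**: per well, colonies ~ Poisson(cells·PE·S_LQ(D)); defaults
  12 wells/dose, 300 cells/well, plating efficiency 0.6, dose ladder
  0–3 Gy (the standard clonogenic design).  Surviving fraction is the mean
  count over wells divided by the nominal zero-dose expectation.  The
  Poisson error model is a declared stand-in — real assays report only
  mean ± SD — and all randomness flows through one seeded generator, so a
  fixed seed gives byte-identical datasets.

Because the generator matches anchors rather than physics, passing tests
demonstrate that the *pipeline* (models → mixing → forward → optimization →
fitting) is correct and self-consistent; they do not validate nuclear
fragment spectra, lateral scattering, ripple-filter effects, or the true
joint dose–LET shape of any measured beam.

## Problem sizes and determinism

Default test/validation sizes: 21 kernels on a 0.1-mm grid for SOBP studies,
10³ random draws for the closed-form equivalence check, 200 seeded plate
replicates for parameter recovery, 2×10⁴ wells for law-of-large-numbers
checks.  These sizes give comfortable statistical margins while keeping the
full suite around a couple of seconds.  Every stochastic path (plate noise,
bootstrap) takes an explicit integer seed.

## Known limitations

* One-dimensional; no lateral dose model, no patient geometry.
* The clinical L* rescaling mode is inert until the user supplies the two
  reference-LET constants; published comparisons that used it cannot be
  reproduced without them.
* z*₁D and intrinsic LEM tables are inputs; the engine neither computes the
  saturation correction nor the double-strand-break statistics behind them.
* The LQ framework itself is assumed valid (doses below D_t); no
  linear-quadratic-cubic or universal-survival-curve extensions.
* Mixed-field combination of intrinsic coefficients is dose-weighted, an
  approximation adequate for table-based engines but not a microdosimetric
  mixture.
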