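# Methods

## Data model and normalization

A CEST acquisition is a stack of saturated images over a saturation-offset
axis plus one unsaturated reference image. The default CEST axis spans +6
to −6 ppm in 0.1 ppm steps (121 nominal grid positions; the acquired count
is configuration-driven and never hard-coded, since acquisitions commonly
drop one endpoint). WASSR uses +1.5 to −1.5 ppm. Axes are stored in
acquisition order (typically high→low ppm) and sorted ascending internally;
positive ppm is downfield of water.

The unsaturated reference M_z⁰ is taken as a dedicated image acquired
without presaturation (either a separate file or a designated frame of the
stack). Z-values above 1 caused by noise are flagged in QC output but
retained — clipping would bias the downstream Lorentzian amplitudes
low. Non-finite spectral entries are imputed by neighbor interpolation and
recorded in a per-spectrum repair log rather than silently dropped.

Spline smoothing uses a cubic smoothing spline; the smoothing budget is a
config parameter, `0` meaning exact interpolation at the knots and `None`
delegating to the spline's generalized cross-validation-style default.

## WASSR B0 estimation and correction

The water-dip position is found in two stages: (1) argmin of a cubic-spline
interpolation of the WASSR spectrum on a 0.001 ppm grid; (2) refinement by
symmetry matching — the center s minimizing Σ_w [z(s+w) − z(s−w)]² over
probe distances w up to 0.5 ppm, solved by bounded scalar minimization in a
±0.1 ppm window around the spline minimum. The symmetry residual is
reported as a per-voxel quality measure. A minimum within 0.05 ppm of an
axis endpoint, a flat spectrum, or a shift beyond the WASSR half-range
marks the voxel unreliable; such voxels are removed from the analysis mask
and counted in the QC report.

Correction resamples Z at (offset + shift) by cubic spline, so the spectrum
moves while the axis stays fixed: every voxel remains on one common grid
for map arithmetic. Offsets that would require extrapolation are evaluated
by the spline's natural extension and flagged. Shifts of magnitude ≥ a
quarter of the axis span are rejected. On noiseless data the estimator is
shift-equivariant to well under 0.005 ppm, and correcting a symmetric
(water-only) spectrum leaves |MTR_asym| < 10⁻³ at all offsets.

## Multi-pool Lorentzian model

Z(ω) = Z_base − Σₖ aₖ / (1 + 4((ω − cₖ)/σₖ)²), with K = 5 pools, aₖ a
dimensionless amplitude, cₖ the pool center (ppm) and σₖ the full width at
half maximum (ppm). Z_base absorbs the constant signal reduction and is
bounded to [0.8, 1.2], initialized at 1.0.

Default priors (all exposed in `PoolSpec` so measured values can be dropped
in): amplitudes bounded [0, 1] with init 0.02 (water 0.8); widths [0.3, 3]
ppm for the narrow solute pools, [2, 20] ppm for the semi-solid MT pool,
[0.5, 10] ppm for NOE, and [0.3, 6] ppm for water — the water upper bound
is wider than the narrow-pool default because direct water saturation at
typical CW powers (3 μT) produces a line broader than 3 ppm. Centers are
fixed at their nominal frequencies ± a 0.1 ppm window (water ± 0.3 ppm;
the four closely spaced glucose pools ± 0.05 ppm). The narrow center
windows are the identifiability mechanism: they prevent neighboring pools
from swapping roles, which is the dominant degeneracy of sums of
Lorentzians.

The MT background is modeled as a broad Lorentzian at −2.0 ppm. A
super-Lorentzian lineshape would be more physical for semi-solid MT, but the
model deliberately keeps all K pools Lorentzian so the difference metrics
below remain closed-form in the fitted parameters.

Fitting is one-stage bounded nonlinear least squares (trust-region
reflective, numerical Jacobian, ftol = xtol = gtol = 10⁻¹², generous
function-evaluation cap) over the full ±6 ppm B0-corrected spectrum —
deterministic and seed-free. Non-convergence is a reported flag, never an
exception, so map generation can continue and the QC report carries the
count. Noiseless five-pool spectra are recovered to machine precision;
at Gaussian noise of sd 0.005 on Z the median amide-amplitude error is
about 5 %.

From a converged fit, Z_lab(δ) = Z_base − Σᵢ Lᵢ(δ) and Z_ref(δ) = Z_base −
Σ_{i≠label} Lᵢ(δ); Z_ref − Z_lab equals the label Lorentzian at δ exactly,
and MTR_REX = 1/Z_lab − 1/Z_ref = L_label(δ)/(Z_lab·Z_ref) — both
identities are asserted to 10⁻¹² in the tests. Z_lab ≤ 0 is treated as a
nonphysical fit and masks the voxel.

## Metrics

MTR_asym is computed from the smoothed, B0-corrected spectrum and evaluated
at exactly ±δ by spline interpolation (the 0.1 ppm grid does not contain
±1.28), and reported in percent. The Lorentzian amplitude metric is the
fitted label amplitude. AREX divides MTR_REX by the voxel's T1_obs, fitted
from a variable-TR saturation-recovery series S(TR) = S0(1 − exp(−TR/T1))
with T1 bounded to (0.05, 10] s and initialized at 1.5 s (a robust midpoint
for mouse tissue at 9.4 T); the model carries no flip-angle or TE term
because the readout is treated as ideal saturation recovery at fixed TE.
Fits pinned at a T1 bound are flagged and excluded from AREX. Delta maps
subtract baseline from post-challenge maps voxelwise with mask
intersection. CNR uses the sample standard deviation (ddof = 1; exposed in
config since the convention is not universal).

## Group statistics

Subject-level analysis operates on ROI means. Outlier screening uses the
Tukey fences Q1 − 1.5·IQR and Q3 + 1.5·IQR with quartiles by linear
interpolation between order statistics (the convention is a config knob
because exclusion counts depend on it), applied once per group per metric
and never iterated — fences are always computed from the full group, which
makes a second pass a no-op by construction.

Comparison is normality-gated: Shapiro–Wilk per group at α = 0.05 (per
group rather than pooled, the conservative choice); if every group passes,
one-way ANOVA with Tukey HSD pairwise p-values; otherwise Kruskal–Wallis
with pairwise Wilcoxon rank-sum tests corrected by Benjamini–Hochberg over
the three pairs. Pairwise tests are reported unconditionally (not gated on
the global test); the familywise significance rate of the full decision
tree under the null is ≈ 0.05–0.06, verified by simulation. Constant
groups short-circuit to an explicit degenerate branch. Reports record the
branch, all p-values, group summaries and significance stars (α = 0.05 /
0.01).

## Synthetic data

The Lorentzian generator is the generative twin of the fit model (baseline
minus pools evaluated at shifted offsets, Gaussian noise on Z, scaled into
saturated/reference intensities). Gaussian noise on Z is the default noise
model, with sd a design parameter; B0 fields are smooth second-order
polynomial surfaces scaled to a design amplitude (default ±0.2 ppm). All
generators are deterministic under their seed and emit truth tables from
which every voxel's generating parameters are reconstructable.

The phantom design places five disjoint circular vials on a square grid;
the label-pool amplitude in vial v is slope × concentration with defaults
following the 2-DG series (4.5–22.5 mM, slope 0.002 per mM), on a
water + MT background; non-label solute pools scale with the same
concentration at a fixed fraction. WASSR stacks use a narrow water dip at
the local B0 offset; T1 series use the saturation-recovery model on the
default TR ladder 867–6000 ms.

The cohort generator targets group-level metric distributions: per subject
it draws a latent metric value from the group's Normal(mean, SD),
standardizes each group's draws to the exact design mean/SD (so the
calibration check measures the amplitude→metric mapping, not sampling luck
of the mean; disable with `standardize=False` for honest sampling
variation), inverts the draw through a precomputed 200-point
amplitude→metric response curve (lookup, not closed form — MTR_REX and
AREX are nonlinear in amplitude and the curve goes through the actual
fitter), and renders a small image bundle per subject. Default group
structure is three breast-cancer-subtype-like groups of 12/14/13 subjects
with APTw metric targets (AREX means 0.016/0.033/0.041); delta-glucoCEST
targets and 9/9/10 sizes are provided alongside. Pre/post challenge pairs
raise the label amplitude by a configurable fraction.

The Bloch–McConnell oracle integrates the coupled two-pool magnetization
equations under continuous-wave saturation (exchange by detailed balance,
exact affine matrix exponential per offset; 9.4 T assumed, ≈ 400 Hz/ppm,
default 3 μT and 3 s saturation). It shares no code with the Lorentzian
model and serves as the independent physics reference: in the water-only
limit it matches the closed-form single-pool CW steady state to < 10⁻⁴,
and it underwrites the package's headline physical check — with solute
fraction and exchange rate fixed and water T1 varied over {1, 2, 3} s, the
relative range of pipeline AREX is ≈ 50× smaller than that of MTR_REX.
That check is run at 20 s saturation: AREX's T1-compensation is a
steady-state property, and at short saturation times the transient itself
depends on T1 for reasons unrelated to the metric.

What the generators do not emulate: realistic anatomy and partial-volume
effects, motion, fat signal, B1 inhomogeneity, and super-Lorentzian MT; Rician
magnitude noise is available on the generator's noise hook but Gaussian
noise on Z is the default. Passing tests therefore
demonstrate correctness of the postprocessing mathematics and its
statistical behavior under the designed conditions, not robustness to
every artifact of in vivo data.

## Problem sizes

Test and acceptance runs use deliberately small grids chosen to exercise
every pipeline stage at full fidelity: 32×32 phantoms with radius-2 vials
(65 fitted voxels), 8×8 cohort images with 3×3 tumor ROIs over 39
subjects, 100–200 Monte-Carlo replicates for estimator recovery, 2000
simulated cohorts for type-I control and 500 for the significance-pattern
comparison. Per-voxel operations are embarrassingly parallel, so larger
grids scale linearly.

## Known limitations

* The Lorentzian water line is an approximation to direct saturation; at
  high B1 the water pool absorbs some MT/solute signal even with the
  widened bound.
* MTR_REX/AREX assume the fitted pools separate cleanly; for the four
  closely spaced glucose hydroxyl pools the ±0.05 ppm center windows make
  the decomposition identifiable but prior-dependent.
* T1 mapping ignores readout efficiency; a global efficiency factor would
  cancel in relative comparisons but not in absolute AREX units.
* The statistics stage implements exactly the three-group decision tree
  described above; it is not a general mixed-model framework.
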