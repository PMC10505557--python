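# Methods

This note documents the models implemented in `lignoporo`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic benchmarks demonstrate.

## Sorption isotherms (DVS)

**Model.** Equilibrium water uptake of a hygroscopic solid is described by
the three-term Park model,
`M(a_w) = A_L·b_L·a_w/(1 + b_L·a_w) + k_H·a_w + n·k_H^n·k_a·a_w^n`,
with `M` in g water / 100 g dry matter (%). The terms represent Langmuir
adsorption on specific sites (dominant at low activity), Henry-type
dissolution (linear mid-range), and clustering of `n` water molecules
(upturn above ~0.7 a_w, the region sensitive to mesoporosity). `n` is
treated as a continuous parameter ≥ 1; nothing in the model requires
integer cluster sizes, and a continuous `n` keeps the optimisation smooth.

**Equilibrium detection.** The instrument records mass vs time under a
stepped activity schedule. A hold counts as equilibrated when the mass
slope, estimated by linear regression over the trailing 10 min window,
falls below 0.002% of dry mass per minute (both configurable). The
equilibrium mass is the mean over that window; holds that never meet the
criterion are reported with a not-equilibrated flag and their terminal
mass, never silently dropped. Dry mass comes from the initial a_w = 0
segment unless supplied explicitly. Closed-form analysis of the
exponential-relaxation kinetics shows that with τ = 20 min, holds of 6τ
satisfy this criterion shortly before hold end for every step of the
default schedule, while 2τ holds never do — which is exactly the behaviour
the flag is meant to surface.

**Branches.** Isotherm points are split into sorption and desorption at the
maximum-activity hold; the peak itself belongs to the sorption branch.
Hysteresis is evaluated by linear interpolation of the desorption branch
onto the sorption grid.

**Fitting.** Trust-region reflective nonlinear least squares (analytic
Jacobian) on the unweighted residual sum of squares, multi-started from an
18-point lattice over (b_L, k_a, n) with data-derived A_L and k_H starts;
the lowest-cost solution wins, and a numerically exact fit ends the sweep
early. Box bounds keep all parameters non-negative (n ∈ [1, 12], finite
upper bounds so trial points cannot overflow in `(k_H·a_w)^n`). MRD is
reported as a diagnostic, not optimised; zero-valued observed points are
excluded from it (the relative residual is undefined there) with a warning.
Standard errors come from the Gauss–Newton covariance at the optimum; for
near-perfect synthetic fits these collapse toward zero and should be read
as "the fit is exact", not as honest replicate-level uncertainty.

## Thermoporosimetry (DSC)

**Model.** Pore-confined ice melts below the bulk melting point; for
cylindrical pores the Gibbs–Thomson relation
`D = 4·T0·γ·cos(θ)/((Tm − T0)·ρ·Hf)` maps depression to diameter. Defaults
are the conventional water/ice values: T0 = 273.15 K, γ = 12.1 mJ m⁻²,
θ = 180° (non-wetting ice front; cos θ = −1 cancels the negative
depression), ρ = 1000 kg m⁻³, Hf = 334 J g⁻¹. Under these constants the
4–32 nm mesopore window corresponds to depressions of ≈ 9.9 to ≈ 1.24 K.
Enthalpy-to-mass conversion uses the same constant Hf at all temperatures —
a standard simplification; the temperature dependence of Hf is ignored.

**Procedure.** The sample is cooled well below T0 and stepped through
increasing isothermal holds. Each programmed hold is located in the
temperature trace as the longest contiguous run within a tolerance band
(default 0.1 K); the endotherm over the hold is integrated above a baseline
anchored at the window endpoints (`linear`, default; endpoint values are
averaged over a few samples for noise robustness) or at the pre-peak
plateau (`flat`). mW integrated over seconds gives mJ; dividing by sample
mass in mg gives J per g of sample directly. Negative integrated areas —
a noise artifact — are clipped to zero with a warning.

**Binning convention.** The enthalpy at hold T_k is assigned to diameters
between D(T_{k−1}) and D(T_k): water melting at T_k was held in pores too
large to have melted at the previous hold. The first bin's lower edge comes
from the thermogram's starting (cooling-minimum) temperature. Holds within
0.2 K of T0, or above it, are pooled as bulk free water, because the
relation diverges as Tm → T0 (0.2 K ≈ 200 nm). Fractions are normalised to
total freezing water (pore + bulk) = 100%; a switch for normalising to
total water including the non-freezing bound fraction is deliberately *not*
provided, since that fraction is not observable from the melting trace
alone — combine with `total_water_content` (saturated vs oven-dry mass) if
needed. A hold whose diameter range is degenerate (the starting hold) but
carries noise-level enthalpy has that mass merged into the next bin with a
warning rather than failing the run.

**Default schedule.** Holds at −30, −10, −5, −3, −2, −1.2, −0.6, −0.2 and
+2 °C, 600 s each — a deep-frozen start, a ladder through the mesopore
melting range, and a bulk-melt hold. Isothermal schedules are
instrument-specific; everything schedule-dependent is configuration, not
constant.

## Immunofluorescence quantification

The workflow mirrors the classic two-channel macro: maximum projection over
z of both channels; a binary wall mask from the counterstain projection —
manual threshold for fidelity to interactive use, Otsu as the scriptable
default — optionally restricted to an ROI polygon (pixel units, (row, col)
vertices, even-odd fill); masked arithmetic mean of the target channel.
Masking is applied after projection, matching the macro's order. Masking
matters because the epitope lives only in the wall: an unmasked mean is
diluted by empty lumina in proportion to the lumen fraction, which differs
between genotypes.

Fold changes between groups are ratios of group means. Sections, not
pixels, are the independent replicates, so the percentile bootstrap CI
(default 95%, 2000 resamples) resamples section-level means within each
group. Sections are equally weighted by default; pixel-count weighting
(`aggregate="pixels"`) is offered because published analyses are ambiguous
between the two — with balanced masks they agree.

## Group statistics

Gate: parametric iff every group's Shapiro–Wilk p ≥ 0.05 *and* Bartlett's
p ≥ 0.05 (per-group Shapiro by default; pooled group-centred residuals as
an option). A zero-variance group forces the nonparametric path with a
warning. Note the arithmetic consequence of the gate: under a true normal
null with k groups, k + 1 independent-ish tests each reject 5%, so the
parametric path is taken only ≈ 0.95^(k+1) of the time (≈ 81% for k = 3).
That is a property of this widely used gate, not a defect of the
implementation.

Parametric path: one-way ANOVA omnibus plus Tukey HSD pairwise p-values
from the exact studentized-range distribution (`scipy.stats.tukey_hsd`);
with k = 2 this reduces to the pooled-variance two-sample t-test, which the
suite checks to 1e−6. Nonparametric path: Kruskal–Wallis omnibus plus
pairwise Wilcoxon rank-sum tests with Holm adjustment — exact enumeration
of the rank-sum null for tie-free samples of n ≤ 10 per group, mid-rank
normal approximation with continuity correction otherwise. (The
continuity-corrected approximation alone is visibly conservative at n = 10;
exact enumeration restores the family-wise error to its nominal
neighbourhood.) The pairwise procedure is pluggable (`pairwise_fn`) so a
relative-effect contrast implementation can be slotted in.

Letter display: insert-and-absorb at α = 0.05 — start from one column
holding all groups, split every column containing a significantly different
pair, absorb subset columns, re-insert singletons for groups that lost all
columns, letter columns in order of their earliest member (groups ordered
alphabetically). By construction two groups share a letter iff their
adjusted p ≥ α; an exhaustive verifier re-checks this on every output.
Minimal letter count is not guaranteed (it is NP-hard in general);
absorption keeps displays compact in practice.

`type1_error_sim` estimates the family-wise error rate of either path under
a normal null. For the parametric path it uses the exact equivalence
"some Tukey-adjusted p < α ⟺ the largest studentized range statistic
exceeds its (1 − α) quantile", replacing thousands of p-value integrations
with one quantile lookup; the suite separately verifies this equivalence
against the full pairwise matrix.

## Synthetic data: what it emulates, and what it does not

Defaults were chosen once to match realistic operating conditions and are
the conditions under which all recovery benchmarks run:

* **DVS** — Park parameters A_L = 2, b_L = 15, k_H = 12, k_a = 1e−8, n = 8
  (mass gain ≈ 2.4% at a_w = 0.1, ≈ 27.5% at 0.9, the scale of
  lignocellulosic samples at 25 °C); dry mass 20 mg; τ = 20 min; 6τ holds;
  first-order exponential approach to equilibrium — the simplest law
  consistent with a dm/dt criterion. Real sorption kinetics are
  multi-exponential/diffusive; the generator does not model water
  transport, so kinetic-shape analyses must not be read into it.
* **DSC** — Gaussian endotherms centred mid-hold (σ = 30 s): only areas
  carry information for the analysis, so peak shape is free; sample 8 mg;
  ramps at 1 K/min; endotherm-positive sign declared in metadata. No
  supercooling, nucleation kinetics or baseline curvature.
* **Imaging** — honeycomb lattice (lumen radius 12 px, wall 4 px) giving
  ≈ 34% wall pixels; counterstain 120, target wall/background 100/10 on an
  8-bit scale; per-voxel Gaussian noise σ = 5; z = 3 planes attenuated by a
  (1.0, 0.8, 0.6) focal profile. The attenuation matters: max-projecting z
  planes of *equal* signal plus i.i.d. noise inflates intensities by
  ≈ 0.85σ (the expected maximum of the noise), biasing ratios; with a
  declining focal profile the projection selects the focal plane and stays
  essentially unbiased, which is also how a focused confocal stack behaves.
  Group-comparison benchmarks add 3% between-section intensity variability
  so that section-level CIs reflect genuine replicate scatter. No optics,
  PSF or photobleaching are modelled.
* **Groups** — i.i.d. draws from normal, lognormal (parameters on the log
  scale) or moment-matched uniform distributions.

All generators take mandatory seeds and are byte-deterministic given them.
Passing recovery tests on these inputs demonstrates that the *analysis*
chain is correct and self-consistent — not that real instruments satisfy
the generators' assumptions.

## Problem sizes and tolerances

Recovery benchmarks use 9-point isotherms, ~22k-sample kinetic traces,
~5k-sample thermograms, 96×96×3 image stacks × 10 sections × 2 groups × 50
replicates, and 1000-replicate null simulations for error rates — sizes at
which every Monte-Carlo band in the suite is stable across reruns while the
whole suite stays fast. Documented tolerances: Park parameter recovery
within 5% at zero noise (MRD < 0.1%); equilibrium masses within 0.25% of
the asymptote for 6τ holds; isotherm round trip within 0.5% per point;
pore-fraction recovery within 2 percentage points with mass conservation to
0.5%; intensity-ratio recovery within 5% with ≥ 90% CI coverage over 50
replicates; family-wise error within 3 binomial standard errors of 0.05 at
1000 replicates.

## Known limitations

* The Park fit is over-parameterised for smooth 9-point isotherms: with
  noise, parameter point estimates (especially k_a and n, which trade off
  against each other inside `n·k_a·(k_H a)^n`) can wander far from truth
  while the fitted curve and MRD remain excellent. Interpret individual
  parameters only from dense, low-noise data.
* Gibbs–Thomson inversion assumes cylindrical pores, a single contact
  angle, and bulk water properties in confinement; diameters are
  model-relative, as in all cryoporometry.
* The nonparametric pairwise procedure is a Holm-adjusted rank-sum
  substitute for relative-effect Tukey-type contrasts; adjusted p-values
  will differ from that method even though both control the family-wise
  error.
* Otsu thresholding assumes a bimodal counterstain histogram; dim or
  unevenly stained sections need a manual threshold and/or ROI.
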