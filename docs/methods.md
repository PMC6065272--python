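# Methods

This note documents the models, numerical conventions and design choices
behind `sticklevision`, and what the synthetic-data generator does and does
not emulate.

## Spectral conventions

All model arithmetic runs on a fixed wavelength grid of 300–700 nm at 1-nm
steps (401 points). Input spectra are linearly interpolated onto this grid;
extrapolation is refused because it invents signal outside the measured
span. Integrals (quantum catch, von Kries denominators, band areas) use the
trapezoid rule on this grid, with one deliberate exception: orange-red
sensitivity is the plain **sum** of weighted absorbance values at the grid
points in [590, 650] nm, because the quantity is defined as a summed
absorbance, not an integral.

Replicate scans are collapsed by the per-wavelength median (even counts use
the midpoint of the central pair). Raw reflectance counts are divided by the
matching white-standard scan, which cancels lamp drift exactly because both
are measured under the same lamp state. Irradiance in W m⁻² nm⁻¹ is
converted to photon units via the physical relation
μmol = W · λ / (h c N_A) · 10⁶; this replaces an instrument calibration
lamp, whose data are not public, and is exact up to the calibration's own
accuracy. A flag selects raw versus surface-normalized irradiance; raw is
the default.

## Color and opsin compositions

Male color is the fraction of reflectance area in the four closed bands
301–400, 401–500, 501–600, 601–700 nm. The 300–301 nm sliver and the 1-nm
segments straddling band boundaries (400–401 nm, etc.) belong to no band —
the bands are taken literally as printed intervals; the affected area is
well under 1%. Opsin profiles are raw expression values divided by their
sum. Both vectors live on the 3-simplex and are scale-invariant by
construction.

## Visual model

Pigment absorbance uses the standard vertebrate rhodopsin template (α band
plus β band) for A1 pigments, with the A2 variant available; templates are
renormalized so the grid maximum is exactly 1. Cone peak sensitivities
default to the midpoints of the published microspectrophotometry ranges —
SWS1 373.5, SWS2 437.5, RH2 530 nm — while LWS, whose peak depends on the
A1/A2 chromophore balance, is run at 566 (lower bound), 638 (upper bound)
or 602 nm (median, the default, effectively averaging across chromophores).
Lens, ocular-media and oil-droplet transmission are not modelled: no
transmission data exist for this species, and behavioral evidence indicates
the eye transmits 300–700 nm well enough for qualitative conclusions.

The RNL chain is: quantum catch → von Kries adaptation to the sidewelling
background → log receptor contrast → noise-weighted tetrachromatic ΔS. The
background for both the contrast and the adaptation is the sidewelling
irradiance itself (background reflectance ≡ 1): sidewelling light is the
veil against which a displaying male is seen by a conspecific at the same
depth. Because the adapting light equals the background light, background
adapted catches are identically 1 and ΔS is invariant to rescaling all
irradiance by a positive constant — two identities the tests verify to
1e-10. The tetrachromatic numerator contains all six receptor-pair terms;
the implementation is checked against the general n-receptor formulation
(noise-metric projection orthogonal to the achromatic direction) to 1e-12.
The Weber fraction defaults to ω = 0.05, a conservative value for fish. A
cone class with zero expression would have divergent noise; such a class is
dropped and the trichromatic (or dichromatic) analogue used, which is the
continuous limit.

Receptor densities η_c are equated to relative opsin mRNA expression. This
is the model's central proxy assumption: mRNA abundance is taken as
proportional to functional cone-class density.

## Transplant null

The grid evaluates ΔS for every (color donor i, opsin donor j, nest depth
of male k) triple — the opsin donor is the *viewer* — giving n³ cells; cell
(i,i,i) is the observed configuration. Contrasts depend only on (i, depth)
and noise only on j, so the grid is assembled from an n×depth contrast
sheet and n noise vectors; a test confirms every cell equals a
one-at-a-time evaluation. Nest depths are mapped to the nearest measured
irradiance depth (50-cm grid). The null expectation at a depth is the mean
over all n² pairings including self-pairings ("all" is read literally); a
no-self-pairing toggle exists. The deviation test is a two-sided one-sample
t on empirical − null with df = n − 1.

A caveat established by simulation in this package: because each male's
empirical cell is itself part of the pairing sheet that defines his null,
and ΔS is to first order additive in a color effect and an opsin effect,
the per-male deviations are mechanically close to sample-centered. Under a
generating process with color and opsins independent of depth, the null
distribution of the t statistic has standard deviation ≈ 0.19 rather than
≈ 1, so the test is strongly conservative: it essentially never rejects at
α = 0.05 under its null, and a non-significant result is weaker evidence
against microhabitat tuning than a nominal t test would suggest. The mean
deviation itself is unbiased (≈ 0 under the null).

## Statistics

CCA is computed by SVD: orthonormal bases of the two centered column
spaces, then the SVD of their cross-product; canonical correlations are the
singular values, clipped to [0, 1]. Compositional blocks are rank-3 after
centering; rank is truncated at singular values below 1e-10 of the largest,
which makes results invariant to the arbitrary choice of a "redundant"
component. Variate scores are standardized to unit variance; loadings are
variable–variate Pearson correlations. Axes are oriented so the orange-red
color loading on each axis is positive ("redder" points in the positive
direction), with signs flipped jointly in both blocks.

Axis significance uses sequential permutation tests with Wilks'
Λ_a = Π_{i≥a}(1 − r_i²): rows of the opsin block are permuted with the
color block fixed, the CCA rerun, and p = (1 + #{Λ_perm ≤ Λ_obs}) / (1 +
n_perm) (add-one convention; minimum attainable p is 1/(1 + n_perm)). All
axes are reported; no gatekeeping stop rule. Type-I error at n = 16 is
verified by simulation to sit near the nominal 5%.

A small-sample degeneracy worth knowing: with two rank-3 blocks the first
canonical correlation is *exactly* 1 whenever n − 1 ≤ 5, since the
subspaces must intersect; n ≥ 8 is needed for a meaningful first axis, and
the emulated design (n = 16) is comfortably above this.

The path model is the saturated three-variable system (depth → opsins,
depth → color, opsins ↔ color) on internally standardized first canonical
variate scores. Being just-identified, its ML estimates are closed-form
(r(d,o), r(d,c), and r(o,c) − r(d,o)·r(d,c)) and the implied matrix
reproduces the sample correlation matrix to machine precision; standard
errors come from the numerically differentiated information matrix of the
Wishart ML discrepancy with an (n−1) divisor, and p-values are two-sided
normal, matching the estimate/SE/z reporting convention for path analyses.
The fit is authored here directly because no installed package provides
structural-equation modelling; the closed-form identities serve as its
independent check.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
fixture: defaults are n = 16 males, nest depths uniform on 0–2.5 m,
irradiance at 50-cm intervals with 3 replicates, two body regions with 3
reflectance replicates each.

* **Optics.** Surface downwelling irradiance is a smooth daylight-like
  curve (broad Gaussian peaking near 560 nm plus a floor, ~O(1) W m⁻²
  nm⁻¹). Depth attenuation is Beer–Lambert with a piecewise-linear K(λ)
  through (300, 1.5), (500, 0.35), (700, 2.6) m⁻¹ — minimal in the
  blue-green and rising steeply into the red, the usual shape for slightly
  stained lake water. Sidewelling is a fixed fraction (0.2) of downwelling
  with an independent noise draw. Measurement noise is multiplicative
  lognormal so spectra stay nonnegative.
* **Color.** Reflectance is a region-specific baseline plus a UV hump
  (Gaussian at 370 nm) and a carotenoid-like long-pass step (logistic,
  inflection 550 nm, width 30 nm) whose amplitude scales with a latent
  redness in [0, 1]; the orange-red band proportion is strictly increasing
  in redness.
* **Planted structure.** Latent standard-normal redness and LWS
  (additive-log-ratio) coordinates are built from standardized depth plus
  shared and idiosyncratic Gaussian components so that the depth effects
  equal `beta_depth_color` / `beta_depth_opsin` and their mutual
  correlation equals `rho_color_lws` exactly on the latent scale;
  infeasible combinations (non-PSD) are rejected with a message. Opsin
  profiles are logistic-normal around a typical profile of roughly
  (0.12, 0.25, 0.38, 0.25) for (SWS1, SWS2, RH2, LWS); raw expression is
  the profile times a lognormal total, so recomputed proportions equal the
  simplex draw identically. Defaults plant a strong color–LWS correlation
  (0.8) and modest depth effects (0.42 on opsins, 0.10 on color), the
  regime the emulated study design is powered to detect.
* **Written tables.** `write_study` emits lamp-modulated raw counts plus
  per-male white scans (so the pipeline must actually perform
  white-normalization), irradiance in W m⁻² nm⁻¹ (so the pipeline must
  convert units), raw expression, and a `truth.json` with the realized
  latent values for parameter-recovery scoring.

What the generator does **not** emulate: Snell's-window and surface-wave
optics, spatial heterogeneity of the water column, within-male temporal
color change, melanic color morphs, distance-dependent attenuation between
signaler and viewer, and any realistic covariance between the three
non-LWS opsins. Passing tests therefore demonstrate correctness and
calibration of the *methods* under a plausible optical-statistical regime,
not field realism of any particular effect size.

## Problem sizes and determinism

Simulation-based checks use 16-male studies: 500 replicate studies for
type-I calibration of the permutation test (199 permutations each), 200
studies per condition for power monotonicity and for transplant-null
calibration. These sizes put Monte-Carlo standard errors on rejection rates
near 0.01–0.015, adequate for the bands being checked. The pipeline derives
every random stream (generator substreams, permutation order) from one
integer seed, and report files contain no timestamps, so a rerun with the
same inputs and seed is byte-identical apart from the provenance hash of
the output location.
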