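# sticklevision

Visual modelling and signal–sensory statistics for nuptial color in
threespine stickleback (*Gasterosteus aculeatus*).

Breeding male stickleback display carotenoid-based red throat and abdomen
coloration, and their retinas express four cone opsins — SWS1 (UV), SWS2
(blue), RH2 (green) and LWS (red) — in proportions that vary between
individuals. This package asks, on fully synthetic but statistically
structured data emulating a 16-male nesting study: do redder males carry
retinas more sensitive to orange-red light, and is any such signal–sensory
correlation an artifact of both traits being tuned to the optical
microhabitat (nest depth)?

It is intended for sensory ecologists and evolutionary biologists who want
a tested, scriptable implementation of this analysis chain — from raw
spectrometer-style tables to receptor-noise contrasts and permutation
statistics — rather than a one-off analysis script.

## What it computes

**Receptor-noise-limited (RNL) color discrimination.** For cone class *c*
with pigment absorbance template *A_c(λ)* (Govardovskii-style α+β band
templates, A1 or A2 chromophore), target reflectance *S(λ)* and illuminant
*I(λ)*:

- quantum catch  Q_c = ∫₃₀₀⁷⁰⁰ A_c(λ) S(λ) I(λ) dλ
- von Kries adaptation  q_c = k_c Q_c,  k_c = 1 / ∫ A_c(λ) I_b(λ) dλ
- receptor contrast  Δf_c = ln(q_c,target / q_c,background)
- channel noise  e_c = ω / √η_c  (Weber fraction ω = 0.05; η_c = relative
  receptor density, proxied by relative opsin expression)
- tetrachromatic chromatic contrast ΔS (JND units): the standard
  noise-weighted quotient over all six receptor pairs.

A male's color patch is lit by downwelling irradiance at his nest depth and
viewed against sidewelling irradiance (which is also the adapting light).

**In-silico transplant experiment.** Color patches and opsin profiles are
permuted exhaustively across males: ΔS is evaluated for every (color donor,
opsin donor) pairing at every nest depth (n³ cells). The mean over all n²
pairings at a depth is the null expectation for contrast there; a
one-sample *t* test of per-male deviations (empirical − null) asks whether
residents are nonrandomly matched to their microhabitat.

**Signal–sensory statistics.** Canonical correlation analysis between the
four reflectance band proportions (UV-blue 301–400, blue-green 401–500,
green-orange 501–600, orange-red 601–700 nm) and the four opsin expression
proportions, with sequential permutation tests on Wilks' Λ = Π(1 − r_i²);
OLS regression of color on summed orange-red (590–650 nm) retinal
absorbance; and a saturated three-variable path model (depth → opsins,
depth → color, opsins ↔ color) with ML standard errors.

**Synthetic study generator.** Every input table (reflectance replicates
with white-standard scans, depth-stratified down/sidewelling irradiance in
W m⁻² nm⁻¹, raw opsin expression) is generated with planted, tunable
statistical structure — the color↔LWS correlation, depth→opsin and
depth→color effects — so every downstream stage is testable end to end.

## Worked example

```bash
sticklevision simulate demo --seed 7
sticklevision run-all demo --seed 7 --n-perm 999
```

prints

```
preoperculum: CCA axis-1 r^2 = 0.931 (p = 0.001); transplant t(15) = -0.063
abdomen: CCA axis-1 r^2 = 0.917 (p = 0.001); transplant t(15) = -0.055
```

and `demo/results/summary.txt` contains, for the abdomen:

```
CCA axis 1: r^2 = 0.917, permutation p = 0.001 (999 permutations)
orange-red sensitivity vs color: r^2 = 0.890, p = 4.262e-08
transplant null: t(15) = -0.055, p = 0.957, mean deviation = -0.03912
path model (standardized):
    depth->opsins:  0.440 (SE 0.232, z 1.895, p 0.058)
     depth->color:  0.451 (SE 0.230, z 1.957, p 0.050)
   opsins<->color:  0.759 (SE 0.285, z 2.664, p 0.008)
```

Reading: the first canonical axis ties redder males (positive orange-red
color loading) to higher relative LWS expression (positive LWS loading) and
is significant under the permutation test; redder males' expression-weighted
retinas absorb more orange-red light (regression); the near-zero transplant
*t* says resident males are no more conspicuous at their own depth than
randomly transplanted color/opsin combinations; and the path model
attributes the color–opsin association to a direct link, not to shared
depth tuning. Per-male tables (`color_proportions.csv`, `transplant.csv`,
`cca_result.csv`, `loadings.csv`, `path_fit.csv`, …) are written next to
the summary, each with a provenance header (version, seed, config hash).

The same machinery is available as a library:

```python
from sticklevision import SimConfig, simulate_males, VisualSystem, male_contrast

study = simulate_males(SimConfig(seed=7))
male = study.males[0]
vs = VisualSystem(eta=male.opsin)           # his own retina as the viewer
res = male_contrast(male.reflectance["abdomen"], male.opsin,
                    male.depth_m, study.irradiance_field, vs)
print(res.delta_s)                          # chromatic contrast in JNDs
```

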