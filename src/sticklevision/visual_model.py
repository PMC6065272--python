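"""Photoreceptor noise-limited color discrimination model for stickleback.

The chain is the standard receptor-noise-limited (RNL) model for a
tetrachromat:

1.  Visual pigment absorbance templates A_c(lambda) (Govardovskii-style
    alpha + beta band rhodopsin templates, A1 or A2 chromophore) for the
    four cone classes SWS1 (U), SWS2 (S), RH2 (M), LWS (L).
2.  Quantum catch  Q_c = integral_300^700 A_c(l) S(l) I(l) dl  for target
    reflectance S under illuminant I.
3.  von Kries adaptation  q_c = k_c Q_c  with
    k_c = 1 / integral A_c(l) I_b(l) dl  for adapting background I_b.
4.  Receptor contrast  Delta f_c = ln(q_c,target / q_c,background).
5.  Channel noise  e_c = omega / sqrt(eta_c)  (Weber fraction omega,
    relative receptor density eta_c), and the tetrachromatic chromatic
    contrast Delta S in just-noticeable-difference units.

Receptor densities eta_c are proxied by relative opsin expression, so each
male carries his own visual system. Lens/ocular-media/oil-droplet
transmission is deliberately not modelled (no transmission data exist for
this species); templates are used as normalized absorbance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .color_metrics import OpsinProfile
from .spectra_io import STANDARD_GRID, IrradianceField, Spectrum

__all__ = [
    "LWS_LAMBDA_MAX",
    "DEFAULT_LAMBDA_MAX",
    "PigmentTemplate",
    "VisualSystem",
    "ContrastResult",
    "pigment_absorbance",
    "quantum_catch",
    "von_kries",
    "receptor_contrast",
    "receptor_noise",
    "delta_S",
    "retina_weighted_absorbance",
    "orange_red_sensitivity",
    "male_contrast",
]

#: LWS peak-sensitivity variants: microspectrophotometry bounds across the
#: A1/A2 chromophore range, and their median (averaging across chromophores).
LWS_LAMBDA_MAX = {"lower": 566.0, "upper": 638.0, "median": 602.0}

#: Default peak sensitivities (nm): midpoints of the published MSP ranges
#: SWS1 365-382, SWS2 434-441, RH2 514-546; LWS per variant.
DEFAULT_LAMBDA_MAX = {"sws1": 373.5, "sws2": 437.5, "rh2": 530.0}

_CONES = ("sws1", "sws2", "rh2", "lws")


@dataclass(frozen=True)
class PigmentTemplate:
    """Normalized visual pigment absorbance spectrum (peak ~= 1)."""

    lambda_max: float
    chromophore: str
    absorbance: Spectrum

    @property
    def values(self) -> np.ndarray:
        return self.absorbance.values


def _govardovskii_alpha_a1(lam: np.ndarray, lmax: float) -> np.ndarray:
    x = lmax / lam
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def _govardovskii_beta_a1(lam: np.ndarray, lmax: float) -> np.ndarray:
    lmb = 189.0 + 0.315 * lmax
    b = -40.5 + 0.195 * lmax
    return 0.26 * np.exp(-(((lam - lmb) / b) ** 2))


def _govardovskii_alpha_a2(lam: np.ndarray, lmax: float) -> np.ndarray:
    x = lmax / lam
    a = 0.875 + 0.0268 * np.exp((lmax - 665.0) / 40.7)
    big_a = 62.7 + 1.834 * np.exp((lmax - 625.0) / 54.2)
    return 1.0 / (
        np.exp(big_a * (a - x))
        + np.exp(20.85 * (0.9101 - x))
        + np.exp(-10.37 * (1.1123 - x))
        + 0.5343
    )


def _govardovskii_beta_a2(lam: np.ndarray, lmax: float) -> np.ndarray:
    lmb = 216.7 + 0.287 * lmax
    b = 317.0 - 1.149 * lmax + 0.00124 * lmax**2
    return 0.37 * np.exp(-(((lam - lmb) / b) ** 2))


def pigment_absorbance(
    lambda_max: float,
    chromophore: str = "A1",
    grid: np.ndarray | None = None,
    include_beta_band: bool = True,
) -> PigmentTemplate:
    """Rhodopsin absorbance template evaluated on the wavelength grid.

    Alpha band plus (optionally) the beta band of the standard vertebrate
    visual-pigment template, renormalized so the grid maximum is 1.
    """
    if not 330.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside template validity")
    if chromophore not in ("A1", "A2"):
        raise ValueError("chromophore must be 'A1' or 'A2'")
    lam = STANDARD_GRID if grid is None else np.asarray(grid, dtype=float)
    if chromophore == "A1":
        vals = _govardovskii_alpha_a1(lam, lambda_max)
        if include_beta_band:
            vals = vals + _govardovskii_beta_a1(lam, lambda_max)
    else:
        vals = _govardovskii_alpha_a2(lam, lambda_max)
        if include_beta_band:
            vals = vals + _govardovskii_beta_a2(lam, lambda_max)
    vals = vals / vals.max()
    return PigmentTemplate(lambda_max, chromophore, Spectrum(lam, vals, "absorbance"))


@dataclass(frozen=True)
class VisualSystem:
    """Per-cone peak sensitivities, Weber fraction and receptor densities.

    ``lws_variant`` selects the LWS peak among the chromophore bounds
    {lower: 566, upper: 638, median: 602 nm}; ``eta`` holds the relative
    receptor densities (opsin expression proportions) used for channel
    noise; ``omega`` is the Weber fraction of the most abundant channel.
    """

    eta: OpsinProfile
    omega: float = 0.05
    lws_variant: str = "median"
    chromophore: str = "A1"
    include_beta_band: bool = True
    lambda_max_overrides: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("Weber fraction must be positive")
        if self.lws_variant not in LWS_LAMBDA_MAX:
            raise ValueError(f"unknown LWS variant {self.lws_variant!r}")

    def lambda_max(self, cone: str) -> float:
        if cone in self.lambda_max_overrides:
            return float(self.lambda_max_overrides[cone])
        if cone == "lws":
            return LWS_LAMBDA_MAX[self.lws_variant]
        return DEFAULT_LAMBDA_MAX[cone]

    def templates(self) -> dict[str, PigmentTemplate]:
        return {
            cone: pigment_absorbance(
                self.lambda_max(cone),
                self.chromophore,
                include_beta_band=self.include_beta_band,
            )
            for cone in _CONES
        }

    def template_matrix(self) -> np.ndarray:
        """4 x n_wavelengths array of template absorbances (U, S, M, L)."""
        tpl = self.templates()
        return np.stack([tpl[c].values for c in _CONES])

    def with_eta(self, eta: OpsinProfile) -> "VisualSystem":
        return VisualSystem(
            eta,
            self.omega,
            self.lws_variant,
            self.chromophore,
            self.include_beta_band,
            dict(self.lambda_max_overrides),
        )


@dataclass(frozen=True)
class ContrastResult:
    """Full trace of one RNL contrast evaluation (per cone class U,S,M,L)."""

    Q_target: np.ndarray
    Q_background: np.ndarray
    k: np.ndarray
    q_target: np.ndarray
    q_background: np.ndarray
    delta_f: np.ndarray
    e: np.ndarray
    delta_s: float


def quantum_catch(template: PigmentTemplate, S: Spectrum, I: Spectrum) -> float:
    """Absolute quantum catch: trapezoid integral of A(l) S(l) I(l) over 300-700."""
    wl = template.absorbance.wavelengths
    if not (np.array_equal(S.wavelengths, wl) and np.array_equal(I.wavelengths, wl)):
        raise ValueError("template, reflectance and irradiance grids must match")
    return float(np.trapezoid(template.values * S.values * I.values, wl))


def von_kries(
    Q: Sequence[float],
    templates: Sequence[PigmentTemplate],
    I_b: Spectrum,
) -> np.ndarray:
    """Adapted catches q_c = k_c Q_c with k_c = 1 / integral A_c(l) I_b(l) dl."""
    q = np.empty(len(Q))
    for i, (qc, tpl) in enumerate(zip(Q, templates)):
        denom = np.trapezoid(tpl.values * I_b.values, tpl.absorbance.wavelengths)
        if denom <= 0:
            raise ValueError(
                f"adapting catch is zero for cone class {i}: adaptation undefined"
            )
        q[i] = qc / denom
    return q


def receptor_contrast(q_target: np.ndarray, q_background: np.ndarray) -> np.ndarray:
    """Delta f_c = ln(q_target / q_background), per cone class."""
    q_target = np.asarray(q_target, dtype=float)
    q_background = np.asarray(q_background, dtype=float)
    if np.any(q_target <= 0) or np.any(q_background <= 0):
        raise ValueError("adapted catches must be positive to take log contrasts")
    return np.log(q_target / q_background)


def receptor_noise(omega: float, eta_c: float) -> float:
    """Channel noise e_c = omega / sqrt(eta_c)."""
    if omega <= 0:
        raise ValueError("Weber fraction must be positive")
    if eta_c <= 0:
        raise ValueError(
            "eta_c must be positive; a class with zero density must be dropped"
        )
    return omega / np.sqrt(eta_c)


def _delta_s_tetra(df: np.ndarray, e: np.ndarray) -> float:
    e1, e2, e3, e4 = e
    f1, f2, f3, f4 = df
    num = (
        (e1 * e2) ** 2 * (f4 - f3) ** 2
        + (e1 * e3) ** 2 * (f4 - f2) ** 2
        + (e1 * e4) ** 2 * (f3 - f2) ** 2
        + (e2 * e3) ** 2 * (f4 - f1) ** 2
        + (e2 * e4) ** 2 * (f3 - f1) ** 2
        + (e3 * e4) ** 2 * (f2 - f1) ** 2
    )
    den = (
        (e1 * e2 * e3) ** 2
        + (e1 * e2 * e4) ** 2
        + (e1 * e3 * e4) ** 2
        + (e2 * e3 * e4) ** 2
    )
    return float(np.sqrt(num / den))


def _delta_s_tri(df: np.ndarray, e: np.ndarray) -> float:
    e1, e2, e3 = e
    f1, f2, f3 = df
    num = (
        e1**2 * (f3 - f2) ** 2 + e2**2 * (f3 - f1) ** 2 + e3**2 * (f2 - f1) ** 2
    )
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return float(np.sqrt(num / den))


def delta_S(delta_f: Sequence[float], e: Sequence[float]) -> float:
    """Receptor-noise-limited chromatic contrast in JND units.

    Four classes use the tetrachromatic quotient (all six pairwise noise
    terms in the numerator); classes whose noise diverged because their
    density is zero should be dropped by the caller, in which case the
    trichromatic/dichromatic analogues apply. Any common shift of all
    Delta f (an achromatic change) gives Delta S = 0.
    """
    df = np.asarray(delta_f, dtype=float)
    ev = np.asarray(e, dtype=float)
    if df.shape != ev.shape:
        raise ValueError("delta_f and e must have equal length")
    if not np.all(np.isfinite(df)):
        raise ValueError("non-finite receptor contrast")
    if np.any(ev <= 0) or not np.all(np.isfinite(ev)):
        raise ValueError("receptor noise must be positive and finite")
    n = df.size
    if n == 4:
        return _delta_s_tetra(df, ev)
    if n == 3:
        return _delta_s_tri(df, ev)
    if n == 2:
        return float(np.abs(df[0] - df[1]) / np.sqrt(ev[0] ** 2 + ev[1] ** 2))
    raise ValueError("delta_S needs 2-4 receptor classes")


def _noise_vector(eta: OpsinProfile, omega: float) -> tuple[np.ndarray, np.ndarray]:
    """(kept-class mask, noise for kept classes); zero-density classes drop out."""
    etas = eta.as_array()
    keep = etas > 0
    if keep.sum() < 2:
        raise ValueError("need at least two cone classes with positive density")
    return keep, omega / np.sqrt(etas[keep])


def retina_weighted_absorbance(eta: OpsinProfile, vs: VisualSystem) -> Spectrum:
    """Expression-weighted retinal absorbance: sum_c eta_c A_c(lambda)."""
    weighted = eta.as_array() @ vs.template_matrix()
    return Spectrum(STANDARD_GRID, weighted, "absorbance")


def orange_red_sensitivity(
    weighted: Spectrum, irradiance: Spectrum | None = None
) -> float:
    """Summed absorbance over grid points in [590, 650] nm.

    The plain sum of the weighted-absorbance values; pass ``irradiance`` to
    weight each grid point by ambient light before summing (off by default).
    """
    if not weighted.on_standard_grid():
        raise ValueError("expected the standard 300-700 nm grid")
    sel = (weighted.wavelengths >= 590) & (weighted.wavelengths <= 650)
    vals = weighted.values[sel]
    if irradiance is not None:
        if not irradiance.on_standard_grid():
            raise ValueError("irradiance must share the standard grid")
        vals = vals * irradiance.values[sel]
    return float(vals.sum())


def male_contrast(
    reflectance: Spectrum,
    viewer_eta: OpsinProfile,
    depth: float,
    field: IrradianceField,
    vs: VisualSystem,
) -> ContrastResult:
    """Chromatic contrast of a male's color patch at a nest depth.

    The target is the reflectance lit by downwelling irradiance at the
    (nearest measured) depth; the visual background is the sidewelling
    irradiance itself (background reflectance == 1), which also serves as
    the adapting light for von Kries normalization. The viewer's opsin
    profile sets the receptor densities; classes with zero density are
    dropped and the lower-dimensional contrast used.
    """
    if not reflectance.on_standard_grid():
        raise ValueError("reflectance must be on the standard grid")
    down = field.at(depth, "down")
    side = field.at(depth, "side")
    templates = [vs.templates()[c] for c in _CONES]
    Q_t = np.array([quantum_catch(t, reflectance, down) for t in templates])
    ones = Spectrum(STANDARD_GRID, np.ones_like(STANDARD_GRID), "reflectance")
    Q_b = np.array([quantum_catch(t, ones, side) for t in templates])
    for i, (qt, qb) in enumerate(zip(Q_t, Q_b)):
        if qt <= 0 or qb <= 0:
            raise ValueError(f"zero quantum catch for cone class {_CONES[i]}")
    k = np.array(
        [
            1.0 / np.trapezoid(t.values * side.values, STANDARD_GRID)
            for t in templates
        ]
    )
    q_t = k * Q_t
    q_b = k * Q_b
    df = receptor_contrast(q_t, q_b)
    keep, e = _noise_vector(viewer_eta, vs.omega)
    ds = delta_S(df[keep], e)
    e_full = np.full(4, np.nan)
    e_full[keep] = e
    return ContrastResult(Q_t, Q_b, k, q_t, q_b, df, e_full, ds)
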