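"""Compositional color and opsin-expression metrics.

Male color is summarized as the proportions of reflectance area in four
100-nm bands (UV-blue 301-400, blue-green 401-500, green-orange 501-600,
orange-red 601-700 nm); retinal tuning as the proportion each cone opsin
(SWS1, SWS2, RH2, LWS) contributes to total cone-opsin expression. Both
live on the 3-simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "BANDS",
    "OPSINS",
    "ColorProportions",
    "OpsinProfile",
    "band_proportions",
    "relative_expression",
]

#: Color bands as printed: closed nm intervals. The 300-301 nm sliver and
#: the segments straddling band boundaries (e.g. 400-401) belong to no band.
BANDS = {
    "p_uv_blue": (301, 400),
    "p_blue_green": (401, 500),
    "p_green_orange": (501, 600),
    "p_orange_red": (601, 700),
}

OPSINS = ("sws1", "sws2", "rh2", "lws")


@dataclass(frozen=True)
class ColorProportions:
    p_uv_blue: float
    p_blue_green: float
    p_green_orange: float
    p_orange_red: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError("color proportions must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("color proportions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_uv_blue, self.p_blue_green, self.p_green_orange, self.p_orange_red]
        )


@dataclass(frozen=True)
class OpsinProfile:
    """Relative cone-opsin expression; the receptor densities eta_c."""

    eta_sws1: float
    eta_sws2: float
    eta_rh2: float
    eta_lws: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < 0):
            raise ValueError("opsin proportions must be nonnegative")
        if abs(vec.sum() - 1.0) > 1e-12:
            raise ValueError("opsin proportions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_sws1, self.eta_sws2, self.eta_rh2, self.eta_lws])


def band_proportions(reflectance: Spectrum) -> ColorProportions:
    """Proportion of reflectance area under each of the four color bands.

    Trapezoid area within each closed band, divided by the summed area of
    the four bands. Requires the standard 1-nm grid so band endpoints fall
    exactly on grid points.
    """
    if not reflectance.on_standard_grid():
        raise ValueError("band_proportions requires the standard 300-700 nm grid")
    wl, vals = reflectance.wavelengths, reflectance.values
    areas = []
    for lo, hi in BANDS.values():
        sel = (wl >= lo) & (wl <= hi)
        areas.append(np.trapezoid(vals[sel], wl[sel]))
    areas = np.array(areas)
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total reflectance area: color undefined")
    return ColorProportions(*(areas / total))


def relative_expression(raw) -> OpsinProfile:
    """Raw (sws1, sws2, rh2, lws) expression -> proportions of the total."""
    vec = np.asarray(raw, dtype=float)
    if vec.shape != (4,):
        raise ValueError("expected four expression values (sws1, sws2, rh2, lws)")
    if np.any(vec < 0):
        raise ValueError("expression values must be nonnegative")
    total = vec.sum()
    if total <= 0:
        raise ValueError("all expression values are zero")
    return OpsinProfile(*(vec / total))
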