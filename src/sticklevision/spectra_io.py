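"""Read, validate, resample and normalize spectral data.

All model math in this package runs on a common 1-nm wavelength grid
spanning 300-700 nm (the integration bounds of the visual model).
Spectrometer exports are long-format CSV tables with a ``wavelength_nm``
column, a ``value`` column and optional grouping labels (male_id, region,
replicate, depth_m, direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, c as speed_of_light, h as planck

__all__ = [
    "STANDARD_GRID",
    "Spectrum",
    "IrradianceField",
    "read_spectra",
    "write_spectra",
    "resample",
    "median_replicates",
    "normalize_to_white",
    "normalize_irradiance",
    "watts_to_umol",
    "read_irradiance_field",
]

#: Standard wavelength grid: 300-700 nm inclusive, 1-nm step.
STANDARD_GRID: np.ndarray = np.arange(300.0, 701.0)
STANDARD_GRID.setflags(write=False)

_KINDS = frozenset({"reflectance", "irradiance", "absorbance"})

# Grouping columns recognised in long-format spectral CSVs, in output order.
_LABEL_COLUMNS = ("male_id", "region", "replicate", "depth_m", "direction")


@dataclass(frozen=True)
class Spectrum:
    """A nonnegative spectral quantity sampled on a strictly increasing grid.

    Parameters
    ----------
    wavelengths
        Wavelengths in nm, strictly increasing.
    values
        Per-wavelength values, same length as ``wavelengths``, all >= 0.
    kind
        One of ``reflectance``, ``irradiance`` or ``absorbance``.
        Reflectance and absorbance are unitless; irradiance is expected in
        umol photons m^-2 s^-1 nm^-1 once inside the visual model (see
        :func:`watts_to_umol`).
    labels
        Optional provenance labels (male_id, region, replicate, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-d and equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectral values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectral values must be nonnegative")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind or self.kind, dict(self.labels))

    def on_standard_grid(self) -> bool:
        return self.wavelengths.shape == STANDARD_GRID.shape and np.array_equal(
            self.wavelengths, STANDARD_GRID
        )


@dataclass(frozen=True)
class IrradianceField:
    """Downwelling/sidewelling irradiance spectra along a depth gradient.

    ``entries`` maps depth (m) to a ``{"down": Spectrum, "side": Spectrum}``
    pair; ``surface`` is the just-below-surface downwelling scan used for
    optional normalization. All spectra share one grid.
    """

    entries: dict
    surface: Spectrum

    def __post_init__(self) -> None:
        depths = sorted(self.entries)
        if not depths:
            raise ValueError("irradiance field has no depth entries")
        if any(d < 0 for d in depths):
            raise ValueError("depths must be >= 0")
        grid = self.surface.wavelengths
        for d in depths:
            for direction in ("down", "side"):
                spec = self.entries[d][direction]
                if not np.array_equal(spec.wavelengths, grid):
                    raise ValueError(f"grid mismatch at depth {d} ({direction})")

    @property
    def depths(self) -> np.ndarray:
        return np.array(sorted(self.entries))

    def nearest_depth(self, depth: float) -> float:
        """Measured depth closest to ``depth`` (ties -> shallower)."""
        depths = self.depths
        if depth < depths[0] - 1e-9 or depth > depths[-1] + 1e-9:
            raise ValueError(
                f"depth {depth} m outside measured span "
                f"[{depths[0]}, {depths[-1]}] m"
            )
        return float(depths[np.argmin(np.abs(depths - depth))])

    def at(self, depth: float, direction: str) -> Spectrum:
        """Irradiance at the nearest measured depth."""
        return self.entries[self.nearest_depth(depth)][direction]


def read_spectra(path: str | Path, kind: str) -> list[Spectrum]:
    """Read a long-format spectral CSV into one Spectrum per label group.

    The file must contain ``wavelength_nm`` and ``value`` columns; any of
    male_id/region/replicate/depth_m/direction present are used as group
    keys and stored on each spectrum's ``labels``.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty spectral file")
    for col in ("wavelength_nm", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        bad = int(np.flatnonzero(~np.isfinite(df["value"].to_numpy(dtype=float)))[0])
        raise ValueError(f"{path}: non-numeric value in row {bad}")
    labels = [c for c in _LABEL_COLUMNS if c in df.columns]
    groups = df.groupby(labels, sort=True) if labels else [((), df)]
    out: list[Spectrum] = []
    for key, sub in groups:
        if labels and not isinstance(key, tuple):
            key = (key,)
        sub = sub.sort_values("wavelength_nm")
        wl = sub["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(wl) == 0):
            raise ValueError(
                f"{path}: duplicate wavelengths in group {dict(zip(labels, key))}"
            )
        out.append(
            Spectrum(
                wl,
                sub["value"].to_numpy(dtype=float),
                kind,
                labels=dict(zip(labels, key)),
            )
        )
    return out


def write_spectra(
    spectra: Iterable[Spectrum], path: str | Path, header_comment: str | None = None
) -> None:
    """Write spectra back to the long CSV dialect ``read_spectra`` accepts."""
    rows = []
    for spec in spectra:
        base = {k: spec.labels[k] for k in _LABEL_COLUMNS if k in spec.labels}
        for wl, v in zip(spec.wavelengths, spec.values):
            rows.append({**base, "wavelength_nm": wl, "value": v})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def resample(spectrum: Spectrum, grid: np.ndarray | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (default standard grid).

    Extrapolation is refused: the target grid must lie within the source
    wavelength span.
    """
    grid = STANDARD_GRID if grid is None else np.asarray(grid, dtype=float)
    src = spectrum.wavelengths
    if grid[0] < src[0] or grid[-1] > src[-1]:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] nm extends beyond source "
            f"span [{src[0]}, {src[-1]}] nm; refusing to extrapolate"
        )
    vals = np.interp(grid, src, spectrum.values)
    return Spectrum(grid, vals, spectrum.kind, dict(spectrum.labels))


def median_replicates(replicates: Sequence[Spectrum]) -> Spectrum:
    """Per-wavelength median across replicate scans.

    An even replicate count uses the midpoint of the two central values.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for rep in replicates[1:]:
        if not np.array_equal(rep.wavelengths, first.wavelengths):
            raise ValueError("replicates on mismatched wavelength grids")
        if rep.kind != first.kind:
            raise ValueError("replicates of mixed kinds")
    stacked = np.stack([r.values for r in replicates])
    labels = {k: v for k, v in first.labels.items() if k != "replicate"}
    return Spectrum(first.wavelengths, np.median(stacked, axis=0), first.kind, labels)


def normalize_to_white(raw: Spectrum, white: Spectrum) -> Spectrum:
    """Divide a raw scan by the matching white-standard scan -> reflectance.

    Corrects for lamp drift between fish; the white standard must be
    strictly positive everywhere.
    """
    if not np.array_equal(raw.wavelengths, white.wavelengths):
        raise ValueError("raw and white scans on mismatched grids")
    if np.any(white.values <= 0):
        raise ValueError("white standard contains nonpositive values")
    return Spectrum(
        raw.wavelengths, raw.values / white.values, "reflectance", dict(raw.labels)
    )


def normalize_irradiance(depth_spec: Spectrum, surface_spec: Spectrum) -> Spectrum:
    """Depth/surface irradiance ratio (the 'normalized irradiance' variant)."""
    if not np.array_equal(depth_spec.wavelengths, surface_spec.wavelengths):
        raise ValueError("depth and surface spectra on mismatched grids")
    if np.any(surface_spec.values <= 0):
        raise ValueError("surface irradiance contains nonpositive values")
    return Spectrum(
        depth_spec.wavelengths,
        depth_spec.values / surface_spec.values,
        "irradiance",
        dict(depth_spec.labels),
    )


def watts_to_umol(irradiance_w: Spectrum) -> Spectrum:
    """Convert spectral irradiance from W m^-2 nm^-1 to umol photons m^-2 s^-1 nm^-1.

    Physical conversion: a photon at wavelength lambda carries h*c/lambda
    joules, so photon flux = power * lambda / (h*c*N_A) mol, times 1e6 for
    micromol. Stands in for an instrument-specific calibration lamp.
    """
    if irradiance_w.kind != "irradiance":
        raise ValueError(f"expected irradiance, got {irradiance_w.kind}")
    lam_m = irradiance_w.wavelengths * 1e-9
    umol = irradiance_w.values * lam_m / (planck * speed_of_light * Avogadro) * 1e6
    return Spectrum(irradiance_w.wavelengths, umol, "irradiance", dict(irradiance_w.labels))


def read_irradiance_field(
    path: str | Path,
    *,
    convert_watts: bool = True,
    normalized: bool = False,
) -> IrradianceField:
    """Assemble an IrradianceField from a long irradiance CSV.

    Expects columns depth_m, direction {down, side}, replicate,
    wavelength_nm, value, plus direction ``surface`` rows. Medians the
    replicates at each (depth, direction), resamples to the standard grid,
    and optionally converts W -> umol and normalizes by the surface scan.
    """
    spectra = read_spectra(path, "irradiance")
    by_key: dict[tuple, list[Spectrum]] = {}
    for spec in spectra:
        key = (spec.labels.get("depth_m"), spec.labels.get("direction"))
        by_key.setdefault(key, []).append(spec)

    def collapse(key: tuple) -> Spectrum:
        med = median_replicates(by_key[key])
        med = resample(med)
        return watts_to_umol(med) if convert_watts else med

    surface_keys = [k for k in by_key if k[1] == "surface"]
    if not surface_keys:
        raise ValueError(f"{path}: no surface irradiance rows")
    surface = collapse(surface_keys[0])

    entries: dict[float, dict[str, Spectrum]] = {}
    for depth, direction in by_key:
        if direction == "surface":
            continue
        spec = collapse((depth, direction))
        if normalized:
            spec = normalize_irradiance(spec, surface)
        entries.setdefault(float(depth), {})[direction] = spec
    for depth, pair in entries.items():
        if set(pair) != {"down", "side"}:
            raise ValueError(f"{path}: depth {depth} missing a direction")
    return IrradianceField(entries, surface)
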