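"""Synthetic study generator emulating the 16-male nesting field design.

Emulated design: nesting males with recorded nest depths (0-2.5 m), two
measured body regions (preoperculum, abdomen) with three reflectance
replicates each and a white-standard scan per male, raw expression of the
four cone opsins, and a downwelling/sidewelling irradiance gradient
measured at 50-cm depth intervals with three replicates.

Statistical structure is planted on latent standard-normal scales:

* nest depth -> male redness with standardized effect ``beta_depth_color``
* nest depth -> LWS expression (additive-log-ratio coordinate) with
  standardized effect ``beta_depth_opsin``
* redness <-> LWS coordinate with latent correlation ``rho_color_lws``

Opsin compositions are logistic-normal (correlations planted on ALR
coordinates and back-transformed, keeping profiles on the simplex).
Optics follow Beer-Lambert attenuation with a piecewise-linear diffuse
attenuation coefficient K(lambda), minimal near 500 nm and rising toward
700 nm as in typical stained lake water. Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .records import MaleRecord
from .spectra_io import (
    STANDARD_GRID,
    IrradianceField,
    Spectrum,
    median_replicates,
)

__all__ = [
    "REGIONS",
    "SimConfig",
    "SyntheticStudy",
    "attenuation_coefficient",
    "surface_irradiance_watts",
    "simulate_irradiance",
    "simulate_irradiance_table",
    "simulate_reflectance",
    "simulate_males",
    "write_study",
]

REGIONS = ("preoperculum", "abdomen")

# substream ids appended to the user seed
_STREAM_IRRADIANCE = 1
_STREAM_MALES = 2
_STREAM_REFLECTANCE = 3
_STREAM_LAMP = 4

# region-specific reflectance shape: (baseline, UV-hump amplitude, red amplitude)
_REGION_SHAPE = {"preoperculum": (0.12, 0.05, 0.50), "abdomen": (0.10, 0.08, 0.55)}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_males: int = 16
    depth_range: tuple = (0.0, 2.5)
    depth_grid_step: float = 0.5
    n_replicates: int = 3
    redness_range: tuple = (0.05, 0.95)
    rho_color_lws: float = 0.8
    beta_depth_opsin: float = 0.42
    beta_depth_color: float = 0.10
    noise_sd_reflectance: float = 0.02
    lamp_drift_sd: float = 0.01
    irradiance_noise_sd: float = 0.03
    sidewelling_fraction: float = 0.2
    #: piecewise-linear K(lambda) knots (nm, 1/m)
    attenuation_knots: tuple = ((300.0, 1.5), (500.0, 0.35), (700.0, 2.6))
    #: ALR means (log ratio to SWS1) for SWS2, RH2, LWS: a profile of
    #: roughly (0.12, 0.25, 0.38, 0.25)
    alr_means: tuple = (0.73, 1.15, 0.73)
    alr_sigma_other: float = 0.15
    alr_sigma_lws: float = 0.45
    total_expression_log_mean: float = 6.9
    total_expression_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 2:
            raise ValueError("n_males must be >= 2")
        if abs(self.rho_color_lws) > 1:
            raise ValueError("|rho_color_lws| must be <= 1")
        for name in ("noise_sd_reflectance", "lamp_drift_sd", "irradiance_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.depth_range
        if lo < 0 or hi <= lo:
            raise ValueError("depth_range must satisfy 0 <= lo < hi")
        if self.depth_grid_step <= 0:
            raise ValueError("depth_grid_step must be positive")
        if any(k < 0 for _, k in self.attenuation_knots):
            raise ValueError("attenuation K(lambda) must be >= 0")

    @property
    def depth_grid(self) -> np.ndarray:
        lo, hi = self.depth_range
        return np.arange(lo, hi + 1e-9, self.depth_grid_step)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticStudy:
    """A complete simulated study plus the generating truth."""

    males: list
    irradiance_field: IrradianceField
    truth: dict
    config: SimConfig = field(repr=False, default=None)


def attenuation_coefficient(config: SimConfig, grid: np.ndarray | None = None) -> np.ndarray:
    """Diffuse attenuation K(lambda) in 1/m on the wavelength grid."""
    grid = STANDARD_GRID if grid is None else grid
    knots = np.array(config.attenuation_knots)
    return np.interp(grid, knots[:, 0], knots[:, 1])


def surface_irradiance_watts(grid: np.ndarray | None = None) -> Spectrum:
    """Smooth daylight-like surface downwelling irradiance, W m^-2 nm^-1."""
    grid = STANDARD_GRID if grid is None else grid
    vals = 1.2 * np.exp(-(((grid - 560.0) / 200.0) ** 2)) + 0.15
    return Spectrum(grid, vals, "irradiance")


def _downwelling_watts(config: SimConfig, depth: float) -> np.ndarray:
    if depth < 0:
        raise ValueError("negative depth")
    surface = surface_irradiance_watts().values
    return surface * np.exp(-attenuation_coefficient(config) * depth)


def simulate_irradiance_table(config: SimConfig) -> pd.DataFrame:
    """Long-format replicate irradiance table (W m^-2 nm^-1), as measured.

    Downwelling follows Beer-Lambert decay of the surface spectrum;
    sidewelling is a fixed fraction of downwelling with an independent
    multiplicative noise draw; three replicates per depth plus surface
    reference scans.
    """
    rng = config.rng(_STREAM_IRRADIANCE)
    grid = STANDARD_GRID
    rows = []

    def emit(depth_m: float, direction: str, replicate: int, values: np.ndarray) -> None:
        rows.append(
            pd.DataFrame(
                {
                    "depth_m": depth_m,
                    "direction": direction,
                    "replicate": replicate,
                    "wavelength_nm": grid,
                    "value": values,
                }
            )
        )

    surface = surface_irradiance_watts().values
    for rep in range(1, config.n_replicates + 1):
        noise = np.exp(config.irradiance_noise_sd * rng.standard_normal(grid.size))
        emit(0.0, "surface", rep, surface * noise)
    for depth in config.depth_grid:
        down_clean = _downwelling_watts(config, depth)
        for rep in range(1, config.n_replicates + 1):
            noise = np.exp(config.irradiance_noise_sd * rng.standard_normal(grid.size))
            emit(depth, "down", rep, down_clean * noise)
            noise = np.exp(config.irradiance_noise_sd * rng.standard_normal(grid.size))
            emit(depth, "side", rep, config.sidewelling_fraction * down_clean * noise)
    return pd.concat(rows, ignore_index=True)


def simulate_irradiance(config: SimConfig) -> IrradianceField:
    """Replicate-collapsed irradiance field (median of replicates), W units."""
    table = simulate_irradiance_table(config)
    entries: dict[float, dict[str, Spectrum]] = {}
    surface = None
    for (depth, direction), sub in table.groupby(["depth_m", "direction"]):
        reps = [
            Spectrum(
                g["wavelength_nm"].to_numpy(),
                g["value"].to_numpy(),
                "irradiance",
            )
            for _, g in sub.groupby("replicate")
        ]
        med = median_replicates(reps)
        if direction == "surface":
            surface = med
        else:
            entries.setdefault(float(depth), {})[direction] = med
    return IrradianceField(entries, surface)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_reflectance(redness: float, region: str, config: SimConfig) -> Spectrum:
    """Noise-free male reflectance for a body region at a given redness.

    A region-specific baseline plus a UV hump (Gaussian at 370 nm) and a
    carotenoid-like long-pass step (logistic, inflection 550 nm) whose
    amplitude scales with ``redness``; the orange-red band proportion is
    strictly increasing in redness.
    """
    if not 0.0 <= redness <= 1.0:
        raise ValueError("redness must lie in [0, 1]")
    if region not in _REGION_SHAPE:
        raise ValueError(f"unknown region {region!r}")
    base, uv_amp, red_amp = _REGION_SHAPE[region]
    lam = STANDARD_GRID
    vals = (
        base
        + uv_amp * np.exp(-(((lam - 370.0) / 25.0) ** 2))
        + red_amp * redness * _logistic((lam - 550.0) / 30.0)
    )
    return Spectrum(lam, vals, "reflectance", {"region": region})


def _plant_latents(config: SimConfig, rng: np.random.Generator, n: int):
    """Latent (depth_z, redness_z, lws_z) with the planted correlation structure."""
    bdc = config.beta_depth_color
    bdo = config.beta_depth_opsin
    rho = config.rho_color_lws
    if abs(bdc) >= 1 or abs(bdo) >= 1:
        raise ValueError("planted depth effects must have |beta| < 1")
    gamma_denom = np.sqrt(1 - bdc**2)
    gamma = (rho - bdc * bdo) / gamma_denom
    resid = 1 - bdo**2 - gamma**2
    if resid < -1e-12:
        raise ValueError(
            "requested correlation structure is not positive semi-definite: "
            f"rho_color_lws={rho}, beta_depth_color={bdc}, beta_depth_opsin={bdo}"
        )
    delta = np.sqrt(max(resid, 0.0))
    lo, hi = config.depth_range
    depths = rng.uniform(lo, hi, n)
    # standardize against the uniform population moments so betas are exact
    d_z = (depths - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))
    eps_r = rng.standard_normal(n)
    eps_l = rng.standard_normal(n)
    r_z = bdc * d_z + gamma_denom * eps_r
    l_z = bdo * d_z + gamma * eps_r + delta * eps_l
    return depths, d_z, r_z, l_z


def simulate_males(config: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study: males, spectra, irradiance, truth."""
    rng = config.rng(_STREAM_MALES)
    refl_rng = config.rng(_STREAM_REFLECTANCE)
    n = config.n_males
    depths, d_z, r_z, l_z = _plant_latents(config, rng, n)

    lo_r, hi_r = config.redness_range
    redness = lo_r + (hi_r - lo_r) * ndtr(r_z)

    mu_s2, mu_rh2, mu_lws = config.alr_means
    alr = np.column_stack(
        [
            mu_s2 + config.alr_sigma_other * rng.standard_normal(n),
            mu_rh2 + config.alr_sigma_other * rng.standard_normal(n),
            mu_lws + config.alr_sigma_lws * l_z,
        ]
    )
    logits = np.column_stack([np.zeros(n), alr])
    expo = np.exp(logits - logits.max(axis=1, keepdims=True))
    eta = expo / expo.sum(axis=1, keepdims=True)  # (n, 4): sws1, sws2, rh2, lws

    totals = np.exp(
        config.total_expression_log_mean
        + config.total_expression_log_sd * rng.standard_normal(n)
    )
    raw_expression = eta * totals[:, None]

    males = []
    for i in range(n):
        record = MaleRecord(male_id=f"M{i + 1:02d}", depth_m=float(depths[i]),
                            raw_expression=raw_expression[i])
        for region in REGIONS:
            clean = simulate_reflectance(float(redness[i]), region, config)
            reps = []
            for rep in range(1, config.n_replicates + 1):
                noise = np.exp(
                    config.noise_sd_reflectance
                    * refl_rng.standard_normal(STANDARD_GRID.size)
                )
                noisy = Spectrum(
                    STANDARD_GRID,
                    clean.values * noise,
                    "reflectance",
                    {"region": region, "replicate": rep},
                )
                reps.append(noisy)
            record.reflectance_replicates[region] = reps
            record.reflectance[region] = median_replicates(reps)
        males.append(record)

    realized = np.corrcoef(r_z, l_z)[0, 1] if n > 2 else np.nan
    truth = {
        "redness": redness.tolist(),
        "depth_m": depths.tolist(),
        "latent_redness": r_z.tolist(),
        "latent_lws": l_z.tolist(),
        "latent_depth": d_z.tolist(),
        "eta": eta.tolist(),
        "realized_latent_corr_color_lws": float(realized),
        "rho_color_lws": config.rho_color_lws,
        "beta_depth_opsin": config.beta_depth_opsin,
        "beta_depth_color": config.beta_depth_color,
        "seed": config.seed,
    }
    return SyntheticStudy(males, simulate_irradiance(config), truth, config)


def _lamp_spectrum() -> np.ndarray:
    """Xenon-lamp-like raw-count spectrum used for white-standard scans."""
    lam = STANDARD_GRID
    return 380.0 * np.exp(-(((lam - 450.0) / 180.0) ** 2)) + 40.0


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write the study as the CSV tables the pipeline reads.

    spectra.csv holds raw (lamp-modulated) counts; white.csv the matching
    per-male white-standard scans, so reflectance must be recovered by
    white-normalization. irradiance.csv is in W m^-2 nm^-1 and must be
    converted to photon units downstream. Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = study.config
    lamp_rng = config.rng(_STREAM_LAMP)
    lamp0 = _lamp_spectrum()

    spec_rows, white_rows = [], []
    for male in study.males:
        lamp = lamp0 * np.exp(config.lamp_drift_sd * lamp_rng.standard_normal())
        white_rows.append(
            pd.DataFrame(
                {
                    "male_id": male.male_id,
                    "wavelength_nm": STANDARD_GRID,
                    "value": lamp,
                }
            )
        )
        for region in REGIONS:
            for rep, spec in enumerate(male.reflectance_replicates[region], start=1):
                spec_rows.append(
                    pd.DataFrame(
                        {
                            "male_id": male.male_id,
                            "region": region,
                            "replicate": rep,
                            "wavelength_nm": STANDARD_GRID,
                            "value": spec.values * lamp,
                        }
                    )
                )

    paths = {
        "spectra": outdir / "spectra.csv",
        "white": outdir / "white.csv",
        "irradiance": outdir / "irradiance.csv",
        "males": outdir / "males.csv",
        "truth": outdir / "truth.json",
    }
    pd.concat(spec_rows, ignore_index=True).to_csv(
        paths["spectra"], index=False, lineterminator="\n"
    )
    pd.concat(white_rows, ignore_index=True).to_csv(
        paths["white"], index=False, lineterminator="\n"
    )
    simulate_irradiance_table(config).to_csv(
        paths["irradiance"], index=False, lineterminator="\n"
    )
    males_df = pd.DataFrame(
        {
            "male_id": [m.male_id for m in study.males],
            "depth_m": [m.depth_m for m in study.males],
            "sws1": [m.raw_expression[0] for m in study.males],
            "sws2": [m.raw_expression[1] for m in study.males],
            "rh2": [m.raw_expression[2] for m in study.males],
            "lws": [m.raw_expression[3] for m in study.males],
        }
    )
    males_df.to_csv(paths["males"], index=False, lineterminator="\n")
    with open(paths["truth"], "w") as fh:
        json.dump({"config": asdict(study.config), "truth": study.truth}, fh, indent=1)
    return paths
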