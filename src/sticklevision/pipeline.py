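"""End-to-end orchestration: spectra -> proportions -> visual model ->
transplant null -> signal-sensory statistics.

Every stage is a pure function of the input tables, the configuration and
the single integer seed; outputs are CSV files with a provenance comment
header plus a human-readable summary.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color_metrics import BANDS, OPSINS, band_proportions
from .records import MaleRecord
from .spectra_io import (
    IrradianceField,
    median_replicates,
    normalize_to_white,
    read_irradiance_field,
    read_spectra,
    resample,
)
from .stats import cca, fit_path_model, fit_regression, wilks_sequential_test
from .synthetic_data import REGIONS
from .transplant_null import deviation_test, transplant_grid
from .visual_model import (
    VisualSystem,
    orange_red_sensitivity,
    retina_weighted_absorbance,
)

__all__ = ["PipelineConfig", "load_study_tables", "run_full_study"]

_ORANGE_RED_COL = list(BANDS).index("p_orange_red")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for a full study run."""

    in_dir: str
    out_dir: str
    lws_variant: str = "median"
    weber_fraction: float = 0.05
    n_perm: int = 999
    seed: int = 0
    region: str = "both"
    normalized_irradiance: bool = False
    include_beta_band: bool = True
    chromophore: str = "A1"
    include_self_pairings: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def regions(self) -> tuple:
        return REGIONS if self.region == "both" else (self.region,)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return (
        f"sticklevision {__version__} seed={config.seed} "
        f"config={config.config_hash()}"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(config)}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")


def load_study_tables(config: PipelineConfig) -> tuple[list, IrradianceField]:
    """Read and preprocess the four input tables into study records.

    Raw spectral counts are white-normalized per male (lamp-drift
    correction), resampled to the standard grid and replicate-collapsed by
    the per-wavelength median; irradiance replicates are medianed and
    converted from W to photon units.
    """
    in_dir = Path(config.in_dir)
    for name in ("spectra.csv", "white.csv", "irradiance.csv", "males.csv"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(
                f"spectra_io: required input {name} missing from {in_dir}"
            )
    whites = {
        s.labels["male_id"]: s for s in read_spectra(in_dir / "white.csv", "irradiance")
    }
    raw = read_spectra(in_dir / "spectra.csv", "irradiance")
    males_df = pd.read_csv(in_dir / "males.csv", comment="#")

    records: dict[str, MaleRecord] = {}
    for _, row in males_df.iterrows():
        records[row["male_id"]] = MaleRecord(
            male_id=row["male_id"],
            depth_m=float(row["depth_m"]),
            raw_expression=[row[g] for g in OPSINS],
        )

    by_group: dict[tuple, list] = {}
    for spec in raw:
        key = (spec.labels["male_id"], spec.labels["region"])
        by_group.setdefault(key, []).append(spec)
    for (male_id, region), reps in by_group.items():
        normalized = [
            resample(normalize_to_white(r, whites[male_id])) for r in reps
        ]
        record = records[male_id]
        record.reflectance_replicates[region] = normalized
        record.reflectance[region] = median_replicates(normalized)

    field = read_irradiance_field(
        in_dir / "irradiance.csv", normalized=config.normalized_irradiance
    )
    males = [records[m] for m in males_df["male_id"]]
    return males, field


def run_full_study(config: PipelineConfig) -> dict:
    """Run every stage and write the full report bundle to ``out_dir``.

    Returns a nested dict with the per-region CCA/Wilks results, the
    orange-red sensitivity regression, transplant t tests and path fits.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        males, irr_field = load_study_tables(config)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage spectra_io failed: {exc}") from exc

    base_vs = VisualSystem(
        eta=males[0].opsin,
        omega=config.weber_fraction,
        lws_variant=config.lws_variant,
        chromophore=config.chromophore,
        include_beta_band=config.include_beta_band,
    )

    # --- color metrics -------------------------------------------------
    color_rows = []
    color_mats: dict[str, np.ndarray] = {}
    for region in config.regions():
        props = [band_proportions(m.reflectance[region]) for m in males]
        color_mats[region] = np.stack([p.as_array() for p in props])
        for m, p in zip(males, props):
            color_rows.append(
                {"male_id": m.male_id, "region": region, **dict(zip(BANDS, p.as_array()))}
            )
    _write_csv(pd.DataFrame(color_rows), out / "color_proportions.csv", config)

    opsin_mat = np.stack([m.opsin.as_array() for m in males])
    _write_csv(
        pd.DataFrame(
            {
                "male_id": [m.male_id for m in males],
                **{f"eta_{g}": opsin_mat[:, i] for i, g in enumerate(OPSINS)},
            }
        ),
        out / "opsin_proportions.csv",
        config,
    )

    # --- visual sensitivity + regression -------------------------------
    sens = np.array(
        [
            orange_red_sensitivity(retina_weighted_absorbance(m.opsin, base_vs))
            for m in males
        ]
    )
    report: dict = {"regions": {}, "seed": config.seed}
    reg_rows = []
    for region in config.regions():
        fit = fit_regression(sens, color_mats[region][:, _ORANGE_RED_COL])
        report["regions"].setdefault(region, {})["orange_red_regression"] = fit
        reg_rows.append(
            {
                "region": region,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    _write_csv(pd.DataFrame(reg_rows), out / "orange_red_regression.csv", config)

    # --- transplant null ------------------------------------------------
    transplant_rows, test_rows = [], []
    for region in config.regions():
        grid = transplant_grid(males, irr_field, base_vs, region)
        result = deviation_test(males, grid, config.include_self_pairings)
        report["regions"][region]["transplant"] = result
        idx = np.arange(len(males))
        for i in idx:
            transplant_rows.append(
                {
                    "region": region,
                    "male_id": males[i].male_id,
                    "depth_m": males[i].depth_m,
                    "delta_s_empirical": result.empirical[i],
                    "delta_s_null": result.null_mean[i],
                    "deviation": result.deviation[i],
                }
            )
        test_rows.append(
            {
                "region": region,
                "mean_deviation": float(result.deviation.mean()),
                "t": result.test.t,
                "df": result.test.df,
                "p": result.test.p,
            }
        )
    _write_csv(pd.DataFrame(transplant_rows), out / "transplant.csv", config)
    _write_csv(pd.DataFrame(test_rows), out / "transplant_test.csv", config)

    # --- CCA + Wilks + path model ---------------------------------------
    cca_rows, loading_rows, path_rows = [], [], []
    depths = np.array([m.depth_m for m in males])
    rng = np.random.default_rng([config.seed, 101])
    for region in config.regions():
        X = color_mats[region]
        Y = opsin_mat
        res = cca(X, Y, orient_x_column=_ORANGE_RED_COL)
        lam, pvals = wilks_sequential_test(X, Y, n_perm=config.n_perm, seed=rng)
        report["regions"][region]["cca"] = res
        report["regions"][region]["wilks_p"] = pvals
        for a in range(res.k):
            cca_rows.append(
                {
                    "region": region,
                    "axis": a + 1,
                    "r": res.correlations[a],
                    "r_squared": res.correlations[a] ** 2,
                    "wilks_lambda": lam[a],
                    "p": pvals[a],
                }
            )
        for names, mat, side in ((BANDS, res.x_loadings, "color"), (OPSINS, res.y_loadings, "opsin")):
            for vi, vname in enumerate(names):
                for a in range(res.k):
                    loading_rows.append(
                        {
                            "region": region,
                            "matrix": side,
                            "variable": vname if side == "color" else f"eta_{vname}",
                            "axis": a + 1,
                            "loading": mat[vi, a],
                        }
                    )
        path = fit_path_model(depths, res.y_scores[:, 0], res.x_scores[:, 0])
        report["regions"][region]["path"] = path
        for edge, est in path.edges.items():
            path_rows.append(
                {
                    "region": region,
                    "edge": edge,
                    "estimate": est.estimate,
                    "se": est.se,
                    "z": est.z,
                    "p": est.p,
                }
            )
    _write_csv(pd.DataFrame(cca_rows), out / "cca_result.csv", config)
    _write_csv(pd.DataFrame(loading_rows), out / "loadings.csv", config)
    _write_csv(pd.DataFrame(path_rows), out / "path_fit.csv", config)

    _write_summary(out / "summary.txt", config, report)
    return report


def _write_summary(path: Path, config: PipelineConfig, report: dict) -> None:
    lines = [f"# {_provenance(config)}", ""]
    for region, res in report["regions"].items():
        lines.append(f"== {region} ==")
        ccares = res["cca"]
        p1 = res["wilks_p"][0]
        lines.append(
            f"CCA axis 1: r^2 = {ccares.correlations[0] ** 2:.3f}, "
            f"permutation p = {p1:.4g} ({config.n_perm} permutations)"
        )
        reg = res["orange_red_regression"]
        lines.append(
            f"orange-red sensitivity vs color: r^2 = {reg.r_squared:.3f}, "
            f"p = {reg.p_value:.4g}"
        )
        tr = res["transplant"].test
        lines.append(
            f"transplant null: t({tr.df}) = {tr.t:.3f}, p = {tr.p:.3f}, "
            f"mean deviation = {tr.mean:.4g}"
        )
        lines.append("path model (standardized):")
        for edge, est in res["path"].edges.items():
            lines.append(
                f"  {edge:>15}: {est.estimate: .3f} (SE {est.se:.3f}, "
                f"z {est.z:.3f}, p {est.p:.3f})"
            )
        lines.append("")
    path.write_text("\n".join(lines))
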