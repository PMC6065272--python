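"""In-silico transplant experiment: a permutation null for microhabitat tuning.

Color patches and opsin profiles are permuted exhaustively across males
and chromatic contrast evaluated for every (color donor, opsin donor)
pairing at every male's nest depth — n^3 evaluations. The mean over all
n^2 pairings at a depth is the null expectation for contrast there; each
male's observed configuration is the grid diagonal. A one-sample t test
of the per-male deviations (empirical - null) asks whether residents are
more (or less) conspicuous than random transplants, i.e. whether color,
opsins and optical microhabitat are nonrandomly matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import MaleRecord
from .spectra_io import STANDARD_GRID, IrradianceField
from .stats import OneSampleT, one_sample_t
from .visual_model import VisualSystem, delta_S, receptor_contrast

__all__ = ["TransplantGrid", "TransplantResult", "transplant_grid", "null_expectation", "deviation_test"]


@dataclass(frozen=True)
class TransplantGrid:
    """delta_S[i, j, k]: color of male i, opsins (viewer) of male j, depth of male k."""

    delta_s: np.ndarray
    male_ids: tuple
    depths: np.ndarray  # nest depth of male k (grid axis 2)
    region: str

    @property
    def n(self) -> int:
        return self.delta_s.shape[0]


@dataclass(frozen=True)
class TransplantResult:
    """Per-male deviations from the transplant null and the study-level t test."""

    male_ids: tuple
    empirical: np.ndarray
    null_mean: np.ndarray
    deviation: np.ndarray
    test: OneSampleT
    region: str


def transplant_grid(
    males: Sequence[MaleRecord],
    field: IrradianceField,
    vs: VisualSystem,
    region: str,
) -> TransplantGrid:
    """Exhaustive n x n x n contrast table over (color, opsin, depth) donors.

    Receptor contrasts depend only on (color donor, depth), and channel
    noise only on the opsin donor, so the n^3 table is assembled from an
    n x n contrast sheet and n noise vectors; every cell equals a direct
    one-at-a-time RNL evaluation.
    """
    n = len(males)
    if n < 1:
        raise ValueError("need at least one male")
    templates = vs.template_matrix()  # (4, W)
    wl = STANDARD_GRID
    refl = np.stack([m.reflectance[region].values for m in males])  # (n, W)
    depths = np.array([m.depth_m for m in males])

    # one optics evaluation per unique measured depth
    near = np.array([field.nearest_depth(d) for d in depths])
    uniq, inv = np.unique(near, return_inverse=True)
    df_ud = np.empty((len(uniq), n, 4))  # (unique depth, color donor, cone)
    for u, d in enumerate(uniq):
        down = field.entries[d]["down"].values
        side = field.entries[d]["side"].values
        # Q_target (n, 4); background catch = adapting catch, so q_bg = 1
        q_t = np.trapezoid(refl[:, None, :] * templates[None, :, :] * down, wl, axis=2)
        adapt = np.trapezoid(templates * side, wl, axis=1)  # (4,)
        if np.any(q_t <= 0) or np.any(adapt <= 0):
            raise ValueError(f"zero quantum catch at depth {d} m")
        df_ud[u] = receptor_contrast(q_t / adapt, np.ones(4))

    etas = np.stack([m.opsin.as_array() for m in males])  # (n, 4)
    if np.any(etas <= 0):
        raise ValueError(
            "transplant grid requires positive density in all four cone classes"
        )
    e = vs.omega / np.sqrt(etas)  # (n, 4)

    ds = np.empty((n, n, n))
    for j in range(n):
        ds[:, j, :] = _delta_s_sheet(df_ud, e[j])[:, inv]
    return TransplantGrid(ds, tuple(m.male_id for m in males), depths, region)


def _delta_s_sheet(df_ud: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Tetrachromatic delta_S for contrast array (n_depth, n_color, 4) and one noise vector."""
    f = df_ud
    e1, e2, e3, e4 = e
    num = (
        (e1 * e2) ** 2 * (f[..., 3] - f[..., 2]) ** 2
        + (e1 * e3) ** 2 * (f[..., 3] - f[..., 1]) ** 2
        + (e1 * e4) ** 2 * (f[..., 2] - f[..., 1]) ** 2
        + (e2 * e3) ** 2 * (f[..., 3] - f[..., 0]) ** 2
        + (e2 * e4) ** 2 * (f[..., 2] - f[..., 0]) ** 2
        + (e3 * e4) ** 2 * (f[..., 1] - f[..., 0]) ** 2
    )
    den = (
        (e1 * e2 * e3) ** 2
        + (e1 * e2 * e4) ** 2
        + (e1 * e3 * e4) ** 2
        + (e2 * e3 * e4) ** 2
    )
    # (n_depth, n_color) -> transpose to (n_color, n_depth)
    return np.sqrt(num / den).T


def null_expectation(
    grid: TransplantGrid, depth: float, include_self: bool = True
) -> float:
    """Mean contrast over all n^2 (color, opsin) pairings at a nest depth."""
    matches = np.flatnonzero(np.isclose(grid.depths, depth))
    if matches.size == 0:
        raise ValueError(f"depth {depth} m not indexed in the transplant grid")
    sheet = grid.delta_s[:, :, matches[0]]
    if include_self:
        return float(sheet.mean())
    mask = ~np.eye(grid.n, dtype=bool)
    return float(sheet[mask].mean())


def deviation_test(
    males: Sequence[MaleRecord], grid: TransplantGrid, include_self: bool = True
) -> TransplantResult:
    """Per-male deviation from the null and its two-sided one-sample t test.

    empirical_i is grid cell (i, i, i) — the male's own color and opsins
    at his own depth; null_i averages the full pairing sheet at his depth.
    Zero deviation variance (e.g. identical males) yields a flagged
    degenerate test rather than a silent NaN.
    """
    n = len(males)
    if n < 2:
        raise ValueError("deviation test needs at least two males")
    idx = np.arange(n)
    empirical = grid.delta_s[idx, idx, idx]
    null_mean = np.array(
        [null_expectation(grid, grid.depths[k], include_self) for k in idx]
    )
    deviation = empirical - null_mean
    test = one_sample_t(deviation, 0.0)
    return TransplantResult(grid.male_ids, empirical, null_mean, deviation, test, grid.region)
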