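"""Per-male study records shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color_metrics import relative_expression
from .spectra_io import Spectrum

__all__ = ["MaleRecord"]


@dataclass
class MaleRecord:
    """One nesting male: nest depth, regional reflectance, opsin expression.

    ``reflectance`` maps body region (preoperculum, abdomen) to the
    replicate-collapsed reflectance spectrum on the standard grid;
    ``raw_expression`` holds the four raw opsin quantities (sws1, sws2,
    rh2, lws), and ``opsin`` their compositional profile.
    """

    male_id: str
    depth_m: float
    reflectance: dict[str, Spectrum] = field(default_factory=dict)
    raw_expression: np.ndarray | None = None
    reflectance_replicates: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError(f"male {self.male_id}: negative nest depth")
        if self.raw_expression is not None:
            self.raw_expression = np.asarray(self.raw_expression, dtype=float)

    @property
    def opsin(self) -> OpsinProfile:
        if self.raw_expression is None:
            raise ValueError(f"male {self.male_id} has no expression data")
        return relative_expression(self.raw_expression)
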