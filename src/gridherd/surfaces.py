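"""Per-pixel density surfaces for one species-year."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridGeometry, valid_mask


@dataclass
class DensitySurface:
    """A head/km^2 raster for one species and year.

    ``stage`` is ``"predicted"`` (raw model output) or ``"adjusted"``
    (rescaled to district census totals). Invalid pixels carry the
    geometry's nodata sentinel.
    """

    values: np.ndarray
    geometry: GridGeometry
    species: str
    year: int
    stage: str = "predicted"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"surface shape {self.values.shape} does not match "
                f"grid {self.geometry.shape}"
            )
        if self.stage not in ("predicted", "adjusted"):
            raise ValueError("stage must be 'predicted' or 'adjusted'")

    @property
    def valid(self) -> np.ndarray:
        return valid_mask(self.values, self.geometry.nodata)
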