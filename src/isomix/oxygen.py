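"""δ18O scale conversions from bioapatite carbonate to drinking water.

Bone/enamel carbonate δ18O is measured against VPDB.  To compare it
with environmental water it is re-expressed on the VSMOW scale,
converted to the phosphate equivalent, and finally to the δ18O of
ingested water, each step an affine map with published regression
coefficients:

    δ18O_VSMOW     = 1.03092 · δ18O_VPDB + 30.92
    δ18O_phosphate = 1.0322  · δ18O_carbonate(VSMOW) − 9.6849
    δ18O_water     = 1.55    · δ18O_phosphate − 33.49

A conservative 2‰ uncertainty is attached to modelled individual water
values by default, reflecting cooking, brewing and diagenetic effects
that the regressions cannot capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Scale",
    "OxygenValue",
    "vpdb_to_vsmow",
    "carbonate_to_phosphate",
    "phosphate_to_water",
    "carbonate_vpdb_to_water",
    "water_to_carbonate_vpdb",
    "DEFAULT_WATER_SIGMA",
]

DEFAULT_WATER_SIGMA = 2.0  # ‰, for individual modelled water values

# (slope, intercept) of each step in the chain
_VPDB_TO_VSMOW = (1.03092, 30.92)
_CARB_TO_PHOS = (1.0322, -9.6849)
_PHOS_TO_WATER = (1.55, -33.49)


class Scale(str, Enum):
    CARBONATE_VPDB = "carbonate_VPDB"
    CARBONATE_VSMOW = "carbonate_VSMOW"
    PHOSPHATE_VSMOW = "phosphate_VSMOW"
    WATER_VSMOW = "water_VSMOW"


@dataclass(frozen=True)
class OxygenValue:
    value: float
    scale: Scale
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _require(x: OxygenValue, scale: Scale) -> None:
    if x.scale is not scale:
        raise ValueError(f"expected {scale.value} input, got {x.scale.value}")


def _affine(x: OxygenValue, coeff: tuple[float, float], out: Scale) -> OxygenValue:
    slope, intercept = coeff
    return OxygenValue(value=slope * x.value + intercept, scale=out, sigma=abs(slope) * x.sigma)


def vpdb_to_vsmow(x: OxygenValue) -> OxygenValue:
    """Carbonate δ18O: VPDB → VSMOW."""
    _require(x, Scale.CARBONATE_VPDB)
    return _affine(x, _VPDB_TO_VSMOW, Scale.CARBONATE_VSMOW)


def carbonate_to_phosphate(x: OxygenValue) -> OxygenValue:
    """Carbonate (VSMOW) → phosphate-equivalent δ18O (VSMOW)."""
    _require(x, Scale.CARBONATE_VSMOW)
    return _affine(x, _CARB_TO_PHOS, Scale.PHOSPHATE_VSMOW)


def phosphate_to_water(x: OxygenValue) -> OxygenValue:
    """Phosphate δ18O (VSMOW) → δ18O of ingested water (VSMOW)."""
    _require(x, Scale.PHOSPHATE_VSMOW)
    return _affine(x, _PHOS_TO_WATER, Scale.WATER_VSMOW)


def carbonate_vpdb_to_water(
    x: float | OxygenValue, sigma_out: float = DEFAULT_WATER_SIGMA
) -> OxygenValue:
    """Full chain carbonate (VPDB) → water (VSMOW), at full precision.

    ``sigma_out`` (default 2.0‰) replaces propagated measurement
    uncertainty as the modelled water uncertainty; round to one decimal
    place only when reporting.
    """
    if not isinstance(x, OxygenValue):
        x = OxygenValue(float(x), Scale.CARBONATE_VPDB)
    w = phosphate_to_water(carbonate_to_phosphate(vpdb_to_vsmow(x)))
    return OxygenValue(value=w.value, scale=Scale.WATER_VSMOW, sigma=float(sigma_out))


def water_to_carbonate_vpdb(x: float | OxygenValue) -> OxygenValue:
    """Algebraic inverse of the carbonate→water chain (exact)."""
    if not isinstance(x, OxygenValue):
        x = OxygenValue(float(x), Scale.WATER_VSMOW)
    _require(x, Scale.WATER_VSMOW)
    v = x.value
    for slope, intercept in (_PHOS_TO_WATER, _CARB_TO_PHOS, _VPDB_TO_VSMOW):
        v = (v - intercept) / slope
    return OxygenValue(value=v, scale=Scale.CARBONATE_VPDB, sigma=0.0)


def convert_array(values, sigma_out: float = DEFAULT_WATER_SIGMA) -> np.ndarray:
    """Vectorised carbonate (VPDB) → water (VSMOW) for tabular pipelines."""
    v = np.asarray(values, dtype=float)
    for slope, intercept in (_VPDB_TO_VSMOW, _CARB_TO_PHOS, _PHOS_TO_WATER):
        v = slope * v + intercept
    return v
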