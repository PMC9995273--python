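"""Sensor constants: band set, solar irradiances and masking thresholds.

The nine nominal wavelengths are the MODIS/Aqua ocean-colour bands used by
the detection algorithm.  Extraterrestrial solar irradiance values ``F`` are
Thuillier-scale band irradiances in mW cm^-2 um^-1; they only matter when the
fluorescence line height is reported in physical units, and they are fully
configurable (exactness tests set F identically 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

#: Nominal band centres (nm), strictly increasing.
BAND_CENTRES: tuple[int, ...] = (443, 469, 488, 555, 645, 667, 678, 748, 869)

#: Default band solar irradiances (mW cm^-2 um^-1), Thuillier-scale.
DEFAULT_F: Mapping[int, float] = {
    443: 187.65,
    469: 205.37,
    488: 194.93,
    555: 186.20,
    645: 160.32,
    667: 152.55,
    678: 148.05,
    748: 128.00,
    869: 95.82,
}


@dataclass(frozen=True)
class SensorConstants:
    """Band centres, irradiances and the fixed masking thresholds.

    ``cloud_rrc869_threshold``: pixels with Rrc(869) at or above this are
    treated as cloud.  ``index1_threshold``: pixels whose shadow index exceeds
    this are removed as cloud shadow.  ``index2_threshold``: pixels whose
    cloud index falls below this are removed as residual cloud.
    ``min_conversion_rrc``: any of the three chromaticity-conversion bands
    below this marks the pixel invalid (residual correction failure).
    """

    band_centres: tuple[int, ...] = BAND_CENTRES
    F: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_F))
    cloud_rrc869_threshold: float = 0.027
    index1_threshold: float = 0.12
    index2_threshold: float = 0.012
    min_conversion_rrc: float = -0.005

    def __post_init__(self) -> None:
        centres = tuple(self.band_centres)
        if any(b >= a for b, a in zip(centres, centres[1:])):
            raise ValueError("band centres must be strictly increasing")
        for wl, f in self.F.items():
            if not f > 0:
                raise ValueError(f"solar irradiance F[{wl}] must be positive")
        for name in ("cloud_rrc869_threshold", "index1_threshold", "index2_threshold"):
            val = getattr(self, name)
            if not (val == val and abs(val) < float("inf")):
                raise ValueError(f"{name} must be finite")

    def with_unit_f(self) -> "SensorConstants":
        """Copy with F = 1 for every band (reflectance-space FLH)."""
        return replace(self, F={wl: 1.0 for wl in self.band_centres})


DEFAULT_CONSTANTS = SensorConstants()
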