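"""Per-pixel spectral computations: CIE chromaticity, fluorescence line
height, ERGB composites, cloud/shadow indices, quality masking, and the
scene-level bloom detector.

Channel assignment for the chromaticity conversion — deliberately and
prominently: **R = Rrc(748 nm), G = Rrc(678 nm, the fluorescence band),
B = Rrc(667 nm)**.  This inverts the intuitive red/green/blue ordering: the
fluorescence band drives the G channel so that the converted y coordinate
measures fluorescence strength.  Do not "fix" the order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .boundary import BloomBoundary, DEFAULT_BOUNDARY, boundary_y
from .constants import DEFAULT_CONSTANTS, SensorConstants
from .scene import ALL_FLAGS, BLOOM, INVALID, NO_BLOOM, BloomMask, Scene

#: CIE tristimulus conversion matrix applied to (R, G, B) = Rrc(748, 678, 667).
CIE_MATRIX = np.array(
    [
        [2.7689, 1.7517, 1.1302],  # X
        [1.0000, 4.5907, 0.0601],  # Y
        [0.0000, 0.0565, 5.5943],  # Z
    ]
)

Spectrum = Mapping[int, float]


@dataclass(frozen=True)
class ChromaticityPoint:
    x: float
    y: float
    valid: bool


def _get(spectrum: Spectrum, *wavelengths: int):
    try:
        return [spectrum[wl] for wl in wavelengths]
    except (KeyError, IndexError):
        missing = [wl for wl in wavelengths if wl not in spectrum]
        raise KeyError(f"spectrum is missing required band(s): {missing}") from None


def chromaticity_xy(r748, g678, b667):
    """Vectorised CIE (x, y) from the three conversion bands.

    Returns ``(x, y, valid)``; invalid where X+Y+Z <= 0 or any input is
    non-finite.  Equal inputs map exactly to the white point (1/3, 1/3)
    because the three matrix rows share the same row-sum (5.6508).
    """
    r748, g678, b667 = np.broadcast_arrays(
        np.asarray(r748, float), np.asarray(g678, float), np.asarray(b667, float)
    )
    rgb = np.stack([r748, g678, b667])
    X, Y, Z = np.tensordot(CIE_MATRIX, rgb, axes=1)
    total = X + Y + Z
    finite = np.isfinite(r748) & np.isfinite(g678) & np.isfinite(b667)
    valid = finite & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, X / np.where(total == 0, np.nan, total), np.nan)
        y = np.where(valid, Y / np.where(total == 0, np.nan, total), np.nan)
    return x, y, valid


def chromaticity(spectrum: Spectrum) -> ChromaticityPoint:
    """CIE chromaticity of a single spectrum (scalar convenience wrapper)."""
    b667, g678, r748 = _get(spectrum, 667, 678, 748)
    x, y, valid = chromaticity_xy(r748, g678, b667)
    if not valid:
        return ChromaticityPoint(float("nan"), float("nan"), False)
    return ChromaticityPoint(float(x), float(y), True)


def flh(spectrum: Spectrum, constants: SensorConstants = DEFAULT_CONSTANTS) -> float:
    """Fluorescence line height (mW cm^-2 um^-1).

    Height of the radiance-scaled 678 nm signal above the linear baseline
    drawn between 667 and 748 nm:
    ``FLH = Rrc678*F678 - [Rrc667*F667 + (Rrc748*F748 - Rrc667*F667)*(678-667)/(748-667)]``.
    Negative values are permitted (signal below its baseline).
    """
    r667, r678, r748 = _get(spectrum, 667, 678, 748)
    F = constants.F
    l667 = r667 * F[667]
    l678 = r678 * F[678]
    l748 = r748 * F[748]
    return float(l678 - (l667 + (l748 - l667) * (678.0 - 667.0) / (748.0 - 667.0)))


def flh_raster(scene: Scene, constants: SensorConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    F = constants.F
    l667 = scene.band(667) * F[667]
    l678 = scene.band(678) * F[678]
    l748 = scene.band(748) * F[748]
    return l678 - (l667 + (l748 - l667) * (678.0 - 667.0) / (748.0 - 667.0))


def ergb(scene: Scene, stretch_max: float = 0.08) -> np.ndarray:
    """Enhanced RGB composite from Rrc at 555 (R), 488 (G) and 443 nm (B).

    Channels are linearly stretched over [0, stretch_max] and clipped to
    [0, 1] — a monotone stretch, for visualisation and fixture labelling
    only.  Returns an (ny, nx, 3) float array.
    """
    chans = [scene.band(555), scene.band(488), scene.band(443)]
    return np.stack([np.clip(c / stretch_max, 0.0, 1.0) for c in chans], axis=-1)


def cloud_shadow_indices(spectrum: Spectrum) -> tuple[float, float]:
    """Cloud-shadow (index1) and cloud (index2) spectral-shape indices.

    Band values are normalized by a reference band so each index depends only
    on spectral shape: index1 uses nRrc = Rrc/Rrc488, index2 uses
    Rrc/Rrc469.  index1 = nRrc488 - nRrc443 - (nRrc555 - nRrc443)*0.5;
    index2 = nRrc555 - nRrc469 - (nRrc645 - nRrc469)*0.5.  A zero reference
    band leaves the index undefined (nan).
    """
    r443, r469, r488, r555, r645 = _get(spectrum, 443, 469, 488, 555, 645)
    i1, i2 = _indices_arrays(*(np.asarray(v, float) for v in (r443, r469, r488, r555, r645)))
    return float(i1), float(i2)


def _indices_arrays(r443, r469, r488, r555, r645):
    with np.errstate(divide="ignore", invalid="ignore"):
        i1 = (r488 - r443 - (r555 - r443) * 0.5) / r488
        i2 = (r555 - r469 - (r645 - r469) * 0.5) / r469
    i1 = np.where(r488 == 0, np.nan, i1)
    i2 = np.where(r469 == 0, np.nan, i2)
    return i1, i2


def apply_quality_masks(
    scene: Scene, constants: SensorConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Per-pixel validity raster (True = usable for detection).

    Removal order: quality flags, then the Rrc(869) cloud threshold, then the
    index2 cloud rule, then the index1 shadow rule, then the negative
    conversion-band guard.  The function is pure, hence idempotent.
    """
    valid = (np.asarray(scene.flags).astype(np.int64) & int(ALL_FLAGS)) == 0

    r869 = scene.band(869)
    valid &= np.isfinite(r869) & (r869 < constants.cloud_rrc869_threshold)

    i1, i2 = _indices_arrays(
        scene.band(443), scene.band(469), scene.band(488), scene.band(555), scene.band(645)
    )
    valid &= np.isfinite(i2) & (i2 >= constants.index2_threshold)  # cloud
    valid &= np.isfinite(i1) & (i1 <= constants.index1_threshold)  # shadow

    for wl in (667, 678, 748):
        b = scene.band(wl)
        valid &= np.isfinite(b) & (b >= constants.min_conversion_rrc)
    return valid


def detect_blooms(
    scene: Scene,
    boundary: BloomBoundary = DEFAULT_BOUNDARY,
    constants: SensorConstants = DEFAULT_CONSTANTS,
) -> BloomMask:
    """Classify every pixel of a scene as bloom / no-bloom / invalid.

    A valid pixel is a bloom when its chromaticity satisfies
    (x < split and y > y1(x)) or (x >= split and y > y2(x)), with y1/y2 the
    two boundary quadratics.  Invalid pixels (masked, degenerate chromaticity)
    propagate as invalid.
    """
    valid = apply_quality_masks(scene, constants)
    x, y, cvalid = chromaticity_xy(scene.band(748), scene.band(678), scene.band(667))
    valid = valid & cvalid

    yb = boundary_y(np.where(np.isfinite(x), x, 0.0), boundary)
    bloom = valid & np.isfinite(y) & (y > yb)

    state = np.full(scene.grid.shape, INVALID, dtype=np.uint8)
    state[valid] = NO_BLOOM
    state[bloom] = BLOOM
    return BloomMask(scene.grid, state, scene.date)
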