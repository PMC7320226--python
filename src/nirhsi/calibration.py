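"""Reflectance calibration and background masking.

Raw detector counts mix the tissue signal with the lamp spectrum, the
illumination geometry and the dark current.  The standard correction uses a
white reference panel imaged in the scene and a dark frame recorded with the
source off and the lens capped:

    R = rho_panel * (I_raw - I_dark) / (I_white - I_dark)

where ``rho_panel`` is the certified reflectance of the panel (1.0 for an
ideal panel).  When the white reference is a per-band vector (panel-averaged)
the spatial part of the illumination field survives calibration as a
multiplicative factor per pixel — which is exactly the variation the spectral
angle classifier is insensitive to.

After calibration, scene pixels are separated from the dark background by
thresholding a single band (1181 nm by default in this pipeline) into a
binary mask; downstream stages operate only on mask-1 pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .envi import Hypercube

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationFrames",
    "CalibrationError",
    "compute_reflectance",
    "build_background_mask",
    "apply_mask",
]


class CalibrationError(ValueError):
    """White/dark frames unusable at an element that must be calibrated."""


@dataclass
class CalibrationFrames:
    """White-reference and dark-current frames.

    Both may be full frames of the scene's shape ``(rows, cols, bands)`` or
    per-band vectors of length ``bands`` (panel-averaged) that broadcast
    spatially.  ``panel_reflectance`` is the certified reflectance of the
    white panel; calibrated values are scaled by it so a perfect measurement
    of the panel itself yields that value rather than 1.0.
    """

    white: np.ndarray
    dark: np.ndarray
    panel_reflectance: float = 1.0

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.ndim not in (1, 3) or self.dark.ndim not in (1, 3):
            raise ValueError("white/dark must be per-band vectors or full frames")
        if not 0 < self.panel_reflectance <= 1.0:
            raise ValueError("panel_reflectance must be in (0, 1]")

    def broadcast(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """White and dark broadcast against a cube shape."""
        try:
            white = np.broadcast_to(self.white, shape)
            dark = np.broadcast_to(self.dark, shape)
        except ValueError as exc:
            raise ValueError(
                f"calibration frames not conformable with scene {shape}"
            ) from exc
        return white, dark


def compute_reflectance(
    raw: Hypercube,
    frames: CalibrationFrames,
    mask: np.ndarray | None = None,
    clamp: tuple[float, float] | None = (0.0, 1.5),
) -> Hypercube:
    """Convert raw counts to relative reflectance.

    Parameters
    ----------
    raw
        Cube of kind ``raw_counts``.
    frames
        White/dark references, conformable with the cube.
    mask
        Optional 2-D binary mask; elements outside it are set to 0 and the
        white > dark requirement is not enforced there.
    clamp
        Post-calibration value range; noise can push values slightly outside
        [0, 1], so a loose cap bounds outliers without erasing signal.  The
        number of clamped elements is logged.  ``None`` disables clamping.

    Raises
    ------
    CalibrationError
        If ``white - dark <= 0`` anywhere calibration is applied, naming the
        first offending pixel and band.
    """
    if raw.kind != "raw_counts":
        raise ValueError("compute_reflectance expects a raw_counts cube")
    white, dark = frames.broadcast(raw.shape)
    denom = white - dark

    applied = np.ones(raw.shape[:2], dtype=bool) if mask is None else mask.astype(bool)
    bad = (denom <= 0) & applied[:, :, None]
    if bad.any():
        r, c, b = np.argwhere(bad)[0]
        raise CalibrationError(
            f"white - dark <= 0 at pixel (row={r}, col={c}), band index {b} "
            f"({raw.grid.centers[b]:g} nm)"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = frames.panel_reflectance * (raw.values.astype(float) - dark) / denom
    refl = np.where(applied[:, :, None], refl, 0.0)
    refl = np.nan_to_num(refl, nan=0.0, posinf=0.0, neginf=0.0)

    if clamp is not None:
        n_clamped = int(np.count_nonzero((refl < clamp[0]) | (refl > clamp[1])))
        if n_clamped:
            log.info("clamped %d of %d elements to [%g, %g]",
                     n_clamped, refl.size, *clamp)
        refl = np.clip(refl, clamp[0], clamp[1])

    meta = dict(raw.meta)
    meta["calibration"] = {
        "panel_reflectance": frames.panel_reflectance,
        "clamp": clamp,
    }
    return Hypercube(refl, raw.grid, kind="reflectance", meta=meta)


def build_background_mask(
    cube: Hypercube,
    band_nm: float = 1181.0,
    method: str | float = "otsu",
) -> np.ndarray:
    """Binary scene mask from a single reflectance band.

    The band used is the grid center nearest ``band_nm``.  ``method`` is
    either ``"otsu"`` (parameter-free threshold on that band) or a fixed
    reflectance threshold; pixels strictly above the threshold are scene
    (mask 1), the rest background (mask 0).
    """
    if cube.kind != "reflectance":
        raise ValueError("background mask is built on a reflectance cube")
    if not cube.grid.centers[0] <= band_nm <= cube.grid.centers[-1]:
        raise ValueError(f"{band_nm:g} nm outside the wavelength grid")
    idx = cube.grid.nearest(band_nm)
    log.info("masking at %g nm -> band index %d (%g nm)",
             band_nm, idx, cube.grid.centers[idx])
    band = cube.values[:, :, idx]

    if method == "otsu":
        if np.ptp(band) == 0:
            log.warning("uniform band image; degenerate all-one mask")
            return np.ones(band.shape, dtype=np.uint8)
        thresh = float(threshold_otsu(band))
    else:
        thresh = float(method)

    mask = (band > thresh).astype(np.uint8)
    ones = int(mask.sum())
    if ones == 0 or ones == mask.size:
        log.warning("degenerate background mask (%d of %d pixels included)",
                    ones, mask.size)
    return mask


def apply_mask(cube: Hypercube, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract the masked pixel-spectrum table.

    Returns ``(coords, spectra)`` where ``coords`` is an ``(n, 2)`` array of
    (row, column) positions with mask 1 in row-major order and ``spectra``
    the matching ``(n, bands)`` reflectance table.
    """
    mask = np.asarray(mask)
    if mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.shape[:2]}"
        )
    coords = np.argwhere(mask.astype(bool))
    spectra = cube.values[coords[:, 0], coords[:, 1], :]
    return coords, spectra
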