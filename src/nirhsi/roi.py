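"""Seeded "grow" region-of-interest selection and spectrum statistics.

A small seed (a few pixels around a chosen point inside a lesion or a patch
of normal tissue) defines per-band acceptance statistics; the region then
expands to all connected pixels whose spectrum stays within
``mean +/- multiplier * std`` of the *seed* at every band.  The acceptance
statistics are frozen at the seed — they are not updated while the region
grows — which makes the result independent of visit order: the grown ROI is
simply the connected component of the static acceptance map that contains
the seed.

Standard deviations are population ones (divide by n) throughout, both for
the seed acceptance rule and for reported ROI statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from .envi import Hypercube

log = logging.getLogger(__name__)

__all__ = ["SeedRegion", "ROI", "SpectrumStats", "make_seed", "grow_roi", "extract_stats"]


@dataclass
class SeedRegion:
    """A small in-mask disc of pixels around a center, with a class label."""

    center: tuple[int, int]
    pixels: np.ndarray  # (n, 2) int rows/cols
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) < 1:
            raise ValueError("seed needs at least one (row, col) pixel")


@dataclass
class ROI:
    """A connected set of pixels grown from a seed, with provenance."""

    label: str
    pixels: np.ndarray  # (n, 2) int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "label": self.label,
            "pixels": self.pixels.tolist(),
            "provenance": self.provenance,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROI":
        d = json.loads(Path(path).read_text())
        return cls(d["label"], np.asarray(d["pixels"]), d.get("provenance", {}))


@dataclass
class SpectrumStats:
    """Per-band mean and population standard deviation of an ROI."""

    mean: np.ndarray
    std: np.ndarray
    n: int
    label: str


def make_seed(
    center: tuple[int, int],
    n_pixels: int,
    label: str,
    mask: np.ndarray,
) -> SeedRegion:
    """The ``n_pixels`` in-mask pixels nearest ``center``.

    Distance is Euclidean; ties are broken row-major.  The center itself must
    be inside the mask.
    """
    mask = np.asarray(mask).astype(bool)
    r0, c0 = center
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise ValueError(f"seed center {center} outside image bounds")
    if not mask[r0, c0]:
        raise ValueError(f"seed center {center} lies on a masked-out pixel")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")

    coords = np.argwhere(mask)
    if len(coords) < n_pixels:
        raise ValueError(
            f"only {len(coords)} in-mask pixels available, need {n_pixels}"
        )
    d2 = (coords[:, 0] - r0) ** 2 + (coords[:, 1] - c0) ** 2
    # lexicographic (distance, row, col) sort = row-major tie-break
    order = np.lexsort((coords[:, 1], coords[:, 0], d2))
    return SeedRegion((r0, c0), coords[order[:n_pixels]], label)


def grow_roi(
    cube: Hypercube,
    seed: SeedRegion,
    std_multiplier: float = 0.2,
    connectivity: int = 8,
    mask: np.ndarray | None = None,
    zero_std_floor: float = 0.01,
) -> ROI:
    """Grow a seed into the connected region of spectrally similar pixels.

    A pixel is acceptable when its spectrum lies within
    ``seed_mean +/- max(std_multiplier * seed_std, zero_std_floor)`` at every
    band; the floor keeps the criterion meaningful at bands where the seed
    has zero variance (e.g. a seed on noiseless data).  The ROI is the
    connected component (4- or 8-connectivity) of acceptable or seed pixels
    that contains the seed, restricted to the mask — a fixed point of
    breadth-first growth.
    """
    if std_multiplier <= 0:
        raise ValueError("std_multiplier must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    rows, cols, _ = cube.shape
    mask = np.ones((rows, cols), dtype=bool) if mask is None else np.asarray(mask).astype(bool)
    rr, cc = seed.pixels[:, 0], seed.pixels[:, 1]
    if not mask[rr, cc].all():
        raise ValueError("seed pixels fall outside the scene mask")

    seed_spectra = cube.values[rr, cc, :]
    mu = seed_spectra.mean(axis=0)
    sigma = seed_spectra.std(axis=0)  # population
    tol = np.maximum(std_multiplier * sigma, zero_std_floor)

    accept = np.all(np.abs(cube.values - mu) <= tol, axis=2) & mask
    accept[rr, cc] = True

    comp = cc_label(accept, connectivity=1 if connectivity == 4 else 2)
    roi_mask = comp == comp[seed.center]
    pixels = np.argwhere(roi_mask)

    if pixels.shape[0] == int(mask.sum()):
        log.warning("grown ROI %r filled the entire scene mask", seed.label)

    return ROI(
        label=seed.label,
        pixels=pixels,
        provenance={
            "seed_center": [int(seed.center[0]), int(seed.center[1])],
            "seed_pixels": seed.pixels.tolist(),
            "std_multiplier": std_multiplier,
            "zero_std_floor": zero_std_floor,
            "connectivity": connectivity,
        },
    )


def extract_stats(cube: Hypercube, roi: ROI) -> SpectrumStats:
    """Per-band arithmetic mean and population std over the ROI pixels."""
    if len(roi.pixels) == 0:
        raise ValueError("cannot extract statistics from an empty ROI")
    spectra = cube.values[roi.pixels[:, 0], roi.pixels[:, 1], :]
    return SpectrumStats(
        mean=spectra.mean(axis=0),
        std=spectra.std(axis=0),
        n=len(roi.pixels),
        label=roi.label,
    )
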