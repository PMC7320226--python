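"""Spectral angle mapper (SAM) classification on a selected band set.

Each pixel spectrum ``t`` is compared against one reference spectrum ``r``
per tissue class via the angle between the two vectors,

    theta = arccos( <t, r> / (||t|| * ||r||) ),

and assigned the class of minimum angle.  Because the angle ignores vector
magnitude, a pixel under brighter or dimmer illumination maps to the same
class — the property that makes SAM a good match for convex tissue surfaces
under nonuniform lighting.  References are built by pooling training ROI
pixels per class and restricting to the selected wavelengths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bands import BandSet
from .envi import Hypercube
from .roi import ROI

log = logging.getLogger(__name__)

__all__ = [
    "ReferenceLibrary",
    "ClassificationMap",
    "spectral_angle",
    "build_references",
    "classify",
    "BACKGROUND",
    "UNCLASSIFIED",
]

#: Label codes in classification maps; classes are 1..n in library order.
BACKGROUND = 0
UNCLASSIFIED = -1


def spectral_angle(t: np.ndarray, r: np.ndarray) -> float:
    """Angle in radians between two spectra; 0 for identical direction.

    Symmetric, invariant to positive scaling of either argument, and in
    [0, pi].  The cosine is clamped to [-1, 1] before the arccos so that
    rounding in the dot product cannot produce NaN.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("spectra must be 1-D vectors of equal length")
    nt, nr = np.linalg.norm(t), np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise ValueError("spectral angle undefined for a zero vector")
    return float(np.arccos(np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)))


@dataclass
class ReferenceLibrary:
    """One reference spectrum per class, restricted to a band set."""

    entries: dict[str, np.ndarray]
    bands: BandSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference library needs at least one class")
        nb = len(self.bands)
        for name, spec in self.entries.items():
            spec = np.asarray(spec, dtype=float)
            self.entries[name] = spec
            if spec.shape != (nb,):
                raise ValueError(f"reference {name!r} does not match the band set")
            if np.linalg.norm(spec) == 0:
                raise ValueError(f"reference {name!r} is a zero vector")

    @property
    def class_names(self) -> list[str]:
        return list(self.entries)

    def matrix(self) -> np.ndarray:
        return np.vstack([self.entries[c] for c in self.entries])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "bands_nm": self.bands.wavelengths.tolist(),
            "classes": {c: v.tolist() for c, v in self.entries.items()},
            "provenance": self.provenance,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceLibrary":
        d = json.loads(Path(path).read_text())
        bands = BandSet(np.asarray(d["bands_nm"], dtype=float))
        entries = {c: np.asarray(v, dtype=float) for c, v in d["classes"].items()}
        return cls(entries, bands, d.get("provenance", {}))


@dataclass
class ClassificationMap:
    """Per-pixel class codes and winning angles.

    ``labels`` holds :data:`BACKGROUND` where the scene mask was 0,
    :data:`UNCLASSIFIED` where the angle threshold rejected the pixel, and
    ``1..n`` (library order) elsewhere.  ``best_angle`` is NaN outside the
    classified pixels.
    """

    labels: np.ndarray
    best_angle: np.ndarray
    class_names: list[str]
    bands: BandSet

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == (self.class_names.index(name) + 1)


def _resolve_bands(grid, bands: BandSet) -> np.ndarray:
    return np.array([grid.resolve(w) for w in bands.wavelengths], dtype=int)


def build_references(
    training: list[tuple[Hypercube, list[ROI]]],
    bands: BandSet,
) -> ReferenceLibrary:
    """Pool training ROI pixels per class into band-restricted references.

    The reference for a class is the pixel-count-weighted mean over all of
    that class's ROI pixels across every training cube — i.e. the plain mean
    of the pooled pixels — evaluated at the grid bands nearest the band-set
    wavelengths.
    """
    if len(bands) == 0:
        raise ValueError("cannot build references on an empty band set")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    scenes: dict[str, int] = {}
    for cube, rois in training:
        if cube.kind != "reflectance":
            raise ValueError("training cubes must be reflectance")
        idx = _resolve_bands(cube.grid, bands)
        for roi in rois:
            if len(roi.pixels) == 0:
                continue
            spectra = cube.values[roi.pixels[:, 0], roi.pixels[:, 1]][:, idx]
            sums[roi.label] = sums.get(roi.label, 0) + spectra.sum(axis=0)
            counts[roi.label] = counts.get(roi.label, 0) + len(spectra)
            scenes[roi.label] = scenes.get(roi.label, 0) + 1
    if not counts:
        raise ValueError("no class has any training pixels")
    for name, n in counts.items():
        if n == 0:
            raise ValueError(f"class {name!r} has zero training pixels")
    entries = {name: sums[name] / counts[name] for name in sums}
    return ReferenceLibrary(
        entries,
        bands,
        provenance={"pixels_per_class": counts, "rois_per_class": scenes},
    )


def classify(
    cube: Hypercube,
    library: ReferenceLibrary,
    mask: np.ndarray,
    max_angle: float | None = None,
) -> ClassificationMap:
    """Minimum-angle classification of every masked pixel.

    Ties go to the earlier library entry (their count is logged).  Pixels
    whose spectrum is zero on the selected bands, or whose best angle exceeds
    ``max_angle`` (when set), become unclassified.
    """
    if cube.kind != "reflectance":
        raise ValueError("classification expects a reflectance cube")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match the cube")

    idx = _resolve_bands(cube.grid, library.bands)
    refs = library.matrix()
    refs_unit = refs / np.linalg.norm(refs, axis=1, keepdims=True)

    coords = np.argwhere(mask)
    X = cube.values[coords[:, 0], coords[:, 1]][:, idx].astype(float)
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    if not ok.all():
        log.warning("%d masked pixels have zero spectrum on the selected bands",
                    int((~ok).sum()))

    cos = np.zeros((len(X), len(refs)))
    cos[ok] = (X[ok] / norms[ok, None]) @ refs_unit.T
    cos = np.clip(cos, -1.0, 1.0)
    angles = np.arccos(cos)

    winner = np.argmin(angles, axis=1)
    best = angles[np.arange(len(X)), winner]
    n_ties = int(np.sum((angles == best[:, None]).sum(axis=1) > 1))
    if n_ties:
        log.info("%d pixels had tied angles; first library entry kept", n_ties)

    labels = np.full(cube.shape[:2], BACKGROUND, dtype=np.int16)
    best_angle = np.full(cube.shape[:2], np.nan)
    lab = winner + 1
    lab[~ok] = UNCLASSIFIED
    if max_angle is not None:
        lab[ok & (best > max_angle)] = UNCLASSIFIED
    labels[coords[:, 0], coords[:, 1]] = lab
    classified = lab != UNCLASSIFIED
    best_angle[coords[classified, 0], coords[classified, 1]] = best[classified]

    return ClassificationMap(labels, best_angle, library.class_names, library.bands)
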