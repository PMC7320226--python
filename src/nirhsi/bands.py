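"""PCA over pixel spectra and loading-extrema wavelength selection.

Principal components of the pooled, band-mean-centered pixel-spectrum matrix
rank the independent modes of spectral variation; the per-band loadings of
the leading components show *where* on the wavelength axis each mode acts.
Wavelengths at the interior local maxima and minima of those loading curves
are the bands that carry most of the between-tissue variance, and the union
over the leading components forms the compact "optimal wavelength" set used
for classification.

The decomposition is computed by singular value decomposition of the
centered table (numerically stabler than forming the covariance explicitly
for many pixels); tests cross-check it against a covariance
eigendecomposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .envi import WavelengthGrid

log = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "BandSet",
    "fit_pca",
    "variance_report",
    "default_components",
    "select_extrema_bands",
]


@dataclass
class PCAResult:
    """Eigenvalues, unit-norm loadings and variance fractions of a PCA fit.

    ``loadings[k]`` is the k-th component's per-band weight vector; the sign
    convention makes each vector's largest-magnitude element positive.
    ``eigenvalues`` are the sample variances (divisor ``n - 1``) along the
    components, sorted non-increasing.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray  # (k, bands)
    variance_fraction: np.ndarray
    band_mean: np.ndarray
    grid: WavelengthGrid | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class BandSet:
    """Selected band-center wavelengths with their provenance.

    ``source`` maps each wavelength to the (component index, ``"max"`` or
    ``"min"``) records that selected it.  Wavelengths are unique, sorted
    ascending, and members of the grid they were selected from.
    """

    wavelengths: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(np.unique(self.wavelengths)) != len(self.wavelengths):
            raise ValueError("band set contains duplicate wavelengths")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("band set wavelengths must be sorted ascending")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "wavelengths_nm": self.wavelengths.tolist(),
            "source": {f"{w:g}": s for w, s in self.source.items()},
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BandSet":
        d = json.loads(Path(path).read_text())
        wl = np.asarray(d["wavelengths_nm"], dtype=float)
        src = {float(k): [tuple(x) for x in v] for k, v in d.get("source", {}).items()}
        return cls(wl, src)


def fit_pca(pixel_spectra: np.ndarray, grid: WavelengthGrid | None = None) -> PCAResult:
    """PCA of an ``(n_pixels, n_bands)`` table via SVD of the centered data.

    Handles rank-deficient input (zero eigenvalues are kept); constant data
    produces all-zero eigenvalues with a warning.
    """
    X = np.asarray(pixel_spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 pixels and 2 bands")
    if not np.all(np.isfinite(X)):
        raise ValueError("pixel spectra must be finite")
    if grid is not None and grid.count != X.shape[1]:
        raise ValueError("grid count does not match the number of bands")

    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)

    if eig.max(initial=0.0) == 0.0:
        log.warning("constant pixel table: all eigenvalues are zero")
        frac = np.zeros_like(eig)
    else:
        frac = eig / eig.sum()

    # sign convention: largest-|.| loading element positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]

    return PCAResult(eig, vt, frac, mean, grid)


def variance_report(result: PCAResult, k: int) -> list[tuple[int, float]]:
    """First ``k`` components as ``(component_number, percent_variance)``.

    Component numbers are 1-based, matching the usual PC1/PC2 naming.
    """
    if k > result.n_components:
        raise ValueError(f"only {result.n_components} components available")
    return [(i + 1, 100.0 * float(result.variance_fraction[i])) for i in range(k)]


def default_components(
    result: PCAResult,
    cumulative: float = 0.97,
    floor: float = 0.01,
) -> list[int]:
    """Leading components to examine for band selection.

    The smallest set of leading components whose cumulative variance fraction
    reaches ``cumulative``, considering only components that individually
    explain at least ``floor`` of the variance (a noise-floor guard: the long
    tail of near-equal noise eigenvalues would otherwise drag dozens of
    meaningless components in).  If the target is unreachable within the
    eligible components, all of them are used.
    """
    frac = result.variance_fraction
    eligible = np.flatnonzero(frac >= floor)
    if eligible.size == 0:
        return [0]
    cum = np.cumsum(frac[eligible])
    if cum[-1] >= cumulative:
        stop = int(np.searchsorted(cum, cumulative) + 1)
    else:
        stop = int(eligible.size)
    return [int(i) for i in eligible[:stop]]


def select_extrema_bands(
    result: PCAResult,
    components: list[int] | None = None,
    prominence: float = 0.15,
    max_per_component: int | None = None,
) -> BandSet:
    """Wavelengths at prominent interior extrema of loading curves.

    For each requested component (0-based indices; default
    :func:`default_components`), interior local maxima and minima of the
    loading-versus-wavelength curve are located, keeping those whose
    prominence is at least ``prominence`` times the component's loading
    range.  Endpoint bands are never selected.  The union over components is
    deduplicated and sorted; ``source`` records which component and extremum
    type proposed each wavelength.
    """
    if result.grid is None:
        raise ValueError("PCA result has no wavelength grid attached")
    if prominence < 0:
        raise ValueError("prominence must be non-negative")
    if components is None:
        components = default_components(result)
    for c in components:
        if not 0 <= c < result.n_components:
            raise ValueError(f"component {c} does not exist")

    centers = result.grid.centers
    found: dict[float, list[tuple[int, str]]] = {}
    for c in components:
        curve = result.loadings[c]
        span = float(curve.max() - curve.min())
        candidates: list[tuple[float, int, str]] = []
        for sign, kind in ((1.0, "max"), (-1.0, "min")):
            # prominence > 0 keeps plateau-free strict extrema only
            peaks, props = find_peaks(
                sign * curve, prominence=max(prominence * span, 1e-12)
            )
            candidates.extend(
                (float(props["prominences"][i]), int(p), kind)
                for i, p in enumerate(peaks)
            )
        candidates.sort(reverse=True)
        if max_per_component is not None:
            candidates = candidates[:max_per_component]
        for _, idx, kind in candidates:
            found.setdefault(float(centers[idx]), []).append((c, kind))

    if not found:
        log.warning("no loading extremum passed the prominence filter")
        return BandSet(np.empty(0), {})
    wl = np.array(sorted(found))
    return BandSet(wl, {w: found[w] for w in wl})
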