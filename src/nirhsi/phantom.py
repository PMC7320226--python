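"""Synthetic tissue-phantom scenes for the NIR-HSI pipeline.

Real specimen cubes for this problem are not publicly available, so the
generator emulates their structure: a 168-band 900–1700 nm cube of 14-bit
raw counts containing a dark background and a central tissue slab in which
elliptical cancerous lesions sit on normal tissue.  Cancerous tissue is
brighter than normal tissue at every wavelength, and both classes carry the
NIR absorption structure reported for gastric tissue: water/organic bands
near 975, 1215 and 1450 nm (1450 strongest, 975 weakest), with reflectance
shoulders between them near 1075 and 1275 nm where the classes also differ,
and a broad water-shoulder mode near 1390 nm whose depth varies from pixel
to pixel *within* both classes (tissue hydration variability) but barely
differs between their means.

That layout gives the pixel population the covariance structure the
loading-extrema band selection relies on: the first principal component carries the
normal/cancer contrast (extrema at 975, 1075, 1215, 1275, 1450 nm) and the
second carries the hydration mode (extremum at 1390 nm).

Endmember model (per class ``c``)::

    R_c(lambda) = B_c(lambda) * (1 - sum_k A_ck * g(lambda; mu_k, sigma_k))

with linear baselines ``B_c`` and Gaussian features ``g``; negative depths
``A`` are reflectance peaks.  The forward model to counts is::

    counts = dark + gain * L(lambda) * R * illum(row, col) + noise

with a smooth unit-mean multiplicative illumination field, a fixed lamp
spectrum ``L``, and additive Gaussian sensor noise, rounded and clipped to
the 14-bit range.  The bundled white reference is the per-band response of a
constant-reflectance panel under unit illumination, so calibrating a
noiseless, gradient-free scene recovers the endmember spectra exactly (to
machine precision with ``quantize=False``, to one count otherwise).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .calibration import CalibrationFrames
from .envi import Hypercube, WavelengthGrid, read_envi, read_mask_envi, write_envi, write_mask_envi

log = logging.getLogger(__name__)

__all__ = [
    "SpectralFeature",
    "EndmemberLibrary",
    "PhantomConfig",
    "PhantomScene",
    "default_endmembers",
    "contrast_depth",
    "contrast_regions",
    "simulate_scene",
    "simulate_study",
    "save_scene",
    "load_scene",
    "TRUTH_BACKGROUND",
    "TRUTH_NORMAL",
    "TRUTH_CANCER",
    "TRUTH_CODES",
]

TRUTH_BACKGROUND = 0
TRUTH_NORMAL = 1
TRUTH_CANCER = 2
TRUTH_CODES = {"normal": TRUTH_NORMAL, "cancer": TRUTH_CANCER}

#: Feature centers (nm) shared by both tissue classes.
FEATURE_CENTERS = (975.0, 1075.0, 1215.0, 1275.0, 1390.0, 1450.0)
#: Feature widths (nm); the 1390 entry matches the hydration-variability mode.
FEATURE_WIDTHS = (20.0, 20.0, 20.0, 20.0, 25.0, 14.0)
#: Depths (fraction of baseline); negative = reflectance shoulder peak.
NORMAL_DEPTHS = (0.08, -0.08, 0.14, -0.09, 0.050, 0.18)
CANCER_DEPTHS = (0.145, -0.12, 0.20, -0.15, 0.034, 0.26)
#: Linear baseline reflectance (value at 900 nm, value at 1700 nm).
NORMAL_BASELINE = (0.30, 0.38)
CANCER_BASELINE = (0.42, 0.52)
BACKGROUND_REFLECTANCE = 0.02


@dataclass(frozen=True)
class SpectralFeature:
    """A Gaussian spectral feature: absorption dip (depth > 0) or peak."""

    center_nm: float
    width_nm: float
    depth: float


def _gaussians(grid: WavelengthGrid, features: list[SpectralFeature]) -> np.ndarray:
    lam = grid.centers[:, None]
    mu = np.array([f.center_nm for f in features])[None, :]
    sig = np.array([f.width_nm for f in features])[None, :]
    return np.exp(-0.5 * ((lam - mu) / sig) ** 2)


def _baseline(grid: WavelengthGrid, lo_hi: tuple[float, float]) -> np.ndarray:
    t = (grid.centers - grid.centers[0]) / (grid.centers[-1] - grid.centers[0])
    return lo_hi[0] + (lo_hi[1] - lo_hi[0]) * t


@dataclass
class EndmemberLibrary:
    """Reference reflectance spectra of the phantom classes.

    ``spectra`` maps class tag to a reflectance vector on ``grid``;
    ``features`` and ``baselines`` keep the closed-form parameters so that
    derived quantities (contrast depth, feature centers) stay exact.
    """

    grid: WavelengthGrid
    spectra: dict[str, np.ndarray]
    features: dict[str, list[SpectralFeature]]
    baselines: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, spec in self.spectra.items():
            if spec.shape != (self.grid.count,):
                raise ValueError(f"endmember {name!r} does not match the grid")
            if spec.min() < 0 or spec.max() > 1:
                raise ValueError(f"endmember {name!r} outside [0, 1]")
        if "normal" in self.spectra and "cancer" in self.spectra:
            if not np.all(self.spectra["cancer"] > self.spectra["normal"]):
                raise ValueError("cancer endmember must exceed normal at every band")

    def feature_centers(self) -> np.ndarray:
        centers = {f.center_nm for fs in self.features.values() for f in fs}
        return np.array(sorted(centers))


def default_endmembers(grid: WavelengthGrid) -> EndmemberLibrary:
    """The phantom's default normal/cancer/background endmembers.

    Requires the grid to span at least [950, 1500] nm so all features fit.
    Within each class the absorption dips keep the reported ordering
    A(1450) > A(1215) > A(975), and the cancer baseline exceeds the normal
    baseline everywhere.
    """
    if grid.centers[0] > 950.0 or grid.centers[-1] < 1500.0:
        raise ValueError("grid too narrow: endmembers need [950, 1500] nm coverage")
    features = {
        "normal": [SpectralFeature(c, w, d) for c, w, d in
                   zip(FEATURE_CENTERS, FEATURE_WIDTHS, NORMAL_DEPTHS)],
        "cancer": [SpectralFeature(c, w, d) for c, w, d in
                   zip(FEATURE_CENTERS, FEATURE_WIDTHS, CANCER_DEPTHS)],
        "background": [],
    }
    baselines = {
        "normal": NORMAL_BASELINE,
        "cancer": CANCER_BASELINE,
        "background": (BACKGROUND_REFLECTANCE, BACKGROUND_REFLECTANCE),
    }
    spectra = {}
    for name in features:
        B = _baseline(grid, baselines[name])
        if features[name]:
            G = _gaussians(grid, features[name])
            depths = np.array([f.depth for f in features[name]])
            spectra[name] = B * (1.0 - G @ depths)
        else:
            spectra[name] = B
    return EndmemberLibrary(grid, spectra, features, baselines)


def contrast_depth(library: EndmemberLibrary) -> np.ndarray:
    """Cancer's excess absorption contrast, per band.

    The difference spectrum cancer − normal rides on the baseline brightness
    difference; subtracting that baseline leaves the feature-driven part,
    positive where cancer absorbs more than normal relative to baseline.
    """
    d_base = (_baseline(library.grid, library.baselines["cancer"])
              - _baseline(library.grid, library.baselines["normal"]))
    diff = library.spectra["cancer"] - library.spectra["normal"]
    return d_base - diff


def contrast_regions(
    library: EndmemberLibrary,
    rel_threshold: float = 0.5,
) -> list[tuple[float, float]]:
    """Contiguous wavelength regions of strong class contrast.

    Regions are maximal runs of bands where :func:`contrast_depth` is at
    least ``rel_threshold`` times its maximum (half-maximum by default),
    returned as (lo_nm, hi_nm) pairs.
    """
    depth = contrast_depth(library)
    above = depth >= rel_threshold * depth.max()
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    lam = library.grid.centers
    return [(float(lam[edges[i]]), float(lam[edges[i + 1] - 1]))
            for i in range(0, len(edges), 2)]


@dataclass
class PhantomConfig:
    """Generator settings; the defaults define the reference study.

    Geometry: a ``rows x cols`` frame whose central ellipse (~70% of each
    linear extent) is tissue, with ``n_lesions`` random cancer ellipses of
    semi-axis range ``lesion_axes`` pixels.  Signal chain: ``white_level``
    counts for the panel, ``dark_level`` dark current, additive Gaussian
    noise of ``noise_sigma`` counts (~SNR 25 in reflectance at mid-scale for
    the default), a smooth multiplicative illumination field of amplitude
    ``illumination_amplitude``, and the per-pixel hydration mode of standard
    deviation ``variability_sigma`` (in depth units) at
    ``variability_center``/``variability_width`` nm.
    """

    rows: int = 96
    cols: int = 96
    n_bands: int = 168
    wavelength_min: float = 900.0
    wavelength_max: float = 1700.0
    n_lesions: tuple[int, int] = (1, 3)
    lesion_axes: tuple[float, float] = (6.0, 14.0)
    tissue_fraction: float = 0.70
    illumination_amplitude: float = 0.15
    noise_sigma: float = 170.0
    variability_sigma: float = 0.116
    variability_center: float = 1390.0
    variability_width: float = 25.0
    dark_level: float = 100.0
    white_level: float = 12000.0
    panel_reflectance: float = 0.9
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols) < 8 or self.n_bands < 2:
            raise ValueError("scene too small")
        if self.noise_sigma < 0 or self.variability_sigma < 0:
            raise ValueError("noise and variability sigmas must be >= 0")
        if not 0 <= self.illumination_amplitude < 1:
            raise ValueError("illumination amplitude must be in [0, 1)")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must be in (0, 1]")
        if self.n_lesions[0] < 1 or self.n_lesions[1] < self.n_lesions[0]:
            raise ValueError("invalid lesion count range")
        if self.lesion_axes[0] <= 0 or self.lesion_axes[1] < self.lesion_axes[0]:
            raise ValueError("invalid lesion axis range")
        if self.white_level <= self.dark_level:
            raise ValueError("white level must exceed dark level")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(
            self.wavelength_min, self.wavelength_max, self.n_bands
        )

    def noiseless(self) -> "PhantomConfig":
        """A copy with every stochastic perturbation switched off."""
        return dataclasses.replace(
            self,
            noise_sigma=0.0,
            illumination_amplitude=0.0,
            variability_sigma=0.0,
            quantize=False,
        )


@dataclass
class PhantomScene:
    """A simulated acquisition: raw cube, references, and ground truth."""

    raw: Hypercube
    frames: CalibrationFrames
    truth: np.ndarray  # int8 image of TRUTH_* codes
    library: EndmemberLibrary
    config: PhantomConfig
    illumination: np.ndarray
    seed_points: dict[str, tuple[int, int]] | None = None
    role: str = "scene"


def _lamp_shape(grid: WavelengthGrid) -> np.ndarray:
    # gentle tungsten-like envelope peaking near 1300 nm
    return 1.0 - 0.25 * ((grid.centers - 1300.0) / 400.0) ** 2


def _illumination_field(rows: int, cols: int, amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth random low-order multiplicative field with unit mean."""
    coeffs = rng.standard_normal(5)
    if amplitude == 0.0:
        return np.ones((rows, cols))
    u = np.linspace(-1.0, 1.0, rows)[:, None]
    v = np.linspace(-1.0, 1.0, cols)[None, :]
    f = (coeffs[0] * u + coeffs[1] * v + coeffs[2] * (u * u - 1 / 3)
         + coeffs[3] * u * v + coeffs[4] * (v * v - 1 / 3))
    f = f - f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return 1.0 + amplitude * f


def _stamp_lesions(truth: np.ndarray, tissue: np.ndarray,
                   config: PhantomConfig, rng: np.random.Generator) -> None:
    rows, cols = truth.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    n = int(rng.integers(config.n_lesions[0], config.n_lesions[1] + 1))
    for _ in range(n):
        for _attempt in range(20):
            r0 = rng.uniform(0.2 * rows, 0.8 * rows)
            c0 = rng.uniform(0.2 * cols, 0.8 * cols)
            a = rng.uniform(*config.lesion_axes)
            b = rng.uniform(*config.lesion_axes)
            theta = rng.uniform(0, np.pi)
            x = (cc - c0) * np.cos(theta) + (rr - r0) * np.sin(theta)
            y = -(cc - c0) * np.sin(theta) + (rr - r0) * np.cos(theta)
            inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
            lesion = inside & tissue  # clip to the tissue slab
            if lesion.any():
                truth[lesion] = TRUTH_CANCER
                break
        else:
            raise RuntimeError("could not place a lesion inside the tissue region")


def simulate_scene(
    config: PhantomConfig,
    library: EndmemberLibrary | None = None,
    rng: np.random.Generator | None = None,
) -> PhantomScene:
    """Generate one phantom acquisition.

    Identical config and seed give a bit-identical scene.  With
    ``config.noiseless()`` settings the calibrated cube reproduces the
    per-pixel endmember spectra exactly.
    """
    grid = config.grid
    if library is None:
        library = default_endmembers(grid)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols

    # ground truth: central tissue ellipse, cancer lesions stamped on top
    rr, cc = np.mgrid[0:rows, 0:cols]
    a = config.tissue_fraction * rows / 2.0
    b = config.tissue_fraction * cols / 2.0
    tissue = (((rr - (rows - 1) / 2.0) / a) ** 2
              + ((cc - (cols - 1) / 2.0) / b) ** 2) <= 1.0
    truth = np.full((rows, cols), TRUTH_BACKGROUND, dtype=np.int8)
    truth[tissue] = TRUTH_NORMAL
    _stamp_lesions(truth, tissue, config, rng)

    illum = _illumination_field(rows, cols, config.illumination_amplitude, rng)

    # per-pixel reflectance
    refl = np.empty((rows, cols, grid.count))
    refl[:] = library.spectra["background"]
    refl[truth == TRUTH_NORMAL] = library.spectra["normal"]
    refl[truth == TRUTH_CANCER] = library.spectra["cancer"]

    if config.variability_sigma > 0:
        g_v = np.exp(-0.5 * ((grid.centers - config.variability_center)
                             / config.variability_width) ** 2)
        z = rng.standard_normal((rows, cols))
        for name, code in (("normal", TRUTH_NORMAL), ("cancer", TRUTH_CANCER)):
            sel = truth == code
            B = _baseline(grid, library.baselines[name])
            refl[sel] -= (config.variability_sigma * z[sel])[:, None] * (B * g_v)
        refl = np.clip(refl, 0.0, 1.0)

    lamp = _lamp_shape(grid)
    gain = (config.white_level - config.dark_level) / config.panel_reflectance
    counts = config.dark_level + gain * lamp * refl * illum[:, :, None]
    if config.noise_sigma > 0:
        counts = counts + rng.normal(0.0, config.noise_sigma, counts.shape)
    if config.quantize:
        counts = np.clip(np.round(counts), 0, 2 ** 14 - 1).astype(np.uint16)
    else:
        counts = np.clip(counts, 0, 2 ** 14 - 1)

    white = config.dark_level + (config.white_level - config.dark_level) * lamp
    dark = np.full(grid.count, config.dark_level)
    frames = CalibrationFrames(white, dark, config.panel_reflectance)

    raw = Hypercube(counts, grid, kind="raw_counts",
                    meta={"scene": "phantom", "seed": config.seed})
    return PhantomScene(raw, frames, truth, library, config, illum)


def _auto_seed_points(truth: np.ndarray) -> dict[str, tuple[int, int]]:
    """Deepest interior point of each tissue class (distance-transform peak)."""
    points = {}
    for name, code in TRUTH_CODES.items():
        inside = truth == code
        if not inside.any():
            raise RuntimeError(f"scene has no {name} pixels to seed from")
        dist = distance_transform_edt(inside)
        r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
        points[name] = (int(r), int(c))
    return points


def simulate_study(
    n_train: int = 5,
    n_test: int = 24,
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> tuple[list[PhantomScene], list[PhantomScene]]:
    """Simulate a training/verification study of independent scenes.

    Per-scene random streams are spawned deterministically from the master
    seed, so the whole study is reproducible end to end.  Training scenes
    carry auto-generated seed points (one inside a lesion, one in normal
    tissue) for ROI growth.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("need at least one training and one test scene")
    if config is None:
        config = PhantomConfig()
    library = default_endmembers(config.grid)
    streams = np.random.SeedSequence(seed).spawn(n_train + n_test)
    train, test = [], []
    for i, stream in enumerate(streams):
        scene = simulate_scene(config, library, np.random.default_rng(stream))
        if i < n_train:
            scene.role = f"train_{i}"
            scene.seed_points = _auto_seed_points(scene.truth)
            train.append(scene)
        else:
            scene.role = f"test_{i - n_train}"
            test.append(scene)
    return train, test


def save_scene(scene: PhantomScene, directory: str | Path) -> Path:
    """Write a scene as ENVI raw cube + reference tables + truth mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_envi(scene.raw, directory / "raw", interleave="bil")
    lam = scene.raw.grid.centers
    for name, vec in (("white", scene.frames.white), ("dark", scene.frames.dark)):
        np.savetxt(directory / f"{name}.txt", np.column_stack([lam, vec]),
                   header="wavelength_nm mean_counts")
    write_mask_envi(scene.truth, directory / "truth")
    info = {
        "role": scene.role,
        "panel_reflectance": scene.frames.panel_reflectance,
        "seed_points": scene.seed_points,
        "config": dataclasses.asdict(scene.config),
    }
    (directory / "scene.json").write_text(json.dumps(info, indent=1))
    return directory


def load_scene(directory: str | Path) -> PhantomScene:
    """Read back a scene written by :func:`save_scene`."""
    directory = Path(directory)
    info = json.loads((directory / "scene.json").read_text())
    cfg_d = dict(info["config"])
    for key in ("n_lesions", "lesion_axes"):
        cfg_d[key] = tuple(cfg_d[key])
    config = PhantomConfig(**cfg_d)
    raw = read_envi(directory / "raw.hdr")
    raw.kind = "raw_counts"
    white = np.loadtxt(directory / "white.txt")[:, 1]
    dark = np.loadtxt(directory / "dark.txt")[:, 1]
    frames = CalibrationFrames(white, dark, info["panel_reflectance"])
    truth = read_mask_envi(directory / "truth.hdr").astype(np.int8)
    seeds = info.get("seed_points")
    if seeds is not None:
        seeds = {k: tuple(v) for k, v in seeds.items()}
    return PhantomScene(raw, frames, truth, default_endmembers(raw.grid),
                        config, np.ones(truth.shape), seeds, info.get("role", "scene"))
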