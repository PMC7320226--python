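"""Minimal ENVI-format hypercube I/O.

An ENVI image is a plain text header (``.hdr``) next to a flat binary file.
The header stores the spatial/spectral dimensions, the element type, the byte
order, the band-interleave layout and the wavelength list.  Three interleaves
exist in the wild:

* ``bsq`` — band sequential, ``(band, row, column)``
* ``bil`` — band interleaved by line, ``(row, band, column)``
* ``bip`` — band interleaved by pixel, ``(row, column, band)``

In memory a cube is always held band-last, ``(row, column, band)``, with row 0
at the top; interleave conversion happens only at the I/O boundary.  Only the
minimal standard header fields are interpreted; unknown keys are kept in
``Hypercube.meta`` and logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "read_mask_envi",
    "write_mask_envi",
    "write_image_envi",
]

#: ENVI numeric data-type codes supported here.
_DTYPES = {
    1: np.dtype(np.uint8),
    4: np.dtype(np.float32),
    5: np.dtype(np.float64),
    12: np.dtype(np.uint16),
}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bsq", "bip")

#: Keys the reader interprets; anything else is passed through as metadata.
_KNOWN_KEYS = {
    "samples", "lines", "bands", "interleave", "data type", "byte order",
    "wavelength", "header offset", "file type", "description",
    "wavelength units",
}


class EnviFormatError(ValueError):
    """Malformed header, truncated binary, or unsupported layout."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths, in nanometres.

    Centers must be strictly increasing, at least two, and lie in the
    plausible optical range [300, 3000] nm.
    """

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("wavelength grid needs at least 2 band centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("wavelength centers must be strictly increasing")
        if centers[0] < 300.0 or centers[-1] > 3000.0:
            raise ValueError("wavelength centers must lie within [300, 3000] nm")

    @property
    def count(self) -> int:
        return int(self.centers.size)

    def nearest(self, nm: float) -> int:
        """Index of the band center nearest ``nm``."""
        return int(np.argmin(np.abs(self.centers - nm)))

    def resolve(self, nm: float) -> int:
        """Nearest band index, erroring if ``nm`` is farther than half the
        local band spacing from every center."""
        i = self.nearest(nm)
        lo = self.centers[max(i - 1, 0)]
        hi = self.centers[min(i + 1, self.count - 1)]
        half_spacing = max(self.centers[i] - lo, hi - self.centers[i]) / 2.0
        if abs(self.centers[i] - nm) > max(half_spacing, 1e-9):
            raise ValueError(
                f"{nm:g} nm is not resolvable on this grid "
                f"(nearest center {self.centers[i]:g} nm)"
            )
        return i

    @classmethod
    def linspace(cls, lo: float, hi: float, count: int) -> "WavelengthGrid":
        return cls(np.linspace(lo, hi, count))


@dataclass
class Hypercube:
    """A 3-D spectral image block, indexed ``(row, column, band)``.

    ``kind`` flags whether values are raw detector counts or calibrated
    relative reflectance.  Raw counts must be non-negative and representable
    in 14 bits when stored as integers; reflectance must be finite.
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw_counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be 3-D (row, column, band)")
        if self.values.shape[2] != self.grid.count:
            raise ValueError(
                f"band dimension {self.values.shape[2]} does not match "
                f"grid count {self.grid.count}"
            )
        if self.values.size == 0:
            raise ValueError("hypercube has no pixels")
        if self.kind not in ("raw_counts", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == "raw_counts":
            if np.issubdtype(self.values.dtype, np.integer):
                if self.values.min() < 0 or self.values.max() >= 2 ** 14:
                    raise ValueError("raw counts must fit a 14-bit detector")
            elif self.values.min() < 0:
                raise ValueError("raw counts must be non-negative")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("reflectance values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


def _parse_header_text(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line in header")
    body = text.lstrip()[4:]
    # join brace-delimited multi-line values before splitting into lines
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    fields: dict[str, str] = {}
    for line in body.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _layout_axes(interleave: str) -> tuple[int, ...]:
    # on-disk axis order expressed as a transpose of internal (row, col, band)
    return {"bsq": (2, 0, 1), "bil": (0, 2, 1), "bip": (0, 1, 2)}[interleave]


def _find_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for ext in ("", ".img", ".bil", ".bsq", ".bip", ".dat", ".raw"):
        cand = stem.with_suffix(ext) if ext else stem
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no companion binary found for {header_path}")


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header/binary pair into a band-last :class:`Hypercube`.

    The in-memory result is identical regardless of the interleave on disk,
    and band order in memory equals band order in the header.
    """
    header_path = Path(header_path)
    fields = _parse_header_text(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        code = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field {exc}") from exc
    if min(samples, lines, bands) <= 0:
        raise EnviFormatError("samples/lines/bands must be positive")
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if code not in _DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")

    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )

    dtype = _DTYPES[code]
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    unknown = set(fields) - _KNOWN_KEYS
    if unknown:
        log.warning("ignoring unknown ENVI header keys: %s", sorted(unknown))

    binary_path = _find_binary(header_path)
    expected = samples * lines * bands * dtype.itemsize
    actual = binary_path.stat().st_size
    if actual != expected:
        raise EnviFormatError(
            f"binary size {actual} does not match header "
            f"({samples}x{lines}x{bands}x{dtype.itemsize} = {expected})"
        )

    flat = np.fromfile(binary_path, dtype=dtype)
    axes = _layout_axes(interleave)
    disk_shape = tuple((lines, samples, bands)[a] for a in axes)
    values = np.ascontiguousarray(
        flat.reshape(disk_shape).transpose(np.argsort(axes))
    ).astype(dtype.newbyteorder("="), copy=False)

    kind = "reflectance" if values.dtype.kind == "f" else "raw_counts"
    meta = {k: fields[k] for k in unknown}
    meta["interleave"] = interleave
    return Hypercube(values, WavelengthGrid(wavelengths), kind=kind, meta=meta)


def write_envi(
    cube: Hypercube,
    path: str | Path,
    interleave: str = "bil",
    byte_order: int = 0,
) -> Path:
    """Write ``cube`` as an ENVI header/binary pair; returns the header path.

    Raw-count cubes are stored as unsigned 16-bit integers, reflectance cubes
    as 32-bit floats (64-bit input is preserved).
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")

    if cube.kind == "raw_counts":
        if cube.values.dtype.kind == "f" and not np.allclose(
            cube.values, np.round(cube.values)
        ):
            raise ValueError(
                "raw_counts cube holds non-integer values; quantize before writing"
            )
        data = cube.values.astype(np.uint16)
    else:
        data = cube.values.astype(
            np.float64 if cube.values.dtype == np.float64 else np.float32
        )
    if byte_order == 1:
        data = data.astype(data.dtype.newbyteorder(">"))

    rows, cols, bands = cube.shape
    axes = _layout_axes(interleave)
    disk = np.ascontiguousarray(data.transpose(axes))

    binary_path = path.with_suffix(".img")
    header_path = path.with_suffix(".hdr")
    disk.tofile(binary_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.grid.centers)
    header = (
        "ENVI\n"
        "description = { nirhsi hypercube }\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(data.dtype.newbyteorder('='))]}\n"
        f"interleave = {interleave}\n"
        f"byte order = {byte_order}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    return header_path


def write_image_envi(
    image: np.ndarray,
    path: str | Path,
    band_nm: float | None = None,
    dtype: np.dtype | type = np.uint8,
) -> Path:
    """Write a single 2-D image plane as a one-band ENVI file."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    image.astype(dtype).tofile(path.with_suffix(".img"))
    wl = f"wavelength = {{ {band_nm:.4f} }}\n" if band_nm is not None else ""
    path.with_suffix(".hdr").write_text(
        "ENVI\n"
        "description = { nirhsi image plane }\n"
        f"samples = {image.shape[1]}\n"
        f"lines = {image.shape[0]}\n"
        "bands = 1\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"{wl}"
    )
    return path.with_suffix(".hdr")


def write_mask_envi(mask: np.ndarray, path: str | Path, band_nm: float | None = None) -> Path:
    """Write a 2-D binary/label mask as a single-band 8-bit ENVI image."""
    return write_image_envi(mask, path, band_nm=band_nm, dtype=np.uint8)


def read_mask_envi(header_path: str | Path) -> np.ndarray:
    """Read a single-band 8-bit ENVI image back as a 2-D uint8 array."""
    header_path = Path(header_path)
    fields = _parse_header_text(header_path.read_text())
    samples, lines = int(fields["samples"]), int(fields["lines"])
    if int(fields.get("bands", "1")) != 1 or int(fields["data type"]) != 1:
        raise EnviFormatError("not a single-band 8-bit mask image")
    flat = np.fromfile(_find_binary(header_path), dtype=np.uint8)
    if flat.size != samples * lines:
        raise EnviFormatError("mask binary size mismatch")
    return flat.reshape(lines, samples)
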