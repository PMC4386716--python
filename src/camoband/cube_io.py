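"""Hyperspectral cube and ground-truth mask I/O.

The package-wide in-memory convention is fixed here: cube data is a 3-D
array indexed ``(line, sample, band)`` with a strictly increasing vector
of band-centre wavelengths in nanometres.  ENVI rasters (raw binary +
text ``.hdr`` sidecar, BIL/BIP/BSQ interleave) are normalised to this
layout on read; the self-describing ``.npz`` container stores it
directly.  Masks are single-channel PNG/TIFF images; any nonzero pixel
is positive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Hypercube",
    "GroundTruthMask",
    "FormatError",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


# ENVI "data type" codes <-> numpy dtypes (little-endian on write).
_ENVI_DTYPES = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    3: np.dtype(np.int32),
    4: np.dtype(np.float32),
    5: np.dtype(np.float64),
    12: np.dtype(np.uint16),
    13: np.dtype(np.uint32),
}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}
_REQUIRED_HDR_KEYS = ("samples", "lines", "bands", "interleave", "data type", "wavelength")


@dataclass
class Hypercube:
    """A line-scanned scene: ``data[line, sample, band]`` plus wavelengths.

    Parameters
    ----------
    data
        3-D non-negative intensity array (dimensionless sensor counts).
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, length equal
        to the band-axis extent.
    meta
        Free-form acquisition metadata (bit depth, source file, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.data.ndim != 3:
            raise ValueError(f"cube data must have 3 axes (line, sample, band), got {self.data.ndim}")
        if self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength count ({self.wavelengths.size}) does not match "
                f"band count ({self.data.shape[2]})"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("cube intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("cube intensities must be non-negative")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Return the 2-D band image at ``index`` (line, sample)."""
        return self.data[:, :, index]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypercube):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths, other.wavelengths)
        )


@dataclass
class GroundTruthMask:
    """Binary reference mask over the (line, sample) grid; 1 = camouflaged."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got {self.mask.ndim} axes")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.mask = self.mask.astype(np.uint8)

    @property
    def n_positive(self) -> int:
        return int(self.mask.sum())


def _infer_format(path: Path) -> str:
    return "npz" if path.suffix.lower() == ".npz" else "envi"


# ---------------------------------------------------------------------------
# ENVI dialect
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str, path: Path) -> dict[str, str]:
    lines = text.splitlines()
    if not lines or lines[0].strip().upper() != "ENVI":
        raise FormatError(f"{path}: missing ENVI magic line")
    entries: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_braces = False
    for line in lines[1:]:
        if in_braces:
            stripped = line.strip()
            if stripped.endswith("}"):
                buf.append(stripped[:-1])
                entries[key] = " ".join(buf).strip()
                in_braces = False
            else:
                buf.append(stripped)
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            if val.endswith("}"):
                entries[key] = val[1:-1].strip()
            else:
                in_braces = True
                buf = [val[1:].strip()]
        else:
            entries[key] = val
    return entries


def _header_path(path: Path) -> Path:
    cand = Path(str(path) + ".hdr")
    if cand.exists():
        return cand
    cand = path.with_suffix(".hdr")
    if cand.exists():
        return cand
    raise FormatError(f"no ENVI header found for {path} (tried {path}.hdr and {path.with_suffix('.hdr')})")


def _read_envi(path: Path) -> Hypercube:
    hdr_path = _header_path(path)
    entries = _parse_envi_header(hdr_path.read_text(), hdr_path)
    for key in _REQUIRED_HDR_KEYS:
        if key not in entries:
            raise FormatError(f"{hdr_path}: missing required header key '{key}'")
    samples = int(entries["samples"])
    n_lines = int(entries["lines"])
    bands = int(entries["bands"])
    interleave = entries["interleave"].strip().lower()
    code = int(entries["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {code}")
    dtype = _ENVI_DTYPES[code]
    if int(entries.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    wavelengths = np.array([float(w) for w in entries["wavelength"].replace(",", " ").split()])
    if wavelengths.size != bands:
        raise ValueError(
            f"{hdr_path}: header lists {wavelengths.size} wavelengths for {bands} bands"
        )
    raw = np.fromfile(path, dtype=dtype)
    expected = samples * n_lines * bands
    if raw.size != expected:
        raise FormatError(f"{path}: expected {expected} values, found {raw.size}")
    if interleave == "bsq":
        data = raw.reshape(bands, n_lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(n_lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(n_lines, samples, bands)
    else:
        raise FormatError(f"{hdr_path}: unknown interleave '{interleave}'")
    meta = {"source": str(path), "interleave": interleave, "envi data type": code}
    return Hypercube(np.ascontiguousarray(data), wavelengths, meta)


def _write_envi(cube: Hypercube, path: Path, interleave: str) -> Path:
    interleave = interleave.lower()
    dtype = cube.data.dtype.newbyteorder("<")
    if np.dtype(dtype.newbyteorder("=")) not in _ENVI_CODES:
        raise FormatError(f"dtype {cube.data.dtype} has no ENVI data-type code")
    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = cube.data
    else:
        raise FormatError(f"unknown interleave '{interleave}'")
    np.ascontiguousarray(arr, dtype=dtype).tofile(path)
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cube.n_samples}\n"
        f"lines = {cube.n_lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype.newbyteorder('='))]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)
    return path


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_cube(path: str | Path, format: str | None = None) -> Hypercube:
    """Read a hypercube from ``path``.

    ``format`` is ``"envi"`` or ``"npz"``; when omitted it is inferred
    from the extension (``.npz`` -> array container, anything else ->
    ENVI raw + ``.hdr`` sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cube file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _read_envi(path)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as archive:
            for key in ("data", "wavelengths"):
                if key not in archive:
                    raise FormatError(f"{path}: container missing array '{key}'")
            meta = json.loads(str(archive["meta"])) if "meta" in archive else {}
            return Hypercube(archive["data"], archive["wavelengths"], meta)
    raise ValueError(f"unknown cube format '{fmt}'")


def write_cube(
    cube: Hypercube,
    path: str | Path,
    format: str | None = None,
    interleave: str = "bil",
) -> Path:
    """Write ``cube`` to ``path``; the file round-trips exactly via :func:`read_cube`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        return _write_envi(cube, path, interleave)
    if fmt == "npz":
        np.savez_compressed(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            meta=json.dumps(cube.meta, sort_keys=True, default=str),
        )
        return path
    raise ValueError(f"unknown cube format '{fmt}'")


def read_mask(path: str | Path) -> GroundTruthMask:
    """Read a single-channel image as a binary mask (nonzero -> 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    return GroundTruthMask((arr != 0).astype(np.uint8))


def write_mask(mask: GroundTruthMask | np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit image (positives -> 255)."""
    arr = mask.mask if isinstance(mask, GroundTruthMask) else np.asarray(mask)
    path = Path(path)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))
    return path
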