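"""ENVI raw-binary hyperspectral cube I/O.

Push-broom VNIR cameras write one spatial row at a time, for every
wavelength, into a raw ``.dat`` payload described by an ASCII ``.hdr``
sidecar.  That acquisition order is exactly the standard BIL
(band-interleaved-by-line) layout, so reorganising the stream into an
``(rows, cols, bands)`` image sequence is plain interleave decoding.
This module parses the header dialect, decodes/encodes the three standard
interleaves, and selects wavelength bands.

All coordinates are 0-based, row 0 at top; cubes are indexed
``values[m, n, k]`` = (row, column, band).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ENVIHeader",
    "SpectralCube",
    "ENVIParseError",
    "parse_header",
    "read_cube",
    "write_cube",
    "save_cube",
    "load_cube",
    "band_indices",
]

#: ENVI numeric data-type codes -> numpy dtypes (little-endian base form).
DTYPE_CODES: dict[int, np.dtype] = {
    1: np.dtype(np.uint8),
    2: np.dtype(np.int16),
    4: np.dtype(np.float32),
    12: np.dtype(np.uint16),
}

INTERLEAVES = ("bil", "bip", "bsq")

_MANDATORY = ("samples", "lines", "bands", "data type", "interleave")

# Non-standard key used to carry the number of leading white-reference rows
# through a save/load round trip.
_CALIB_KEY = "calibration rows"


class ENVIParseError(ValueError):
    """Raised when a header cannot be parsed or fails validation."""


@dataclass
class ENVIHeader:
    """Parsed ENVI header.

    Parameters mirror the standard header keys; ``extra`` preserves any
    unrecognised keys verbatim (they are never fatal).
    """

    samples: int
    lines: int
    bands: int
    data_type: int
    interleave: str
    wavelengths_nm: np.ndarray
    wavelength_units: str = "Nanometers"
    default_bands: tuple[int, ...] | None = None
    sensor_type: str = ""
    byte_order: int = 0
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.interleave = self.interleave.lower()
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.samples < 1 or self.lines < 1 or self.bands < 1:
            raise ENVIParseError("samples, lines and bands must all be >= 1")
        if self.interleave not in INTERLEAVES:
            raise ENVIParseError(f"unsupported interleave {self.interleave!r}")
        if self.data_type not in DTYPE_CODES:
            raise ENVIParseError(f"unsupported data type code {self.data_type}")
        if self.wavelengths_nm.size != self.bands:
            raise ENVIParseError(
                f"wavelength list length {self.wavelengths_nm.size} "
                f"!= bands {self.bands}"
            )
        if self.wavelengths_nm.size > 1 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ENVIParseError("wavelengths must be strictly increasing")

    @property
    def dtype(self) -> np.dtype:
        dt = DTYPE_CODES[self.data_type]
        return dt.newbyteorder(">") if self.byte_order == 1 else dt


@dataclass
class SpectralCube:
    """An M x N x Lambda brightness grid with its wavelength vector (nm).

    ``calib_rows`` counts leading image rows that contain the in-frame white
    reference used for calibration (0 when absent).
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    calib_rows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be a 3-D (rows, cols, bands) array")
        if self.wavelengths_nm.size != self.values.shape[2]:
            raise ValueError("wavelength vector length must equal the band count")
        if self.wavelengths_nm.size > 1 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelengths must be strictly increasing")
        if not (0 <= self.calib_rows <= self.values.shape[0]):
            raise ValueError("calib_rows out of range")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def band_sum(self, lo: float | None = None, hi: float | None = None) -> np.ndarray:
        """Per-pixel sum over all bands, or over a closed wavelength range."""
        if lo is None and hi is None:
            return self.values.sum(axis=2)
        lo = self.wavelengths_nm[0] if lo is None else lo
        hi = self.wavelengths_nm[-1] if hi is None else hi
        idx = band_indices(self.wavelengths_nm, lo, hi)
        if idx.size == 0:
            raise ValueError(f"no bands in [{lo}, {hi}] nm")
        return self.values[:, :, idx].sum(axis=2)


# ---------------------------------------------------------------------------
# header parsing / writing
# ---------------------------------------------------------------------------

def _split_pairs(text: str):
    """Yield (key, value) pairs from the ``key = value`` ENVI dialect.

    Values wrapped in braces may span multiple lines.
    """
    body = re.sub(r"^\s*ENVI\s*\n", "", text, count=1)
    pos = 0
    pair_re = re.compile(r"\s*([^={}\n][^=\n]*?)\s*=\s*", re.S)
    while pos < len(body):
        m = pair_re.match(body, pos)
        if m is None:
            # skip blank / comment line
            nl = body.find("\n", pos)
            if nl < 0:
                break
            pos = nl + 1
            continue
        key = m.group(1).strip().lower()
        pos = m.end()
        if pos < len(body) and body[pos] == "{":
            close = body.find("}", pos)
            if close < 0:
                raise ENVIParseError(f"unterminated brace list for key {key!r}")
            value = body[pos + 1 : close]
            pos = close + 1
        else:
            nl = body.find("\n", pos)
            if nl < 0:
                nl = len(body)
            value = body[pos:nl]
            pos = nl + 1
        yield key, value.strip()


def parse_header(text: str) -> ENVIHeader:
    """Parse the contents of an ENVI ``.hdr`` file.

    Missing mandatory keys raise :class:`ENVIParseError` naming the key;
    unknown keys are preserved in :attr:`ENVIHeader.extra`.
    """
    raw = dict(_split_pairs(text))
    for key in _MANDATORY:
        if key not in raw:
            raise ENVIParseError(f"mandatory header key {key!r} is missing")

    known = {
        "samples",
        "lines",
        "bands",
        "data type",
        "interleave",
        "wavelength",
        "wavelength units",
        "default bands",
        "sensor type",
        "byte order",
    }
    extra = {k: v for k, v in raw.items() if k not in known}

    bands = int(raw["bands"])
    if "wavelength" in raw:
        wl = np.array(
            [float(tok) for tok in re.split(r"[,\s]+", raw["wavelength"]) if tok],
            dtype=float,
        )
    else:
        # band index stand-in; keeps headers without a wavelength list usable
        wl = np.arange(bands, dtype=float)

    default_bands = None
    if "default bands" in raw:
        default_bands = tuple(
            int(tok) for tok in re.split(r"[,\s]+", raw["default bands"]) if tok
        )

    return ENVIHeader(
        samples=int(raw["samples"]),
        lines=int(raw["lines"]),
        bands=bands,
        data_type=int(raw["data type"]),
        interleave=raw["interleave"].lower(),
        wavelengths_nm=wl,
        wavelength_units=raw.get("wavelength units", "Nanometers"),
        default_bands=default_bands,
        sensor_type=raw.get("sensor type", ""),
        byte_order=int(raw.get("byte order", 0)),
        extra=extra,
    )


def _format_header(header_fields: dict[str, str]) -> str:
    lines = ["ENVI"]
    lines += [f"{k} = {v}" for k, v in header_fields.items()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cube decode / encode
# ---------------------------------------------------------------------------

def read_cube(data: bytes, header: ENVIHeader) -> SpectralCube:
    """Decode a raw interleaved byte stream into a :class:`SpectralCube`."""
    m, n, b = header.lines, header.samples, header.bands
    dtype = header.dtype
    expected = m * n * b * dtype.itemsize
    if len(data) != expected:
        raise IOError(
            f"stream length mismatch: expected {expected} bytes "
            f"({m}x{n}x{b} of {dtype.itemsize}), got {len(data)}"
        )
    flat = np.frombuffer(data, dtype=dtype)
    il = header.interleave
    if il == "bil":
        values = flat.reshape(m, b, n).transpose(0, 2, 1)
    elif il == "bip":
        values = flat.reshape(m, n, b)
    else:  # bsq
        values = flat.reshape(b, m, n).transpose(1, 2, 0)
    calib = int(header.extra.get(_CALIB_KEY, 0))
    return SpectralCube(
        values=np.ascontiguousarray(values),
        wavelengths_nm=header.wavelengths_nm.copy(),
        calib_rows=calib,
    )


def write_cube(
    cube: SpectralCube, interleave: str = "bil", data_type: int = 4
) -> tuple[bytes, str]:
    """Encode a cube as ``(.dat bytes, .hdr text)``.

    ``read_cube(parse_header(hdr), dat)`` reproduces the cube bit-exactly
    for float32 data.
    """
    interleave = interleave.lower()
    if interleave not in INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if data_type not in DTYPE_CODES:
        raise ValueError(f"unsupported data type code {data_type}")
    m, n, b = cube.shape
    arr = np.asarray(cube.values, dtype=DTYPE_CODES[data_type])
    if interleave == "bil":
        payload = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        payload = arr
    else:
        payload = arr.transpose(2, 0, 1)
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    fields = {
        "description": "{handspec exported cube}",
        "samples": str(n),
        "lines": str(m),
        "bands": str(b),
        "header offset": "0",
        "file type": "ENVI Standard",
        "data type": str(data_type),
        "interleave": interleave,
        "byte order": "0",
        "sensor type": "VNIR",
        "wavelength units": "Nanometers",
        "wavelength": "{ " + wl + " }",
    }
    if cube.calib_rows:
        fields[_CALIB_KEY] = str(cube.calib_rows)
    return np.ascontiguousarray(payload).tobytes(), _format_header(fields)


def save_cube(
    cube: SpectralCube, stem: str | Path, interleave: str = "bil", data_type: int = 4
) -> tuple[Path, Path]:
    """Write ``<stem>.dat`` and ``<stem>.hdr``; returns the two paths."""
    stem = Path(stem)
    dat, hdr = write_cube(cube, interleave=interleave, data_type=data_type)
    dat_path = stem.with_suffix(".dat")
    hdr_path = stem.with_suffix(".hdr")
    dat_path.write_bytes(dat)
    hdr_path.write_text(hdr)
    return dat_path, hdr_path


def load_cube(path: str | Path) -> SpectralCube:
    """Load a cube from a ``.dat``/``.hdr`` pair (either path accepted)."""
    path = Path(path)
    stem = path.with_suffix("")
    header = parse_header(stem.with_suffix(".hdr").read_text())
    return read_cube(stem.with_suffix(".dat").read_bytes(), header)


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------

def band_indices(wavelengths_nm: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices ``k`` with ``lo <= wavelengths_nm[k] <= hi`` (closed interval),
    in ascending order.  An empty result is allowed."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    wl = np.asarray(wavelengths_nm, dtype=float)
    return np.nonzero((wl >= lo) & (wl <= hi))[0]
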