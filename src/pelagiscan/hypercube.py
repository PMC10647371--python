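"""Hyperspectral cube data model, ENVI-style I/O and white-reference calibration.

A push-broom VIS-NIR line-scan camera (e.g. a Resonon Pika L) emits cubes of
``N`` scan lines x ``M`` cross-track pixels x ``Lc`` spectral bands, stored as
an ENVI raster (flat little-endian binary + plain-text ``.hdr``).  Raw digital
counts are converted to reflectance by dividing, band by band, by a frame of a
diffuse white standard (Spectralon) captured under the same illumination::

    S(i, j, c) = A(i, j, c) / R(j, c)

The reference varies with cross-track position and band but not along the scan
axis, so a single reference frame of shape (M, Lc) is broadcast over scan
lines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Hypercube",
    "ReferenceFrame",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "nominal_wavelengths",
]

#: Nominal spectral axis of the instrument: 281 evenly spaced band centers
#: spanning 400-1000 nm.
NOMINAL_BAND_COUNT = 281
NOMINAL_RANGE_NM = (400.0, 1000.0)

# ENVI "data type" codes <-> numpy dtypes (little-endian).
_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


def nominal_wavelengths(n_bands: int = NOMINAL_BAND_COUNT) -> np.ndarray:
    """Evenly spaced band centers over the instrument's 400-1000 nm range."""
    lo, hi = NOMINAL_RANGE_NM
    return np.linspace(lo, hi, n_bands)


def _check_wavelengths(wavelengths: np.ndarray, n_bands: int) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size != n_bands:
        raise ValueError(
            f"corrupt raster: {wl.size} wavelengths for {n_bands} bands"
        )
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelengths must be finite")
    return wl


@dataclass
class Hypercube:
    """A 3-D raster (scan line i, cross-track pixel j, band c) with a nm axis.

    ``data`` holds raw digital counts when ``calibrated`` is False and
    reflectance (unitless, nominally in [0, 1]) when True.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("corrupt raster: cube data must be 3-D (N, M, Lc)")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.data.shape[2])
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data must be finite")
        if np.any(self.data < 0):
            raise ValueError("cube data must be nonnegative")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, c: int) -> np.ndarray:
        """2-D slice of band ``c`` (view)."""
        return self.data[:, :, c]


@dataclass
class ReferenceFrame:
    """White-standard frame: counts per (cross-track pixel j, band c).

    Entries below ``eps_fraction`` of the frame maximum are raised to that
    floor so the Eq.-style division never hits zero.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    eps_fraction: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reference frame must be 2-D (M, Lc)")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.values.shape[1])
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("reference frame must be finite and nonnegative")

    def guarded(self) -> np.ndarray:
        """Values with the zero-guard applied; errors if degenerate."""
        vmax = float(self.values.max(initial=0.0))
        if vmax <= 0:
            raise ValueError("degenerate reference: frame is all zeros")
        floor = self.eps_fraction * vmax
        out = np.maximum(self.values, floor)
        if np.any(out <= 0):  # pragma: no cover - floor > 0 guarantees this
            raise ValueError("degenerate reference")
        return out


def calibrate_reflectance(
    raw: Hypercube, reference: ReferenceFrame, clip: bool = True
) -> Hypercube:
    """Divide raw counts by the white-reference frame, band by band.

    Parameters
    ----------
    raw
        Uncalibrated cube of digital counts.
    reference
        White-standard frame with an identical wavelength axis; broadcast
        along the scan axis (push-broom geometry).
    clip
        Clamp the result into [0, 1].  On by default, matching the convention
        that reflectance is reported in [0, 1]; turn off for diagnostics of
        specular or >99%-standard pixels.

    Returns
    -------
    Hypercube
        New calibrated cube; ``raw`` is left untouched.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    if raw.n_pixels != reference.values.shape[0]:
        raise ValueError("wavelength mismatch: cross-track size differs")
    if raw.n_bands != reference.values.shape[1] or not np.allclose(
        raw.wavelengths, reference.wavelengths
    ):
        raise ValueError("wavelength mismatch between cube and reference")
    denom = reference.guarded()  # (M, Lc)
    refl = raw.data.astype(float) / denom[np.newaxis, :, :]
    if clip:
        refl = np.clip(refl, 0.0, 1.0)
    return Hypercube(refl, raw.wavelengths.copy(), calibrated=True)


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    """Parse an ENVI ``key = value`` header; ``{...}`` blocks may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("corrupt raster: not an ENVI header")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        offset = len(body) - len(rest)
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise ValueError("corrupt raster: unterminated '{' block")
            value = rest[1:close]
            i = offset + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl]
            i = offset + nl + 1
        if key:
            fields[key] = value.strip()
    return fields


def read_envi(header_path: str | os.PathLike) -> Hypercube:
    """Read an ENVI header/raster pair into a :class:`Hypercube`.

    The raster file is located by replacing the header extension with
    ``.raw`` (or stripping ``.hdr``); ``samples``/``lines``/``bands``,
    ``interleave``, ``data type`` and the ``wavelength`` block are honoured.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())

    for key in ("samples", "lines", "bands"):
        if key not in fields:
            raise ValueError(f"corrupt raster: header missing '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    if "wavelength" not in fields:
        raise ValueError("no spectral axis: header has no wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"corrupt raster: {wavelengths.size} wavelengths for {bands} bands"
        )
    interleave = fields.get("interleave", "bil").strip().lower()
    dtype = _ENVI_DTYPES.get(int(fields.get("data type", 4)))
    if dtype is None:
        raise ValueError("corrupt raster: unsupported data type")
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("corrupt raster: only little-endian rasters supported")

    raster_path = _raster_path(header_path)
    raw = np.fromfile(raster_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError(
            "corrupt raster: file holds "
            f"{raw.size} values, header declares {samples * lines * bands}"
        )
    if interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"corrupt raster: unknown interleave '{interleave}'")
    calibrated = fields.get("calibrated", "false").strip().lower() == "true"
    return Hypercube(np.ascontiguousarray(data), wavelengths, calibrated=calibrated)


def _raster_path(header_path: str) -> str:
    root, ext = os.path.splitext(header_path)
    for candidate in (root + ".raw", root):
        if os.path.exists(candidate):
            return candidate
    raise FileNotFoundError(f"no raster file found for header {header_path}")


def write_envi(
    cube: Hypercube, path: str | os.PathLike, interleave: str = "bil"
) -> str:
    """Write ``cube`` as an ENVI header (``path``, normally ``*.hdr``) plus a
    companion ``.raw`` raster.  Inverse of :func:`read_envi`.
    """
    header_path = os.fspath(path)
    if not header_path.endswith(".hdr"):
        header_path += ".hdr"
    raster_path = os.path.splitext(header_path)[0] + ".raw"
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave '{interleave}'")

    data = cube.data
    dtype = data.dtype.newbyteorder("<") if data.dtype.byteorder == ">" else data.dtype
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype("<f8") if data.dtype.kind == "f" else np.dtype("<i4")
    arr = np.ascontiguousarray(data, dtype=dtype)

    lines, samples, bands = arr.shape
    if interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = arr
    else:
        flat = arr.transpose(2, 0, 1)

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"calibrated = {'true' if cube.calibrated else 'false'}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    np.ascontiguousarray(flat).tofile(raster_path)
    return header_path
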