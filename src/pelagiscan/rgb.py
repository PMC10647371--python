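"""Render RGB images from hypercubes by emulating an RGB camera.

The cube's Lc narrow bands are first averaged into the LRGB (default 33)
10-nm-wide channels of a reference camera by a projection matrix whose
column i puts weight 1/n_i on each hyperspectral band whose center falls in
camera interval i.  The camera's spectral sensitivity (an LRGB x 3 table of
relative R/G/B responses) then maps camera channels to linear RGB:

    (N*M x Lc) @ (Lc x LRGB) @ (LRGB x 3)  ->  reshape to N x M x 3

and the linear result is scaled to 8 bits.  A bundled 33-channel CSV with
Gaussian-shaped R/G/B response curves stands in for a measured camera table
(synthetic; any ``wavelength_nm,R,G,B`` CSV is accepted).
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypercube import Hypercube

__all__ = [
    "ProjectionMatrix",
    "SensitivityMatrix",
    "RGBImage",
    "build_projection_matrix",
    "load_sensitivity",
    "default_sensitivity",
    "default_camera_bands",
    "render_rgb",
    "save_png",
]

#: Default camera channel layout: 33 centers, 400-720 nm, 10 nm apart/wide.
DEFAULT_CAMERA_CENTERS = np.arange(400.0, 721.0, 10.0)
DEFAULT_CAMERA_WIDTH = 10.0


@dataclass
class ProjectionMatrix:
    """Lc x LRGB band-averaging weights; columns are convex combinations
    (or all-zero when no hyperspectral band falls in that camera interval)."""

    weights: np.ndarray
    camera_band_edges: np.ndarray  # LRGB + 1 interval edges, nm
    empty_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.camera_band_edges = np.asarray(self.camera_band_edges, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("projection weights must be 2-D (Lc, LRGB)")
        if self.camera_band_edges.size != self.weights.shape[1] + 1:
            raise ValueError("need LRGB + 1 camera band edges")
        if np.any(self.weights < 0):
            raise ValueError("projection weights must be nonnegative")
        sums = self.weights.sum(axis=0)
        ok = np.isclose(sums, 1.0) | np.isclose(sums, 0.0)
        if not ok.all():
            raise ValueError("each projection column must sum to 1 (or be empty)")

    @property
    def n_camera_bands(self) -> int:
        return self.weights.shape[1]


@dataclass
class SensitivityMatrix:
    """LRGB x 3 relative response of the emulated camera's R, G, B channels."""

    response: np.ndarray
    band_centers: np.ndarray  # LRGB, nm

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.response.ndim != 2 or self.response.shape[1] != 3:
            raise ValueError("sensitivity must be LRGB x 3")
        if self.response.shape[0] != self.band_centers.size:
            raise ValueError("sensitivity rows must match band centers")
        if self.response.shape[0] < 2:
            raise ValueError("sensitivity table needs at least 2 rows")
        if np.any(self.response < 0):
            raise ValueError("sensitivity responses must be nonnegative")
        if np.any(self.response.sum(axis=0) <= 0):
            raise ValueError("every RGB channel needs a nonzero response")

    @property
    def n_bands(self) -> int:
        return self.response.shape[0]


@dataclass
class RGBImage:
    """8-bit H x W x 3 image with provenance back to its source cube."""

    pixels: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RGB image must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("RGB values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def default_camera_bands() -> tuple[np.ndarray, float]:
    """(centers, width) of the default 33-channel camera layout."""
    return DEFAULT_CAMERA_CENTERS.copy(), DEFAULT_CAMERA_WIDTH


def build_projection_matrix(
    cube_wavelengths: np.ndarray,
    camera_centers: np.ndarray | None = None,
    camera_width: float = DEFAULT_CAMERA_WIDTH,
) -> ProjectionMatrix:
    """Averaging matrix from hyperspectral bands onto camera channels.

    Camera channel i spans the half-open interval
    ``[center_i - width/2, center_i + width/2)``; every hyperspectral band
    whose center lies inside gets weight ``1/n_i`` in column i.  Channels
    that catch no band get an all-zero column, reported in
    ``empty_columns``.
    """
    wl = np.asarray(cube_wavelengths, dtype=float)
    centers = (
        DEFAULT_CAMERA_CENTERS.copy()
        if camera_centers is None
        else np.asarray(camera_centers, dtype=float)
    )
    half = camera_width / 2.0
    edges = np.concatenate([centers - half, [centers[-1] + half]])
    weights = np.zeros((wl.size, centers.size))
    empty = []
    for i, c in enumerate(centers):
        inside = (wl >= c - half) & (wl < c + half)
        n_i = int(inside.sum())
        if n_i == 0:
            empty.append(i)
        else:
            weights[inside, i] = 1.0 / n_i
    if len(empty) == len(centers):
        raise ValueError("disjoint spectral ranges: no camera band overlaps the cube")
    return ProjectionMatrix(weights, edges, empty_columns=tuple(empty))


def load_sensitivity(path: str | os.PathLike) -> SensitivityMatrix:
    """Read a ``wavelength_nm,R,G,B`` CSV into a sensitivity matrix."""
    df = pd.read_csv(path)
    required = ["wavelength_nm", "R", "G", "B"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sensitivity CSV missing columns {missing}")
    return SensitivityMatrix(
        df[["R", "G", "B"]].to_numpy(float), df["wavelength_nm"].to_numpy(float)
    )


def default_sensitivity() -> SensitivityMatrix:
    """Bundled 33-channel Gaussian-response camera table (synthetic).

    Channel response peaks: B at 460 nm, G at 530 nm, R at 600 nm, all with
    a 30 nm standard deviation, tabulated at the default camera centers.
    """
    ref = importlib.resources.files("pelagiscan.data") / "canon_like_33band.csv"
    with importlib.resources.as_file(ref) as path:
        return load_sensitivity(path)


def _sensitivity_table() -> pd.DataFrame:
    """Generate the bundled synthetic sensitivity table (used to ship it)."""
    wl = DEFAULT_CAMERA_CENTERS
    def gauss(center: float, sigma: float = 30.0) -> np.ndarray:
        return np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "R": np.round(gauss(600.0), 6),
            "G": np.round(gauss(530.0), 6),
            "B": np.round(gauss(460.0), 6),
        }
    )


def render_rgb(
    cube: Hypercube,
    proj: ProjectionMatrix | None = None,
    sens: SensitivityMatrix | None = None,
    gain: float | None = None,
    provenance: str = "unknown",
) -> RGBImage:
    """Project the cube onto camera channels, apply the RGB sensitivity, and
    quantize to 8 bits.

    With ``gain=None`` the linear image is divided by its own maximum channel
    value (per-image max normalization) before scaling to 255; pass a fixed
    ``gain`` (counts-per-full-scale) for cross-image comparability.  Rounding
    is half-up.
    """
    if proj is None:
        proj = build_projection_matrix(cube.wavelengths)
    if sens is None:
        sens = default_sensitivity()
    if proj.weights.shape[0] != cube.n_bands:
        raise ValueError("projection/sensitivity incompatible: Lc mismatch")
    if proj.n_camera_bands != sens.n_bands:
        raise ValueError("projection/sensitivity incompatible: LRGB mismatch")
    n, m, lc = cube.shape
    flat = cube.data.reshape(n * m, lc)
    linear = flat @ proj.weights @ sens.response  # (N*M, 3)
    linear = linear.reshape(n, m, 3)
    scale = float(linear.max()) if gain is None else float(gain)
    if scale <= 0:
        pixels = np.zeros((n, m, 3), dtype=np.uint8)
    else:
        pixels = np.floor(np.clip(linear / scale, 0.0, 1.0) * 255.0 + 0.5)
        pixels = pixels.astype(np.uint8)
    return RGBImage(pixels, provenance=provenance)


def save_png(image: RGBImage, path: str | os.PathLike) -> str:
    """Write an :class:`RGBImage` to disk as PNG."""
    from PIL import Image

    Image.fromarray(image.pixels, mode="RGB").save(os.fspath(path))
    return os.fspath(path)
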