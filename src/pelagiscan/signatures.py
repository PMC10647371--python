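"""Spectral signatures: whole-body averages, random-RoI averages, resampling.

A fish's *spectral signature* is its average reflectance curve over a set of
pixels.  The whole-body signature averages every masked pixel per band; for
data augmentation, R regions of interest (RoIs) of P pixels each are drawn
uniformly at random (without replacement within an RoI, not necessarily
contiguous) inside the fish mask and averaged the same way, yielding an
R x Lc' signature array per sample after optional spectral resampling to
Lc' <= Lc bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import Hypercube
from .segmentation import FishMask

__all__ = [
    "SpectralSignature",
    "RoiSet",
    "SignatureSet",
    "whole_body_signature",
    "sample_rois",
    "roi_signatures",
    "resample_signature",
]


@dataclass
class SpectralSignature:
    """A reflectance curve: ``values[c]`` at ``wavelengths[c]`` nm."""

    values: np.ndarray
    wavelengths: np.ndarray
    provenance: tuple = ("unknown", "whole-body")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape or self.values.ndim != 1:
            raise ValueError("signature values and wavelengths must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RoiSet:
    """R random RoIs of P pixels each, all inside one fish mask."""

    rois: list[np.ndarray]  # each (P, 2) int array of (row, col)
    seed: int

    def __post_init__(self) -> None:
        self.rois = [np.asarray(r, dtype=int) for r in self.rois]
        for r in self.rois:
            if r.ndim != 2 or r.shape[1] != 2:
                raise ValueError("each RoI must be a (P, 2) coordinate array")
        sizes = {len(r) for r in self.rois}
        if len(sizes) > 1:
            raise ValueError("all RoIs must contain the same number of pixels")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def pixels_per_roi(self) -> int:
        return len(self.rois[0]) if self.rois else 0


@dataclass
class SignatureSet:
    """Stack of R RoI signatures (rows) over Lc' bands (columns)."""

    signatures: np.ndarray  # (R, Lc')
    wavelengths: np.ndarray
    sample_id: str = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.ndim != 2:
            raise ValueError("signature set must be 2-D (R, Lc')")
        if self.signatures.shape[1] != np.asarray(self.wavelengths).size:
            raise ValueError("signature set and wavelength axis must align")

    @property
    def shape(self) -> tuple[int, int]:
        return self.signatures.shape


def whole_body_signature(
    fish_cube: Hypercube,
    mask: FishMask | None = None,
    include_background: bool = False,
    sample_id: str = "unknown",
) -> SpectralSignature:
    """Per-band mean reflectance over the fish.

    By default only pixels inside ``mask`` contribute, so the board background
    retained in the crop does not contaminate the curve.  With
    ``include_background=True`` the mean runs over all N x M pixels of the
    crop (the literal all-pixel average).
    """
    if include_background or mask is None:
        values = fish_cube.data.reshape(-1, fish_cube.n_bands).mean(axis=0)
    else:
        if mask.mask.shape != fish_cube.shape[:2]:
            raise ValueError("inconsistent mask: shape differs from cube")
        sel = mask.mask
        if not sel.any():  # pragma: no cover - FishMask forbids this
            raise ValueError("empty mask")
        values = fish_cube.data[sel].mean(axis=0)
    return SpectralSignature(
        values, fish_cube.wavelengths.copy(), provenance=(sample_id, "whole-body")
    )


def sample_rois(mask: FishMask, R: int, P: int, seed: int) -> RoiSet:
    """Draw R RoIs of P distinct mask pixels each, uniformly at random.

    Pixels are drawn without replacement within an RoI; distinct RoIs may
    overlap.  Each RoI uses its own counter-derived substream of ``seed`` so
    the draw is reproducible and order-independent.
    """
    if R < 1 or P < 1:
        raise ValueError("R and P must be positive")
    coords = mask.pixels
    if P > len(coords):
        raise ValueError(
            f"RoI larger than fish: P={P} exceeds mask area {len(coords)}"
        )
    rois = []
    for r in range(R):
        rng = np.random.default_rng([seed, r])
        idx = rng.choice(len(coords), size=P, replace=False)
        rois.append(coords[idx])
    return RoiSet(rois, seed=seed)


def roi_signatures(
    fish_cube: Hypercube, rois: RoiSet, sample_id: str = "unknown"
) -> SignatureSet:
    """Average the spectrum of each RoI's pixels: row r = mean over its P
    pixels, per band.  Output shape (R, Lc)."""
    n, m = fish_cube.shape[:2]
    out = np.empty((rois.n_rois, fish_cube.n_bands))
    for r, coords in enumerate(rois.rois):
        if (
            coords[:, 0].min() < 0
            or coords[:, 1].min() < 0
            or coords[:, 0].max() >= n
            or coords[:, 1].max() >= m
        ):
            raise ValueError("inconsistent RoI: pixel outside cube bounds")
        out[r] = fish_cube.data[coords[:, 0], coords[:, 1], :].mean(axis=0)
    return SignatureSet(
        out, fish_cube.wavelengths.copy(), sample_id=sample_id, seed=rois.seed
    )


def resample_signature(
    sig: SpectralSignature, target_length: int
) -> SpectralSignature:
    """Linearly interpolate a signature onto ``target_length`` evenly spaced
    wavelengths spanning the original range (endpoints preserved).

    Only reduction is allowed: ``target_length`` must be in [2, Lc].
    """
    lc = len(sig)
    if target_length > lc:
        raise ValueError("upsampling not allowed")
    if target_length < 2:
        raise ValueError("target_length must be at least 2")
    if target_length == lc:
        return SpectralSignature(
            sig.values.copy(), sig.wavelengths.copy(), provenance=sig.provenance
        )
    new_wl = np.linspace(sig.wavelengths[0], sig.wavelengths[-1], target_length)
    new_vals = np.interp(new_wl, sig.wavelengths, sig.values)
    return SpectralSignature(new_vals, new_wl, provenance=sig.provenance)


def resample_signature_set(sset: SignatureSet, target_length: int) -> SignatureSet:
    """Row-wise :func:`resample_signature` for a whole signature set."""
    rows = [
        resample_signature(
            SpectralSignature(row, sset.wavelengths), target_length
        )
        for row in sset.signatures
    ]
    new_wl = rows[0].wavelengths
    return SignatureSet(
        np.stack([r.values for r in rows]),
        new_wl,
        sample_id=sset.sample_id,
        seed=sset.seed,
    )
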