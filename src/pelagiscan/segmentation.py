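"""Isolate individual fish from a calibrated multi-fish cube.

Two steps: (1) pick a high-contrast band and threshold it (Otsu) to get a
binary foreground; (2) label 8-connected components, keep those above a
minimum area, and carry each one's tight bounding box through every band of
the cube.  Fish are laid out on a uniform board without touching, so plain
connected components suffice — no instance splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .hypercube import Hypercube

__all__ = ["FishMask", "choose_contrast_band", "segment_fish", "crop_fish"]


@dataclass
class FishMask:
    """Binary mask for one fish plus its tight 0-based half-open bbox."""

    mask: np.ndarray  # bool (N, M)
    bbox: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max)
    source_band: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("empty mask")
        tight = _tight_bbox(self.mask)
        if tuple(self.bbox) != tight:
            raise ValueError(
                f"inconsistent mask: bbox {tuple(self.bbox)} is not tight {tight}"
            )

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def pixels(self) -> np.ndarray:
        """(area, 2) array of (row, col) coordinates, row-major order."""
        return np.argwhere(self.mask)


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def _otsu_between_class_variance(slice2d: np.ndarray) -> float:
    """Maximum between-class variance of a 2-D slice over all thresholds.

    Computed from a 256-bin histogram, the same criterion Otsu's method
    maximises; 0 for a constant slice.
    """
    x = slice2d.ravel()
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    hist, edges = np.histogram(x, bins=256, range=(lo, hi))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    m = np.cumsum(p * centers)
    mt = m[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return 0.0
    num = (mt * w0[valid] - m[valid]) ** 2
    return float(np.max(num / (w0[valid] * w1[valid])))


def choose_contrast_band(cube: Hypercube) -> int:
    """Index of the band whose slice maximises Otsu between-class variance.

    Deterministic; ties resolved to the lowest band index.  Raises
    ``ValueError("no contrast")`` when every band is constant.
    """
    variances = [
        _otsu_between_class_variance(cube.band(c)) for c in range(cube.n_bands)
    ]
    best = int(np.argmax(variances))  # argmax takes the first maximum
    if variances[best] <= 0.0:
        raise ValueError("no contrast: every band is constant")
    return best


def segment_fish(
    cube: Hypercube,
    band: int | None = None,
    min_area: int = 50,
    closing: bool = True,
) -> list[FishMask]:
    """Threshold one band and split the foreground into per-fish masks.

    Otsu's threshold is applied to the band slice; polarity is chosen so the
    foreground (fish) is the minority class.  A single 3x3 morphological
    closing bridges gaps from scale glint before 8-connected labeling.
    Components smaller than ``min_area`` pixels are dropped.  Masks are
    returned ordered by leftmost column (then topmost row).
    """
    from skimage.filters import threshold_otsu

    if band is None:
        band = choose_contrast_band(cube)
    if not 0 <= band < cube.n_bands:
        raise ValueError(f"band {band} out of range")
    slice2d = cube.band(band).astype(float)
    if slice2d.max() <= slice2d.min():
        raise ValueError("no contrast: band slice is constant")
    thresh = threshold_otsu(slice2d)
    fg = slice2d > thresh
    # fish occupy less of the frame than the board
    if fg.sum() > fg.size / 2:
        fg = ~fg
    if closing:
        fg = morphology.closing(fg, footprint=np.ones((3, 3), dtype=bool))
    labels = measure.label(fg, connectivity=2)  # 8-connectivity
    masks: list[FishMask] = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() < min_area:
            continue
        bbox = _tight_bbox(m)
        masks.append(FishMask(m, bbox, source_band=band))
    masks.sort(key=lambda f: (f.bbox[2], f.bbox[0]))
    return masks


def crop_fish(cube: Hypercube, fish: FishMask) -> tuple[Hypercube, FishMask]:
    """Crop the fish's bounding box out of every band of the cube.

    Returns the sub-cube over the bbox window (background pixels inside the
    box are retained) and the mask cropped to the same window.
    """
    r0, r1, c0, c1 = fish.bbox
    if fish.mask.shape != cube.shape[:2]:
        raise ValueError("inconsistent mask: shape differs from cube")
    if r0 < 0 or c0 < 0 or r1 > cube.n_lines or c1 > cube.n_pixels:
        raise ValueError("inconsistent mask: bbox outside cube bounds")
    sub = Hypercube(
        cube.data[r0:r1, c0:c1, :].copy(),
        cube.wavelengths.copy(),
        calibrated=cube.calibrated,
    )
    sub_mask = fish.mask[r0:r1, c0:c1].copy()
    cropped = FishMask(sub_mask, _tight_bbox(sub_mask), source_band=fish.source_band)
    return sub, cropped
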