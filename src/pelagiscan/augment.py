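"""Dataset assembly: image standardization, geometric augmentation, balancing.

Each labeled sample pairs a standardized RGB crop (fish on a white
background, resized to a square frame, 256x256 by default) with a spectral
signature of reduced length Lc'.  Classes are balanced to a common target
count by cycling the provided (original) samples: every synthetic copy gets
a fresh geometric transform of the image *and* a fresh random-RoI signature
drawn from the same source fish cube, so the two input streams are augmented
jointly but independently.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .hypercube import Hypercube
from .rgb import RGBImage
from .segmentation import FishMask
from .signatures import (
    SpectralSignature,
    roi_signatures,
    resample_signature,
    sample_rois,
)

__all__ = [
    "Sample",
    "SourceFish",
    "Dataset",
    "AugmentRanges",
    "standardize_image",
    "augment_image",
    "balance_dataset",
]

WHITE = 255


@dataclass
class AugmentRanges:
    """Geometric augmentation ranges: silhouette-preserving by default."""

    rotation_deg: float = 25.0  # uniform in +/- this
    translate_frac: float = 0.10  # uniform in +/- this, per axis
    flip_horizontal: bool = True  # applied with p = 0.5
    flip_vertical: bool = True  # applied with p = 0.5


@dataclass
class Sample:
    """One labeled training example: image + signature + provenance."""

    id: str
    label: str
    image: RGBImage
    signature: SpectralSignature
    provenance: dict = field(default_factory=dict)


@dataclass
class SourceFish:
    """A segmented physical fish kept around for fresh augmentation draws."""

    source_id: str
    label: str
    cube: Hypercube  # cropped, calibrated
    mask: FishMask  # cropped to the same window
    image: RGBImage  # standardized


@dataclass
class Dataset:
    """A list of samples plus the registry of source fish they came from."""

    samples: list[Sample]
    classes: list[str]
    sources: dict[str, SourceFish] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        unknown = {s.label for s in self.samples} - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside class set: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def images(self) -> np.ndarray:
        """(n, H, W, 3) uint8 stack."""
        return np.stack([s.image.pixels for s in self.samples])

    def signatures(self) -> np.ndarray:
        """(n, Lc') float matrix."""
        return np.stack([s.signature.values for s in self.samples])

    def source_ids(self) -> np.ndarray:
        return np.array(
            [s.provenance.get("source", s.id) for s in self.samples]
        )

    def subset(self, indices) -> "Dataset":
        picked = [self.samples[i] for i in np.asarray(indices, dtype=int)]
        return Dataset(picked, list(self.classes), self.sources)


def standardize_image(
    img: RGBImage, mask: FishMask | None = None, size: int = 256
) -> RGBImage:
    """White out the background and resize to ``size`` x ``size``.

    Non-mask pixels become (255, 255, 255) before a bilinear resize; the
    aspect ratio is *not* preserved (a 1070x260 crop maps onto the full
    square frame).  Pass ``mask=None`` for an already background-free image.
    """
    pixels = img.pixels
    if pixels.size == 0:
        raise ValueError("empty image")
    work = pixels.astype(float)
    if mask is not None:
        if mask.mask.shape != pixels.shape[:2]:
            raise ValueError("mask shape differs from image")
        work[~mask.mask] = WHITE
    if work.shape[:2] != (size, size):
        work = sktransform.resize(
            work, (size, size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    out = np.clip(np.floor(work + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(out, provenance=img.provenance)


def augment_image(
    img: RGBImage, seed: int, ranges: AugmentRanges | None = None
) -> RGBImage:
    """Randomly flip, rotate and translate a standardized image.

    Applied in that order; regions exposed by the transform are filled
    white.  Bilinear interpolation throughout; fully determined by ``seed``.
    """
    if ranges is None:
        ranges = AugmentRanges()
    rng = np.random.default_rng(seed)
    work = img.pixels.astype(float) / 255.0
    do_h = ranges.flip_horizontal and rng.random() < 0.5
    do_v = ranges.flip_vertical and rng.random() < 0.5
    angle = rng.uniform(-ranges.rotation_deg, ranges.rotation_deg)
    h, w = work.shape[:2]
    ty = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * h
    tx = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * w
    if do_h:
        work = work[:, ::-1, :]
    if do_v:
        work = work[::-1, :, :]
    if angle != 0.0:
        work = sktransform.rotate(
            work, angle, resize=False, order=1, mode="constant", cval=1.0
        )
    if tx != 0.0 or ty != 0.0:
        shift = sktransform.AffineTransform(translation=(-tx, -ty))
        work = sktransform.warp(
            work, shift.inverse, order=1, mode="constant", cval=1.0
        )
    out = np.clip(np.floor(work * 255.0 + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(out, provenance=img.provenance)


def balance_dataset(
    originals: Dataset,
    target_per_class: int,
    seed: int,
    ranges: AugmentRanges | None = None,
    roi_pixels: int = 256,
    n_rois: int = 1,
) -> Dataset:
    """Grow every class to exactly ``target_per_class`` samples.

    Originals are kept verbatim.  The ``target - n_originals`` synthetic
    samples per class cycle through that class's originals; each gets a
    fresh :func:`augment_image` transform and a fresh random-RoI signature
    (``n_rois`` RoIs of ``roi_pixels`` pixels, averaged) drawn from the
    source fish registered in ``originals.sources``.  Signature length
    matches the original sample's Lc'.
    """
    counts = originals.class_counts
    for cls, n in counts.items():
        if n == 0:
            raise ValueError(f"cannot augment empty class '{cls}'")
        if n > target_per_class:
            raise ValueError(
                f"class '{cls}' already exceeds target ({n} > {target_per_class})"
            )
    by_class: dict[str, list[Sample]] = {c: [] for c in originals.classes}
    for s in originals.samples:
        by_class[s.label].append(s)

    out = list(originals.samples)
    master = np.random.default_rng(seed)
    for cls in originals.classes:
        pool = by_class[cls]
        needed = target_per_class - len(pool)
        for i in range(needed):
            base = pool[i % len(pool)]
            aug_seed = int(master.integers(0, 2**31 - 1))
            roi_seed = int(master.integers(0, 2**31 - 1))
            image = augment_image(base.image, aug_seed, ranges)
            signature = _fresh_signature(
                originals, base, roi_seed, roi_pixels, n_rois
            )
            out.append(
                Sample(
                    id=f"{base.id}/aug{i:04d}",
                    label=cls,
                    image=image,
                    signature=signature,
                    provenance={
                        **base.provenance,
                        "augmented_from": base.id,
                        "aug_seed": aug_seed,
                        "roi_seed": roi_seed,
                    },
                )
            )
    return Dataset(out, list(originals.classes), originals.sources)


def _fresh_signature(
    ds: Dataset, base: Sample, roi_seed: int, roi_pixels: int, n_rois: int
) -> SpectralSignature:
    source_id = base.provenance.get("source")
    source = ds.sources.get(source_id) if source_id else None
    if source is None:
        # No cube available (e.g. a dataset loaded without sources): reuse
        # the base curve unchanged.
        return SpectralSignature(
            base.signature.values.copy(),
            base.signature.wavelengths.copy(),
            provenance=(base.id, f"reused-{roi_seed}"),
        )
    p = min(roi_pixels, source.mask.area)
    rois = sample_rois(source.mask, R=n_rois, P=p, seed=roi_seed)
    sset = roi_signatures(source.cube, rois, sample_id=source.source_id)
    sig = SpectralSignature(
        sset.signatures.mean(axis=0),
        sset.wavelengths,
        provenance=(source.source_id, f"roi-{roi_seed}"),
    )
    return resample_signature(sig, len(base.signature))


# ---------------------------------------------------------------------------
# Manifest I/O (PNG images + CSV signatures + JSON manifest)
# ---------------------------------------------------------------------------

def save_dataset(ds: Dataset, outdir: str | os.PathLike) -> str:
    from .rgb import save_png

    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "images"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "signatures"), exist_ok=True)
    entries = []
    for k, s in enumerate(ds.samples):
        img_rel = f"images/{k:05d}.png"
        sig_rel = f"signatures/{k:05d}.csv"
        save_png(s.image, os.path.join(outdir, img_rel))
        np.savetxt(
            os.path.join(outdir, sig_rel),
            np.column_stack([s.signature.wavelengths, s.signature.values]),
            delimiter=",",
            header="wavelength_nm,value",
            comments="",
        )
        entries.append(
            {
                "id": s.id,
                "label": s.label,
                "image_path": img_rel,
                "signature_path": sig_rel,
                "provenance": {k2: _jsonable(v) for k2, v in s.provenance.items()},
            }
        )
    manifest = {"classes": list(ds.classes), "samples": entries}
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def load_dataset(outdir: str | os.PathLike) -> Dataset:
    from PIL import Image

    outdir = os.fspath(outdir)
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    samples = []
    for e in manifest["samples"]:
        pixels = np.asarray(Image.open(os.path.join(outdir, e["image_path"])))
        table = np.loadtxt(
            os.path.join(outdir, e["signature_path"]), delimiter=",", skiprows=1
        )
        samples.append(
            Sample(
                id=e["id"],
                label=e["label"],
                image=RGBImage(pixels, provenance=e["id"]),
                signature=SpectralSignature(table[:, 1], table[:, 0]),
                provenance=e.get("provenance", {}),
            )
        )
    return Dataset(samples, manifest["classes"])


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
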