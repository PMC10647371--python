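"""Synthetic VIS-NIR scenes of fish-shaped objects for end-to-end testing.

Emulates what the bench-top line-scan setup produces: several fish laid out
without touching on a uniform board, imaged over 400-1000 nm.  Each of the
five species has (a) a smooth reflectance curve — a shared gentle baseline
plus species-specific Gaussian peaks and valleys whose contrast is scaled by
a single difficulty knob ``delta`` in [0, 1] — and (b) an elliptical,
tail-tapered silhouette.  Two species have distinctive silhouettes while
three share one, so shape alone separates the classes only partially while
spectra (at ``delta`` = 1) separate them easily.  Raw counts are reflectance
times a smooth reference-frame illumination, so white-reference calibration
inverts the construction exactly when noise is off; realism comes from
multiplicative lognormal pixel noise and a smooth low-frequency texture gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import Dataset, Sample, SourceFish, balance_dataset
from .hypercube import Hypercube, ReferenceFrame, calibrate_reflectance, nominal_wavelengths
from .rgb import build_projection_matrix, default_sensitivity, render_rgb
from .segmentation import FishMask, choose_contrast_band, crop_fish, segment_fish
from .signatures import SpectralSignature, resample_signature, roi_signatures, sample_rois
from .augment import standardize_image

__all__ = [
    "SpectralBump",
    "SpeciesTemplate",
    "SceneSpec",
    "default_templates",
    "generate_scene",
    "generate_experiment",
]


@dataclass(frozen=True)
class SpectralBump:
    """One Gaussian feature of a reflectance curve (sign via amplitude)."""

    center_nm: float
    width_nm: float
    amplitude: float


@dataclass(frozen=True)
class SpeciesTemplate:
    """Spectral curve + silhouette parameters for one synthetic species."""

    name: str
    baseline: float = 0.40
    slope: float = 0.05  # linear rise of the shared base over 400-1000 nm
    bumps: tuple[SpectralBump, ...] = ()
    length_px: float = 110.0
    aspect: float = 5.5  # length / width
    taper: float = 0.55  # tail-ward width reduction, 0..1
    size_jitter: float = 0.05  # relative s.d. of per-fish length

    def base_curve(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.baseline + self.slope * (wl - 400.0) / 600.0

    def deviation(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for b in self.bumps:
            out += b.amplitude * np.exp(-0.5 * ((wl - b.center_nm) / b.width_nm) ** 2)
        return out

    def reflectance(self, wavelengths: np.ndarray, delta: float = 1.0) -> np.ndarray:
        """Curve at difficulty ``delta``: base + delta * species deviation."""
        return self.base_curve(wavelengths) + delta * self.deviation(wavelengths)


def default_templates() -> list[SpeciesTemplate]:
    """Five named templates emulating the studied pelagic species.

    ``merluza`` carries a pronounced peak near 600 nm (its real counterpart
    is the most spectrally distinctive there).  ``anchoveta`` and ``merluza``
    get distinctive silhouettes; ``mote``, ``pampanito`` and ``sardina``
    share one silhouette and place their spectral features beyond 720 nm —
    outside the emulated RGB camera's range — so neither shape nor color
    separates those three and only the VIS-NIR spectrum does.
    """
    return [
        SpeciesTemplate(
            name="anchoveta",
            bumps=(SpectralBump(450, 40, -0.12), SpectralBump(850, 60, 0.10)),
            length_px=90.0, aspect=4.8,
        ),
        SpeciesTemplate(
            name="merluza",
            bumps=(SpectralBump(600, 35, 0.18), SpectralBump(900, 80, -0.08)),
            length_px=140.0, aspect=3.0,
        ),
        SpeciesTemplate(
            name="mote",
            bumps=(SpectralBump(800, 45, 0.12), SpectralBump(950, 60, -0.08)),
        ),
        SpeciesTemplate(
            name="pampanito",
            bumps=(SpectralBump(800, 45, -0.10), SpectralBump(930, 50, 0.10)),
        ),
        SpeciesTemplate(
            name="sardina",
            bumps=(SpectralBump(760, 35, -0.08), SpectralBump(870, 40, 0.12)),
        ),
    ]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    species_counts: dict = field(default_factory=dict)  # name -> count
    shape: tuple[int, int] = (400, 600)  # (scan lines, cross-track pixels)
    n_bands: int = 281
    board_reflectance: float = 0.15
    noise_sigma: float = 0.02  # multiplicative lognormal s.d.
    texture: bool = True
    texture_amplitude: float = 0.2  # gain field in [1-a, 1+a]
    delta: float = 1.0  # inter-species spectral separation, 0..1
    reference_counts: float = 3000.0
    max_placement_tries: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if any(v < 0 for v in self.species_counts.values()):
            raise ValueError("species counts must be nonnegative")


def _silhouette_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length: float,
    width: float,
    taper: float,
    angle_rad: float,
) -> np.ndarray:
    """Rasterize a tail-tapered ellipse at an arbitrary pose."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = rr - center[0]
    dx = cc - center[1]
    # into fish frame: u along the body, v across
    u = dx * np.cos(angle_rad) + dy * np.sin(angle_rad)
    v = -dx * np.sin(angle_rad) + dy * np.cos(angle_rad)
    half_l = length / 2.0
    with np.errstate(invalid="ignore"):
        ellipse = np.sqrt(np.clip(1.0 - (u / half_l) ** 2, 0.0, 1.0))
    # width shrinks toward the tail (u -> +half_l)
    taper_factor = 1.0 - taper * (u / half_l + 1.0) / 2.0
    half_w = (width / 2.0) * ellipse * np.clip(taper_factor, 0.0, 1.0)
    return (np.abs(u) <= half_l) & (np.abs(v) <= half_w) & (half_w > 0)


def _illumination(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth positive halogen-like spectral profile."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.55 + 0.45 * np.exp(-0.5 * ((wl - 700.0) / 250.0) ** 2)


def _texture_field(shape: tuple[int, int], amplitude: float, rng) -> np.ndarray:
    """Smooth low-frequency gain field in [1 - amplitude, 1 + amplitude]."""
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=min(shape) / 8.0)
    span = np.abs(smooth).max()
    if span == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / span


def generate_scene(
    spec: SceneSpec, templates: list[SpeciesTemplate] | None = None
) -> tuple[Hypercube, ReferenceFrame, list[tuple[FishMask, str]]]:
    """Build one raw scene: cube of digital counts, its white-reference
    frame, and exact ground-truth (mask, species) pairs."""
    if templates is None:
        templates = default_templates()
    by_name = {t.name: t for t in templates}
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    wl = nominal_wavelengths(spec.n_bands)

    reflectance = np.full((rows, cols, spec.n_bands), spec.board_reflectance)
    occupied = np.zeros((rows, cols), dtype=bool)
    truth: list[tuple[FishMask, str]] = []

    order = [
        name
        for name, count in spec.species_counts.items()
        for _ in range(count)
    ]
    for name in order:
        t = by_name[name]
        placed = False
        for _ in range(spec.max_placement_tries):
            length = t.length_px * np.exp(rng.normal(0.0, t.size_jitter))
            width = length / t.aspect
            margin = length / 2.0 + 3
            if 2 * margin >= min(rows, cols):
                raise ValueError("cannot place fish: scene too small")
            center = (
                rng.uniform(margin, rows - margin),
                rng.uniform(margin, cols - margin),
            )
            angle = np.deg2rad(rng.uniform(-20.0, 20.0))
            mask = _silhouette_mask(spec.shape, center, length, width, t.taper, angle)
            if not mask.any():
                continue
            # a 3-pixel halo around the bounding box keeps fish separated
            r0, r1, c0, c1 = _bbox(mask)
            r0, c0 = max(0, r0 - 3), max(0, c0 - 3)
            r1, c1 = min(rows, r1 + 3), min(cols, c1 + 3)
            if occupied[r0:r1, c0:c1].any():
                continue
            occupied[r0:r1, c0:c1] = True
            curve = t.reflectance(wl, spec.delta)
            reflectance[mask] = curve
            bbox_mask = FishMask(mask, _bbox(mask))
            truth.append((bbox_mask, name))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot place fish '{name}' without overlap after "
                f"{spec.max_placement_tries} tries"
            )

    if spec.texture:
        gain = _texture_field(spec.shape, spec.texture_amplitude, rng)
        reflectance = reflectance * gain[:, :, np.newaxis]
    if spec.noise_sigma > 0:
        noise = np.exp(
            rng.normal(0.0, spec.noise_sigma, size=reflectance.shape)
        )
        reflectance = reflectance * noise

    vignette = 1.0 - 0.1 * (np.linspace(-1, 1, cols)) ** 2
    ref_values = spec.reference_counts * np.outer(vignette, _illumination(wl))
    reference = ReferenceFrame(ref_values, wl)
    raw = Hypercube(reflectance * ref_values[np.newaxis, :, :], wl, calibrated=False)
    return raw, reference, truth


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def generate_experiment(
    n_per_class: int,
    seed: int = 0,
    templates: list[SpeciesTemplate] | None = None,
    originals_per_class: int | None = None,
    scene_shape: tuple[int, int] = (400, 600),
    n_bands: int = 281,
    delta: float = 1.0,
    noise_sigma: float = 0.02,
    texture: bool = True,
    fish_scale: float = 1.0,
    image_size: int = 256,
    lc_prime: int = 200,
    roi_pixels: int = 256,
) -> Dataset:
    """Run the full chain scenes -> calibrate -> segment -> signatures + RGB
    -> standardize -> balance, producing a labeled, balanced dataset.

    Each scene holds one fish of every species; ``originals_per_class``
    scenes are generated (default: min(10, n_per_class)), then classes are
    balanced up to ``n_per_class`` with augmented copies.  ``fish_scale``
    shrinks silhouettes (with the scene) for fast desk-scale runs.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    if templates is None:
        templates = default_templates()
    if fish_scale != 1.0:
        templates = [
            replace(t, length_px=t.length_px * fish_scale) for t in templates
        ]
    names = [t.name for t in templates]
    if originals_per_class is None:
        originals_per_class = min(10, n_per_class)
    originals_per_class = min(originals_per_class, n_per_class)

    master = np.random.default_rng(seed)
    samples: list[Sample] = []
    sources: dict[str, SourceFish] = {}
    proj_cache = {}
    sens = default_sensitivity()

    for scene_idx in range(originals_per_class):
        truth = None
        for attempt in range(5):
            scene_seed = int(master.integers(0, 2**31 - 1))
            spec = SceneSpec(
                species_counts={n: 1 for n in names},
                shape=scene_shape,
                n_bands=n_bands,
                delta=delta,
                noise_sigma=noise_sigma,
                texture=texture,
                seed=scene_seed,
            )
            try:
                raw, reference, truth = generate_scene(spec, templates)
                break
            except ValueError:
                truth = None
        if truth is None:
            raise ValueError("could not generate a scene without overlap")

        cal = calibrate_reflectance(raw, reference)
        band = choose_contrast_band(cal)
        min_area = max(20, int(0.2 * min(t.length_px for t in templates)))
        masks = segment_fish(cal, band, min_area=min_area)
        for k, m in enumerate(masks):
            best = max(truth, key=lambda tv: _jaccard(m.mask, tv[0].mask))
            if _jaccard(m.mask, best[0].mask) < 0.5:
                continue
            label = best[1]
            source_id = f"scene{scene_idx:03d}/fish{k}"
            fish_cube, fish_mask = crop_fish(cal, m)
            if fish_mask.area < 4:
                continue
            if n_bands not in proj_cache:
                proj_cache[n_bands] = build_projection_matrix(fish_cube.wavelengths)
            rgb = render_rgb(
                fish_cube, proj_cache[n_bands], sens, provenance=source_id
            )
            std = standardize_image(rgb, fish_mask, size=image_size)
            roi_seed = int(master.integers(0, 2**31 - 1))
            p = min(roi_pixels, fish_mask.area)
            rois = sample_rois(fish_mask, R=1, P=p, seed=roi_seed)
            sset = roi_signatures(fish_cube, rois, sample_id=source_id)
            sig = resample_signature(
                SpectralSignature(
                    sset.signatures[0], sset.wavelengths, provenance=(source_id, roi_seed)
                ),
                min(lc_prime, n_bands),
            )
            sources[source_id] = SourceFish(source_id, label, fish_cube, fish_mask, std)
            samples.append(
                Sample(
                    id=source_id,
                    label=label,
                    image=std,
                    signature=sig,
                    provenance={
                        "source": source_id,
                        "scene": scene_idx,
                        "roi_seed": roi_seed,
                    },
                )
            )

    originals = Dataset(samples, names, sources)
    counts = originals.class_counts
    if min(counts.values()) == 0:
        missing = [c for c, n in counts.items() if n == 0]
        raise ValueError(f"segmentation recovered no fish for classes {missing}")
    balance_seed = int(master.integers(0, 2**31 - 1))
    return balance_dataset(
        originals, n_per_class, seed=balance_seed, roi_pixels=roi_pixels
    )
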