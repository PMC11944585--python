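"""Seeded generator of artificial culture-plate photographs.

Fungal colonies grown on solid media under standardized conditions develop
species-specific pigment palettes — the basis of chromogenic profiling.  This
module renders parametric stand-ins for top-down Petri-dish photographs: a
bright circular plate (agar surface plus rim) on a light or dark benchtop
background, carrying a colony whose colour grades radially from a centre tone
to a peripheral ring tone, with seeded low-frequency mottling and per-pixel
sensor noise.  Every image is emitted together with its ground-truth plate
circle so that the detector and classifier can be validated against known
geometry and known class palettes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SpeciesColorProfile",
    "PlateSpec",
    "DatasetManifest",
    "ManifestRow",
    "make_profile_set",
    "render_plate",
    "generate_dataset",
    "blended_colony_mean",
]

# Rendering constants shared by all plates.
LIGHT_BACKGROUND = 205.0
DARK_BACKGROUND = 40.0
AGAR_RGB = (196.0, 183.0, 150.0)  # pale Sabouraud-agar tone
RIM_RGB = (245.0, 245.0, 245.0)  # bright plastic rim
RIM_WIDTH = 3.0  # px
COLONY_FRACTION = 0.88  # colony radius as a fraction of plate radius
DEFAULT_CANVAS = (512, 512)
MIN_PROFILE_DISTANCE = 60.0  # RGB-space floor between species palettes


@dataclass(frozen=True)
class SpeciesColorProfile:
    """Pigment palette of one species: centre and ring tones plus mottle."""

    name: str
    center_rgb: tuple[float, float, float]
    ring_rgb: tuple[float, float, float]
    color_sd: float = 12.0
    texture_scale: float = 24.0

    def __post_init__(self) -> None:
        for rgb in (self.center_rgb, self.ring_rgb):
            if not all(0.0 <= c <= 255.0 for c in rgb):
                raise ValueError(f"channel means must lie in [0, 255], got {rgb}")
        if self.color_sd < 0:
            raise ValueError("color_sd must be >= 0")
        if self.texture_scale < 1:
            raise ValueError("texture_scale must be >= 1 px")


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and imaging conditions for one rendered plate."""

    center_xy: tuple[float, float]
    radius: float
    background: Literal["light", "dark"] = "light"
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("plate radius must be positive")
        if self.background not in ("light", "dark"):
            raise ValueError("background must be 'light' or 'dark'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def fits(self, canvas: tuple[int, int]) -> bool:
        h, w = canvas
        cx, cy = self.center_xy
        r = self.radius
        return cx - r >= 0 and cy - r >= 0 and cx + r <= w - 1 and cy + r <= h - 1


@dataclass(frozen=True)
class ManifestRow:
    path: str
    label: str
    cx: float
    cy: float
    r: float
    seed: int


@dataclass
class DatasetManifest:
    """One row per emitted image, with ground-truth circle and per-image seed."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "cx", "cy", "r", "seed"])
            for row in self.rows:
                writer.writerow([row.path, row.label, row.cx, row.cy, row.r, row.seed])

    @classmethod
    def read_csv(cls, path: str | Path) -> "DatasetManifest":
        manifest = cls()
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                manifest.rows.append(
                    ManifestRow(
                        path=rec["path"],
                        label=rec["label"],
                        cx=float(rec["cx"]),
                        cy=float(rec["cy"]),
                        r=float(rec["r"]),
                        seed=int(rec["seed"]),
                    )
                )
        return manifest


def make_profile_set(
    n_species: int,
    seed: int,
    min_distance: float = MIN_PROFILE_DISTANCE,
) -> list[SpeciesColorProfile]:
    """Draw ``n_species`` palettes with pairwise-distinct centre colours.

    Centre colours are rejection-sampled in RGB space until every pair is at
    least ``min_distance`` apart (Euclidean), which guarantees the classes are
    separable by colour alone.  Ring tones are a darker, desaturated version
    of the centre tone, mimicking the concentric zoning of *Aspergillus* and
    *Penicillium* colonies.  Deterministic for a fixed seed.
    """
    if not 2 <= n_species <= 26:
        raise ValueError(f"n_species must be in [2, 26], got {n_species}")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_species:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(
                f"could not place {n_species} palettes at distance {min_distance}"
            )
        cand = rng.uniform(30.0, 235.0, size=3)
        if all(np.linalg.norm(cand - c) >= min_distance for c in centers):
            centers.append(cand)
    profiles = []
    for i, c in enumerate(centers):
        # ring: colony periphery is paler and greyer than the pigmented centre
        towards_grey = 0.55 * c + 0.45 * np.array([170.0, 170.0, 170.0])
        ring = np.clip(towards_grey + rng.normal(0, 6, size=3), 0, 255)
        profiles.append(
            SpeciesColorProfile(
                name=f"species_{chr(ord('A') + i)}",
                center_rgb=tuple(float(v) for v in c),
                ring_rgb=tuple(float(v) for v in ring),
                color_sd=12.0,
                texture_scale=24.0,
            )
        )
    return profiles


def blended_colony_mean(profile: SpeciesColorProfile) -> np.ndarray:
    """Expected mean colour over the colony disc, ignoring mottle and noise.

    The rendered colony blends centre→ring linearly in normalised radius t,
    so the area-weighted disc mean is ∫0..1 2t[(1−t)·centre + t·ring] dt
    = centre/3 + 2·ring/3.
    """
    c = np.asarray(profile.center_rgb, dtype=float)
    r = np.asarray(profile.ring_rgb, dtype=float)
    return c / 3.0 + 2.0 * r / 3.0


def _mottle_field(
    shape: tuple[int, int], scale: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian random field with correlation length ~scale px."""
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale)
    s = smooth.std()
    if s < 1e-12:
        return np.zeros(shape)
    return smooth * (sd / s)


def render_plate(
    profile: SpeciesColorProfile,
    spec: PlateSpec,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    seed: int = 0,
) -> tuple[np.ndarray, PlateSpec]:
    """Render one plate photograph; returns (HxWx3 uint8 image, ground truth).

    Layout from the centre outwards: colony disc (radial centre→ring colour
    gradient plus seeded mottling), an agar annulus, a thin bright plastic
    rim at the plate radius, then the background tone.  Per-pixel Gaussian
    sensor noise (sd = ``spec.noise_sd``) is added everywhere and the result
    clipped to [0, 255].  The pixel at the exact centre equals ``center_rgb``
    when noise and mottle are disabled.
    """
    if not spec.fits(canvas):
        raise ValueError(
            f"plate circle (center={spec.center_xy}, r={spec.radius}) "
            f"does not fit canvas {canvas}"
        )
    h, w = canvas
    rng = np.random.default_rng(seed)
    cx, cy = spec.center_xy
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)

    bg = LIGHT_BACKGROUND if spec.background == "light" else DARK_BACKGROUND
    img = np.full((h, w, 3), bg, dtype=np.float64)

    inside_plate = dist <= spec.radius
    for ch in range(3):
        img[..., ch][inside_plate] = AGAR_RGB[ch]

    rim = inside_plate & (dist >= spec.radius - RIM_WIDTH)
    for ch in range(3):
        img[..., ch][rim] = RIM_RGB[ch]

    colony_r = COLONY_FRACTION * spec.radius
    colony = dist <= colony_r
    t = np.clip(dist / colony_r, 0.0, 1.0)
    center = np.asarray(profile.center_rgb)
    ring = np.asarray(profile.ring_rgb)
    for ch in range(3):
        grad = (1.0 - t) * center[ch] + t * ring[ch]
        mottle = _mottle_field((h, w), profile.texture_scale, profile.color_sd, rng)
        img[..., ch][colony] = (grad + mottle)[colony]

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    return np.clip(np.round(img), 0, 255).astype(np.uint8), spec


def generate_dataset(
    profiles: Sequence[SpeciesColorProfile],
    n_per_species: int,
    out_dir: str | Path,
    seed: int,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    radius_range: tuple[float, float] = (80.0, 200.0),
    noise_sd: float = 6.0,
    image_format: str = "png",
) -> DatasetManifest:
    """Emit a labelled image tree (one subdirectory per species) plus manifest.

    Each image gets a randomized plate position, radius, and light/dark
    background, drawn reproducibly from ``seed``; colony size additionally
    varies through the plate radius, a crude proxy for developmental stage.
    The manifest (``manifest.csv`` in ``out_dir``) records the ground-truth
    circle and the per-image render seed.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = canvas
    rng = np.random.default_rng(seed)
    manifest = DatasetManifest()
    for profile in profiles:
        cls_dir = out_dir / profile.name
        cls_dir.mkdir(exist_ok=True)
        for i in range(n_per_species):
            img_seed = int(rng.integers(0, 2**31 - 1))
            r = float(rng.uniform(*radius_range))
            margin = r + 2.0
            cx = float(rng.uniform(margin, w - 1 - margin))
            cy = float(rng.uniform(margin, h - 1 - margin))
            background = "light" if rng.random() < 0.5 else "dark"
            spec = PlateSpec(
                center_xy=(cx, cy), radius=r, background=background, noise_sd=noise_sd
            )
            img, _ = render_plate(profile, spec, canvas=canvas, seed=img_seed)
            fname = cls_dir / f"{profile.name}_{i:03d}.{image_format}"
            Image.fromarray(img).save(fname)
            manifest.rows.append(
                ManifestRow(
                    path=str(fname.relative_to(out_dir)),
                    label=profile.name,
                    cx=cx,
                    cy=cy,
                    r=r,
                    seed=img_seed,
                )
            )
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest
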