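"""Synthetic ultrasound-like face phantoms and simulated manual raters.

The generator emulates axis-aligned Cartesian exports of fetal-face 3D
ultrasound sweeps: a half-ellipsoid "head" facing +y with a nasal protrusion
and two orbital indentations, surrounded by an anechoic amniotic-fluid band
and brighter maternal tissue, everything degraded by smoothed multiplicative
speckle.  Per-subject anatomy is a smooth random deformation of the template,
so a population of seeds plays the role of a cohort of fetuses.

All randomness flows from explicit integer seeds; identical parameters give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .bank import AtlasBank, AtlasEntry
from .core import SegmentationMask, Volume3D

__all__ = [
    "PhantomParams",
    "RaterNoiseParams",
    "generate_phantom_subject",
    "generate_population",
    "simulate_rater_mask",
]

_MIN_GRID = 16  # below this the template's nose/orbits collapse into single voxels


@dataclass(frozen=True)
class PhantomParams:
    """Conditions under which a synthetic subject is generated.

    ``subject_deformation_scale`` is the RMS magnitude (mm) of the smooth
    random warp that individualises the template; ``speckle_contrast`` is the
    relative amplitude of the multiplicative speckle field; ``clutter_probability``
    is the chance of a limb/cord-like structure touching the face.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_deformation_scale: float = 3.0
    speckle_contrast: float = 0.35
    clutter_probability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid_shape and spacing must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.subject_deformation_scale < 0 or self.speckle_contrast < 0:
            raise ValueError("deformation scale and speckle contrast must be >= 0")
        if not 0.0 <= self.clutter_probability <= 1.0:
            raise ValueError("clutter_probability must be in [0, 1]")


@dataclass(frozen=True)
class RaterNoiseParams:
    """Perturbation model for a simulated human rater.

    ``boundary_jitter_mm`` is the RMS amplitude of a smooth random boundary
    displacement; ``volume_bias_fraction`` rescales the segmented volume
    toward (1 + bias) times the truth.  Zero noise reproduces the truth
    exactly.
    """

    boundary_jitter_mm: float = 0.5
    volume_bias_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_mm < 0:
            raise ValueError("boundary_jitter_mm must be >= 0")


# --------------------------------------------------------------------------
# template geometry, evaluated analytically at (possibly warped) world points


def _template_predicates(shape, spacing):
    """Return closures mapping world-coordinate arrays to region predicates."""
    extent = np.array(shape) * np.array(spacing)
    cx, cy, cz = extent * np.array([0.5, 0.42, 0.5])
    ax, ay, az = extent * np.array([0.30, 0.34, 0.36])
    nose_c = np.array([cx, cy + 0.92 * ay, cz - 0.05 * extent[2]])
    nose_r = extent * np.array([0.075, 0.11, 0.075])
    orb_d = 0.13 * extent[0]
    orb_c1 = np.array([cx - orb_d, cy + 0.90 * ay, cz + 0.16 * extent[2]])
    orb_c2 = np.array([cx + orb_d, cy + 0.90 * ay, cz + 0.16 * extent[2]])
    orb_r = 0.060 * float(np.mean(extent))

    def ellipsoid(x, y, z, c, r):
        return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2

    def face(x, y, z):
        head = (ellipsoid(x, y, z, (cx, cy, cz), (ax, ay, az)) <= 1.0) & (y >= cy)
        nose = ellipsoid(x, y, z, nose_c, nose_r) <= 1.0
        orbits = (ellipsoid(x, y, z, orb_c1, (orb_r,) * 3) <= 1.0) | (
            ellipsoid(x, y, z, orb_c2, (orb_r,) * 3) <= 1.0
        )
        return (head | nose) & ~orbits

    def fluid(x, y, z):
        # anechoic pocket in front of the face, inside an enlarged head envelope
        env = ellipsoid(x, y, z, (cx, cy, cz), (1.5 * ax, 1.6 * ay, 1.5 * az)) <= 1.0
        return env & (y >= cy)

    def clutter(x, y, z, toward):
        c = nose_c + toward * extent * np.array([0.13, 0.16, 0.13])
        return ellipsoid(x, y, z, c, 0.085 * extent) <= 1.0

    return face, fluid, clutter


def _smooth_vector_field(shape, spacing, rms_mm, sigma_vox, rng):
    """Smooth random displacement field with the requested RMS magnitude (mm)."""
    disp = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox) for _ in range(3)]
    )
    mag = np.sqrt(np.mean(np.sum(disp**2, axis=0)))
    if mag > 0:
        disp *= rms_mm / mag
    return disp  # (3, nx, ny, nz), in mm


def generate_phantom_subject(params: PhantomParams) -> tuple[Volume3D, SegmentationMask]:
    """Generate one synthetic subject: (speckled image, ground-truth face mask)."""
    shape = tuple(int(s) for s in params.grid_shape)
    if min(shape) < _MIN_GRID:
        raise ValueError(
            f"grid {shape} too small to contain the face template (min {_MIN_GRID} per axis)"
        )
    spacing = params.spacing
    rng = np.random.default_rng(params.seed)
    face, fluid, clutter = _template_predicates(shape, spacing)

    # world coordinates of voxel centres, pulled back through the subject warp
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    if params.subject_deformation_scale > 0:
        disp = _smooth_vector_field(
            shape, spacing, params.subject_deformation_scale, sigma_vox=8.0, rng=rng
        )
        x, y, z = (g + d for g, d in zip(grids, disp))
    else:
        rng.standard_normal()  # keep the stream position independent of the branch
        x, y, z = grids

    mask = face(x, y, z)
    in_fluid = fluid(x, y, z) & ~mask

    has_clutter = rng.random() < params.clutter_probability
    toward = rng.standard_normal(3)
    toward[1] = abs(toward[1])  # push clutter out in front of the face
    toward /= np.linalg.norm(toward) + 1e-12
    clut = clutter(x, y, z, toward) & ~mask if has_clutter else np.zeros(shape, bool)

    tissue_var = ndimage.gaussian_filter(rng.standard_normal(shape), 8.0)
    tissue_var /= np.std(tissue_var) + 1e-12
    img = np.full(shape, 0.45)  # maternal tissue / uterine wall
    img[in_fluid] = 0.10  # amniotic fluid, anechoic
    img[clut] = 0.65
    img[mask] = 0.75 + 0.08 * tissue_var[mask]

    if params.speckle_contrast > 0:
        speckle = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
        speckle /= np.std(speckle) + 1e-12
        img = img * (1.0 + params.speckle_contrast * speckle)
    else:
        rng.standard_normal()
    img = np.clip(img, 0.0, None)

    return (
        Volume3D(img, spacing),
        SegmentationMask(mask.astype(np.uint8), spacing),
    )


def generate_population(n: int, params: PhantomParams) -> AtlasBank:
    """Generate ``n`` subjects on identical grids from seeds seed, seed+1, ..."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    entries = []
    for i in range(n):
        img, msk = generate_phantom_subject(replace(params, seed=params.seed + i))
        entries.append(AtlasEntry(id=f"subj_{i:03d}", image=img, mask=msk))
    return AtlasBank(entries)


# --------------------------------------------------------------------------
# simulated manual raters


def simulate_rater_mask(truth: SegmentationMask, noise: RaterNoiseParams) -> SegmentationMask:
    """Perturb a ground-truth mask the way a human rater would.

    A signed volume bias is applied first (level-set shift of the boundary to
    hit (1 + bias) x |truth| voxels), then the boundary is jittered by a
    smooth random displacement field of RMS amplitude ``boundary_jitter_mm``.
    """
    if truth.is_empty:
        raise ValueError("truth mask is empty")
    labels = truth.labels
    spacing = truth.spacing
    rng = np.random.default_rng(noise.seed)

    if noise.volume_bias_fraction != 0.0:
        target = int(round((1.0 + noise.volume_bias_fraction) * truth.voxel_count))
        target = max(1, min(target, labels.size))
        inside = ndimage.distance_transform_edt(labels, sampling=spacing)
        outside = ndimage.distance_transform_edt(1 - labels, sampling=spacing)
        signed = (inside - outside).ravel()  # > 0 strictly inside, < 0 outside
        # exactly `target` voxels with the largest signed distance (distance
        # ties at the cut are broken deterministically by argpartition)
        keep = np.argpartition(signed, signed.size - target)[signed.size - target :]
        flat = np.zeros(signed.size, np.uint8)
        flat[keep] = 1
        labels = flat.reshape(labels.shape)

    if noise.boundary_jitter_mm > 0.0:
        disp = _smooth_vector_field(
            labels.shape, spacing, noise.boundary_jitter_mm, sigma_vox=3.0, rng=rng
        )
        idx = np.meshgrid(*[np.arange(n, dtype=float) for n in labels.shape], indexing="ij")
        sample = [i + d / s for i, d, s in zip(idx, disp, spacing)]
        warped = ndimage.map_coordinates(
            labels.astype(np.float64), sample, order=1, mode="constant", cval=0.0
        )
        labels = (warped >= 0.5).astype(np.uint8)

    return SegmentationMask(labels, spacing, truth.origin)
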