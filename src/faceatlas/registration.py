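"""Intensity-based affine and B-spline free-form-deformation (FFD) registration.

The similarity measure is normalised mutual information (NMI),
``(H(A)+H(B)) / H(A,B)``, computed from a joint intensity histogram.  The
FFD stage maximises ``NMI - bending_weight * bending_energy`` over the
displacements of a cubic B-spline control-point lattice, coarse-to-fine, by
L-BFGS with an analytic gradient (hard binning of the fixed image, linear
Parzen windowing of the moving image).  The affine stage maximises NMI over
12-parameter world-coordinate maps through an image pyramid.

Transform convention (pull-back): a transform maps *target* world
coordinates to *moving* world coordinates, so resampling is single-pass and
hole-free.  The composite FFD map is ``T(p) = A(p + D(p))`` with ``A`` the
affine pre-alignment and ``D`` the B-spline displacement (mm) anchored on
the target grid.

All optimisation is deterministic: full-resolution histograms, no sampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .core import GridMismatchError, SegmentationMask, Volume3D

__all__ = [
    "GridSpec",
    "AffineTransform",
    "BSplineTransform",
    "RegistrationParams",
    "RegistrationError",
    "nmi",
    "affine_register",
    "ffd_register",
    "apply_transform",
    "random_smooth_warp",
    "save_transform",
    "load_transform",
]


class RegistrationError(RuntimeError):
    """Registration failed (degenerate input or non-finite objective)."""


@dataclass(frozen=True)
class GridSpec:
    """Shape + spacing + origin defining a sampling grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def of(cls, obj) -> "GridSpec":
        if isinstance(obj, GridSpec):
            return obj
        return cls(tuple(obj.shape), tuple(obj.spacing), tuple(obj.origin))

    def world_points(self) -> np.ndarray:
        """(3, N) world coordinates of all voxel centres."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh])


@dataclass
class AffineTransform:
    """Homogeneous 4x4 world-coordinate map (target world -> moving world)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("upper-left 3x3 block must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def from_rotation_z(cls, degrees: float, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        th = np.deg2rad(degrees)
        r = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        c = np.asarray(center, dtype=float)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c - r @ c
        return cls(m)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=1e-12)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (3, N) world points."""
        return self.matrix[:3, :3] @ points + self.matrix[:3, 3:4]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()


# ---------------------------------------------------------------------------
# cubic B-spline lattice


def _cubic_weights(w: np.ndarray) -> list[np.ndarray]:
    w2, w3 = w * w, w * w * w
    return [
        (1 - w) ** 3 / 6.0,
        (3 * w3 - 6 * w2 + 4) / 6.0,
        (-3 * w3 + 3 * w2 + 3 * w + 1) / 6.0,
        w3 / 6.0,
    ]


def _lattice_size(n_vox: int, spacing_vox: float) -> int:
    # control point j sits at voxel coordinate (j - 1) * spacing_vox
    return int(np.floor((n_vox - 1) / spacing_vox)) + 4


def _weight_matrix(n_vox: int, spacing_vox: float) -> np.ndarray:
    """Dense (n_vox, K) matrix of cubic B-spline weights along one axis."""
    K = _lattice_size(n_vox, spacing_vox)
    t = np.arange(n_vox) / spacing_vox + 1.0
    j0 = np.floor(t).astype(int)
    parts = _cubic_weights(t - j0)
    W = np.zeros((n_vox, K))
    rows = np.arange(n_vox)
    for m in range(4):
        W[rows, j0 - 1 + m] += parts[m]
    return W


def _expand_field(coef: np.ndarray, Ws: list[np.ndarray]) -> np.ndarray:
    """Dense displacement (nx, ny, nz, 3) from lattice coefficients (K1,K2,K3,3)."""
    T = np.tensordot(Ws[0], coef, axes=(1, 0))
    T = np.tensordot(Ws[1], T, axes=(1, 1))
    T = np.tensordot(Ws[2], T, axes=(1, 2))
    return T.transpose(2, 1, 0, 3)


def _splat_gradient(g: np.ndarray, Ws: list[np.ndarray]) -> np.ndarray:
    """Adjoint of :func:`_expand_field`: dense (nx,ny,nz,3) -> lattice grads."""
    G = np.tensordot(Ws[0].T, g, axes=(1, 0))
    G = np.tensordot(Ws[1].T, G, axes=(1, 1))
    G = np.tensordot(Ws[2].T, G, axes=(1, 2))
    return G.transpose(2, 1, 0, 3)


@dataclass
class BSplineTransform:
    """FFD transform: B-spline coefficient displacements (mm) over a target
    grid, composed after an affine pre-alignment: ``T(p) = affine_pre(p + D(p))``."""

    grid: GridSpec
    control_spacing: tuple[float, float, float]  # mm per axis
    coefficients: np.ndarray  # (K1, K2, K3, 3) displacements in mm
    affine_pre: AffineTransform = field(default_factory=AffineTransform.identity)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = tuple(
            _lattice_size(self.grid.shape[a], self.control_spacing[a] / self.grid.spacing[a])
            for a in range(3)
        ) + (3,)
        if self.coefficients.shape != expected:
            raise ValueError(
                f"coefficient lattice {self.coefficients.shape} does not cover grid "
                f"{self.grid.shape} at control spacing {self.control_spacing} "
                f"(expected {expected})"
            )

    def _weight_matrices(self) -> list[np.ndarray]:
        return [
            _weight_matrix(self.grid.shape[a], self.control_spacing[a] / self.grid.spacing[a])
            for a in range(3)
        ]

    def displacement_field(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) displacement in mm on the target grid."""
        return _expand_field(self.coefficients, self._weight_matrices())

    @classmethod
    def zero(
        cls, grid: GridSpec, control_spacing, affine_pre: AffineTransform | None = None
    ) -> "BSplineTransform":
        cs = tuple(float(c) for c in control_spacing)
        shape = tuple(
            _lattice_size(grid.shape[a], cs[a] / grid.spacing[a]) for a in range(3)
        )
        return cls(
            grid, cs, np.zeros(shape + (3,)), affine_pre or AffineTransform.identity()
        )


def random_smooth_warp(
    grid_like,
    amplitude_mm: float,
    control_spacing_mm: float = 10.0,
    seed: int = 0,
    affine_pre: AffineTransform | None = None,
) -> BSplineTransform:
    """A random smooth B-spline warp whose dense RMS magnitude is ``amplitude_mm``."""
    grid = GridSpec.of(grid_like)
    t = BSplineTransform.zero(grid, (control_spacing_mm,) * 3, affine_pre)
    rng = np.random.default_rng(seed)
    coef = rng.standard_normal(t.coefficients.shape)
    t.coefficients = coef
    dense = t.displacement_field()
    rms = np.sqrt(np.mean(np.sum(dense**2, axis=-1)))
    t.coefficients = coef * (amplitude_mm / rms) if rms > 0 else coef
    return t


# ---------------------------------------------------------------------------
# NMI


def _entropy(p: np.ndarray) -> float:
    p = p[p > 1e-300]
    return float(-np.sum(p * np.log(p)))


def nmi(a: Volume3D, b: Volume3D, bins: int = 64) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B), in [1, 2].

    Defined as 2 when both images are constant and 1 when exactly one is
    (with a warning): a constant image carries zero entropy.
    """
    a.require_same_grid(b)
    x = np.asarray(a.data, dtype=float).ravel()
    y = np.asarray(b.data, dtype=float).ravel()
    cx, cy = x.max() == x.min(), y.max() == y.min()
    if cx or cy:
        warnings.warn("constant image in NMI: zero marginal entropy", stacklevel=2)
        return 2.0 if (cx and cy) else 1.0
    H, _, _ = np.histogram2d(x, y, bins=bins)
    P = H / H.sum()
    return (_entropy(P.sum(axis=1)) + _entropy(P.sum(axis=0))) / _entropy(P.ravel())


class _ParzenNMI:
    """Differentiable NMI: hard-binned fixed image, linear Parzen moving image.

    Moving samples are expected on a fixed [0, 1] intensity scale.
    """

    def __init__(self, fixed: np.ndarray, bins: int):
        f = np.asarray(fixed, dtype=float).ravel()
        lo, hi = f.min(), f.max()
        if hi <= lo:
            raise RegistrationError("fixed image is constant; NMI is degenerate")
        self.bins = int(bins)
        self.a_idx = np.clip(
            ((f - lo) / (hi - lo) * self.bins).astype(int), 0, self.bins - 1
        )
        self.n = f.size

    def value_and_sample_grad(self, m: np.ndarray) -> tuple[float, np.ndarray]:
        bins, n = self.bins, self.n
        tm = np.clip(m, 0.0, 1.0) * (bins - 1)
        b0 = np.floor(tm).astype(int)
        w1 = tm - b0
        b1 = np.minimum(b0 + 1, bins - 1)
        flat0 = self.a_idx * bins + b0
        flat1 = self.a_idx * bins + b1
        counts = np.bincount(flat0, weights=1.0 - w1, minlength=bins * bins)
        counts += np.bincount(flat1, weights=w1, minlength=bins * bins)
        P = (counts / n).reshape(bins, bins)
        pa, pb = P.sum(axis=1), P.sum(axis=0)
        Ha, Hb, Hab = _entropy(pa), _entropy(pb), _entropy(P.ravel())
        val = (Ha + Hb) / Hab
        logP = np.log(np.maximum(P, 1e-12))
        log_pa = np.log(np.maximum(pa, 1e-12))
        log_pb = np.log(np.maximum(pb, 1e-12))
        # d val / d P(a,b)
        L = (-(log_pa[:, None] + 1.0) - (log_pb[None, :] + 1.0) + val * (logP + 1.0)) / Hab
        Lf = L.ravel()
        grad_m = (bins - 1) / n * (Lf[flat1] - Lf[flat0])
        return val, grad_m


# ---------------------------------------------------------------------------
# parameters and shared machinery


@dataclass(frozen=True)
class RegistrationParams:
    """Fixed, versioned defaults for both registration stages.

    ``pyramid_levels`` image-pyramid depth (factor 2 between levels);
    ``min_pyramid_factor`` lets a pipeline stop above full resolution for
    speed; ``control_spacing_vox`` is the finest B-spline knot spacing in
    voxels; ``bending_weight`` scales the bending-energy penalty.
    """

    pyramid_levels: int = 3
    histogram_bins: int = 64
    bending_weight: float = 1e-3
    max_iterations: int = 300
    convergence_tol: float = 1e-5
    control_spacing_vox: float = 5.0
    min_pyramid_factor: int = 1

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1 or self.max_iterations < 1 or self.histogram_bins < 2:
            raise ValueError("counts must be >= 1 (bins >= 2)")
        if self.bending_weight < 0 or self.convergence_tol <= 0:
            raise ValueError("bending_weight >= 0 and convergence_tol > 0 required")

    def pyramid_factors(self) -> list[int]:
        return [
            self.min_pyramid_factor * 2 ** (self.pyramid_levels - 1 - l)
            for l in range(self.pyramid_levels)
        ]


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise RegistrationError("constant image cannot be registered")
    return (img - lo) / (hi - lo)


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    """Smooth-and-decimate; voxel (0,0,0) keeps its world position."""
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    return Volume3D(data, tuple(s * factor for s in vol.spacing), vol.origin)


def _sample(img: np.ndarray, idx: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(img, idx, order=order, mode="constant", cval=0.0)


def _level_bins(bins: int, factor: int) -> int:
    return max(16, bins // factor)


# ---------------------------------------------------------------------------
# affine registration


def affine_register(
    target: Volume3D, moving: Volume3D, params: RegistrationParams | None = None
) -> AffineTransform:
    """Maximise NMI over 12-parameter affine maps via a multi-resolution pyramid.

    Deterministic: L-BFGS on the analytic NMI gradient, full-image histograms.
    """
    params = params or RegistrationParams()
    tgt_n = _normalize(np.asarray(target.data, dtype=float))
    mov_n = _normalize(np.asarray(moving.data, dtype=float))
    tgt = Volume3D(tgt_n, target.spacing, target.origin)

    center = np.asarray(target.origin) + (np.asarray(target.shape) - 1) * np.asarray(
        target.spacing
    ) / 2.0
    scale_l = float(np.mean((np.asarray(target.shape) - 1) * np.asarray(target.spacing))) / 2.0
    sm = np.asarray(moving.spacing, dtype=float)
    om = np.asarray(moving.origin, dtype=float)

    theta = np.zeros(12)  # [linear deviations * L, translation mm]
    for factor in params.pyramid_factors():
        lvl = _downsample(tgt, factor)
        mov_l = (
            ndimage.gaussian_filter(mov_n, factor / 2.0) if factor > 1 else mov_n
        )
        grad_m = np.gradient(mov_l)
        cost = _ParzenNMI(lvl.data, _level_bins(params.histogram_bins, factor))
        pts = GridSpec.of(lvl).world_points()  # (3, N)
        pc = pts - center[:, None]

        def objective(th, pts=pts, pc=pc, mov_l=mov_l, grad_m=grad_m, cost=cost):
            A = np.eye(3) + th[:9].reshape(3, 3) / scale_l
            t = th[9:]
            q = A @ pc + center[:, None] + t[:, None]  # moving world
            idx = (q - om[:, None]) / sm[:, None]
            m = _sample(mov_l, idx, order=1)
            val, dval_dm = cost.value_and_sample_grad(m)
            gq = np.stack([_sample(g, idx, order=1) for g in grad_m])  # d m / d idx
            gq *= dval_dm[None, :]
            gq /= sm[:, None]  # d val / d q (per mm)
            g_lin = (gq @ pc.T) / scale_l
            g_t = gq.sum(axis=1)
            g = -np.concatenate([g_lin.ravel(), g_t])
            f = -val
            if not np.isfinite(f):
                raise RegistrationError("non-finite affine objective")
            return f, g

        res = optimize.minimize(
            objective,
            theta,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": params.max_iterations,
                "ftol": params.convergence_tol,
                "gtol": 1e-8,
            },
        )
        theta = res.x

    A = np.eye(3) + theta[:9].reshape(3, 3) / scale_l
    t = theta[9:]
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = center - A @ center + t
    return AffineTransform(m)


# ---------------------------------------------------------------------------
# FFD registration


def _bending_energy(coef: np.ndarray) -> tuple[float, np.ndarray]:
    """Discrete bending energy of the lattice and its gradient.

    Sum of squared second and mixed differences of the coefficients,
    normalised by the number of control points.
    """
    grad = np.zeros_like(coef)
    n = coef[..., 0].size
    total = 0.0
    idx = [slice(None)] * 4

    for a in range(3):
        d2 = np.diff(coef, n=2, axis=a)
        total += np.sum(d2**2)
        g = 2.0 * d2
        for offset, w in ((0, 1.0), (1, -2.0), (2, 1.0)):
            sl = list(idx)
            sl[a] = slice(offset, offset + d2.shape[a])
            grad[tuple(sl)] += w * g
    for a in range(3):
        for b in range(a + 1, 3):
            d11 = np.diff(np.diff(coef, axis=a), axis=b)
            total += 2.0 * np.sum(d11**2)
            g = 4.0 * d11
            for oa, wa in ((0, -1.0), (1, 1.0)):
                for ob, wb in ((0, -1.0), (1, 1.0)):
                    sl = list(idx)
                    sl[a] = slice(oa, oa + d11.shape[a])
                    sl[b] = slice(ob, ob + d11.shape[b])
                    grad[tuple(sl)] += wa * wb * g
    return total / n, grad / n


def _subdivide_axis(coef: np.ndarray, axis: int, new_k: int) -> np.ndarray:
    """Cubic B-spline knot-halving along one lattice axis (old spacing -> /2)."""
    c = np.moveaxis(coef, axis, 0)
    K = c.shape[0]
    pad = np.zeros((K + 2,) + c.shape[1:])
    pad[1 : K + 1] = c
    out = np.zeros((new_k,) + c.shape[1:])
    for jp in range(new_k):
        if jp % 2 == 1:  # new knot coincides with old knot j
            j = (jp + 1) // 2
            if 0 <= j < K:
                out[jp] = (pad[j] + 6.0 * pad[j + 1] + pad[j + 2]) / 8.0
        else:  # midpoint between old knots j and j+1
            j = jp // 2
            if 0 <= j < K:
                out[jp] = (pad[j + 1] + pad[j + 2]) / 2.0
    return np.moveaxis(out, 0, axis)


def ffd_register(
    target: Volume3D,
    moving: Volume3D,
    init: AffineTransform | None = None,
    params: RegistrationParams | None = None,
) -> BSplineTransform:
    """Maximise ``NMI - bending_weight * bending energy`` over B-spline
    coefficients, coarse-to-fine in the control-point lattice.

    The moving image is first resampled through ``init`` onto the target
    grid; the returned transform composes the optimised displacement with
    that affine (``T(p) = init(p + D(p))``).  If the optimised field does not
    improve the (hard-binned) NMI over the affine initialisation, the zero
    field is returned instead, so the result never degrades the similarity.
    """
    params = params or RegistrationParams()
    init = init or AffineTransform.identity()
    grid = GridSpec.of(target)
    spacing = np.asarray(grid.spacing, dtype=float)

    if init.is_identity and grid == GridSpec.of(moving):
        mov_res = Volume3D(np.asarray(moving.data, dtype=float), grid.spacing, grid.origin)
    else:
        mov_res = apply_transform(moving, init, grid, mode="linear")
    tgt_n = _normalize(np.asarray(target.data, dtype=float))
    mov_n = _normalize(np.asarray(mov_res.data, dtype=float))

    base_idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    ).reshape(3, -1)

    spacings_vox = [
        params.control_spacing_vox * 2 ** (params.pyramid_levels - 1 - l)
        for l in range(params.pyramid_levels)
    ]
    coef = None
    for level, s_vox in enumerate(spacings_vox):
        sigma = max(s_vox / params.control_spacing_vox / 2.0, 0.0)
        mov_l = ndimage.gaussian_filter(mov_n, sigma) if sigma > 0.5 else mov_n
        tgt_l = ndimage.gaussian_filter(tgt_n, sigma) if sigma > 0.5 else tgt_n
        grad_m = np.gradient(mov_l)
        cost = _ParzenNMI(tgt_l, params.histogram_bins)
        Ws = [_weight_matrix(grid.shape[a], s_vox) for a in range(3)]
        kshape = tuple(W.shape[1] for W in Ws) + (3,)
        if coef is None:
            coef = np.zeros(kshape)
        elif coef.shape != kshape:
            for a in range(3):
                coef = _subdivide_axis(coef, a, kshape[a])

        def objective(cvec, Ws=Ws, kshape=kshape, mov_l=mov_l, grad_m=grad_m, cost=cost):
            c = cvec.reshape(kshape)
            disp = _expand_field(c, Ws).reshape(-1, 3).T  # (3, N) mm
            idx = base_idx + disp / spacing[:, None]
            m = _sample(mov_l, idx, order=1)
            val, dval_dm = cost.value_and_sample_grad(m)
            gdisp = np.empty_like(disp)
            for a in range(3):
                gdisp[a] = dval_dm * _sample(grad_m[a], idx, order=1) / spacing[a]
            gcoef = _splat_gradient(
                gdisp.T.reshape(grid.shape + (3,)), Ws
            )
            be, gbe = _bending_energy(c)
            f = -(val - params.bending_weight * be)
            g = -(gcoef - params.bending_weight * gbe)
            if not np.isfinite(f) or not np.all(np.isfinite(g)):
                raise RegistrationError(
                    f"non-finite FFD objective at level {level} (val={val}, be={be})"
                )
            return f, g.ravel()

        res = optimize.minimize(
            objective,
            coef.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": params.max_iterations,
                "ftol": params.convergence_tol,
                "gtol": 1e-8,
            },
        )
        coef = res.x.reshape(kshape)

    cs_mm = tuple(params.control_spacing_vox * s for s in grid.spacing)
    out = BSplineTransform(grid, cs_mm, coef, init)

    # monotone acceptance: never return a field that worsens the hard NMI
    tgt_vol = Volume3D(tgt_n, grid.spacing, grid.origin)
    mov_vol = Volume3D(mov_n, grid.spacing, grid.origin)
    identity = BSplineTransform.zero(grid, cs_mm)
    warped = apply_transform(mov_vol, _strip_affine(out), grid, mode="linear")
    nmi_final = nmi(tgt_vol, warped, params.histogram_bins)
    nmi_init = nmi(tgt_vol, mov_vol, params.histogram_bins)
    if nmi_final < nmi_init:
        identity.affine_pre = init
        return identity
    return out


def _strip_affine(t: BSplineTransform) -> BSplineTransform:
    return BSplineTransform(t.grid, t.control_spacing, t.coefficients)


# ---------------------------------------------------------------------------
# resampling


def apply_transform(
    x: Volume3D | SegmentationMask,
    t: AffineTransform | BSplineTransform,
    target_grid=None,
    mode: str = "linear",
) -> Volume3D | SegmentationMask:
    """Pull-back resampling of ``x`` onto ``target_grid`` through ``t``.

    Each target voxel samples the moving object at its mapped location;
    out-of-field samples are 0.  ``mode`` is ``linear`` or ``nearest``; a
    mask resampled with ``linear`` becomes a probabilistic [0, 1] volume.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode: {mode!r}")
    grid = GridSpec.of(target_grid) if target_grid is not None else GridSpec.of(x)
    pts = grid.world_points()
    if isinstance(t, BSplineTransform):
        if t.grid != grid:
            raise GridMismatchError(
                f"transform grid {t.grid} does not match target grid {grid}"
            )
        disp = t.displacement_field().reshape(-1, 3).T
        q = t.affine_pre.apply(pts + disp)
    elif isinstance(t, AffineTransform):
        q = t.apply(pts)
    else:
        raise TypeError(f"unsupported transform type: {type(t)!r}")
    idx = (q - np.asarray(x.origin)[:, None]) / np.asarray(x.spacing)[:, None]
    order = 1 if mode == "linear" else 0
    data = _sample(np.asarray(x.data, dtype=float), idx, order).reshape(grid.shape)
    if isinstance(x, SegmentationMask) and mode == "nearest":
        return SegmentationMask(data.astype(np.uint8), grid.spacing, grid.origin)
    return Volume3D(data, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# serialisation

_FORMAT_VERSION = 1


def save_transform(t: AffineTransform | BSplineTransform, path) -> None:
    """Serialise a transform to the package's JSON container."""
    doc: dict = {"format_version": _FORMAT_VERSION}
    if isinstance(t, AffineTransform):
        doc["type"] = "affine"
        doc["matrix"] = t.matrix.tolist()
    elif isinstance(t, BSplineTransform):
        doc["type"] = "bspline"
        doc["matrix"] = t.affine_pre.matrix.tolist()
        doc["grid"] = {
            "shape": list(t.grid.shape),
            "spacing": list(t.grid.spacing),
            "origin": list(t.grid.origin),
        }
        doc["control_spacing"] = list(t.control_spacing)
        doc["coefficients_shape"] = list(t.coefficients.shape)
        doc["coefficients"] = t.coefficients.ravel().tolist()
    else:
        raise TypeError(f"unsupported transform type: {type(t)!r}")
    Path(path).write_text(json.dumps(doc))


def load_transform(path) -> AffineTransform | BSplineTransform:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported transform format version: {doc.get('format_version')}")
    if doc["type"] == "affine":
        return AffineTransform(np.asarray(doc["matrix"]))
    grid = GridSpec(
        tuple(doc["grid"]["shape"]),
        tuple(doc["grid"]["spacing"]),
        tuple(doc["grid"]["origin"]),
    )
    coef = np.asarray(doc["coefficients"]).reshape(doc["coefficients_shape"])
    return BSplineTransform(
        grid, tuple(doc["control_spacing"]), coef, AffineTransform(np.asarray(doc["matrix"]))
    )
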