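"""Label propagation and consensus fusion.

Propagated atlas labels are fused by a STEPS-like scheme: atlases are ranked
per voxel by locally normalised cross-correlation (LNCC) between the target
and each warped atlas image, the ``top_k`` best are kept, and a STAPLE-style
EM jointly estimates the consensus probability and each selected atlas's
sensitivity/specificity.  With EM disabled the selected votes are averaged
(locally weighted majority vote).

The E-step prior is global: the mean vote rate over the target grid.
Probabilistic votes enter the likelihood geometrically
(``p^d (1-p)^(1-d)`` with the vote value ``d`` in [0, 1]), which reduces to
classical STAPLE for binary votes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SegmentationMask, Volume3D
from .registration import BSplineTransform, GridSpec, apply_transform

__all__ = [
    "ProbabilisticLabel",
    "SimilarityMap",
    "FusionParams",
    "RaterPerformance",
    "propagate_label",
    "lncc_map",
    "staple_em",
    "steps_fuse",
    "majority_vote",
]

_EPS = 1e-6
_PQ_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass
class ProbabilisticLabel:
    """Per-voxel foreground probability on a target grid."""

    probabilities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 3:
            raise ValueError("probabilities must be a 3D grid")
        if p.min() < -_EPS or p.max() > 1 + _EPS:
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = np.clip(p, 0.0, 1.0)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def threshold(self, level: float = 0.5) -> SegmentationMask:
        """Voxels with probability >= ``level`` become foreground."""
        return SegmentationMask(
            (self.probabilities >= level).astype(np.uint8), self.spacing, self.origin
        )

    @classmethod
    def from_mask(cls, m: SegmentationMask) -> "ProbabilisticLabel":
        return cls(m.labels.astype(float), m.spacing, m.origin)


@dataclass
class SimilarityMap:
    """Local normalised cross-correlation in [-1, 1] under a Gaussian window."""

    values: np.ndarray
    kernel_sigma_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.abs(v).max() > 1 + 1e-6:
            raise ValueError("LNCC values must lie in [-1, 1]")
        self.values = v


@dataclass(frozen=True)
class FusionParams:
    """STEPS fusion settings: ``top_k`` atlases kept per voxel, LNCC window
    scale, EM iteration controls, and an optional Gaussian smoothing of the
    posterior (voxels) before the 0.5 threshold (off by default so that the
    fusion rule's exact equivalences hold)."""

    top_k: int = 8
    lncc_sigma_mm: float = 2.0
    em_max_iter: int = 30
    em_tol: float = 1e-4
    em_enabled: bool = True
    posterior_smoothing_sigma_vox: float = 0.0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")


@dataclass
class RaterPerformance:
    """Estimated per-atlas sensitivity p and specificity q."""

    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.specificity = np.asarray(self.specificity, dtype=float)
        for arr in (self.sensitivity, self.specificity):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("performance parameters must lie in [0, 1]")


def propagate_label(
    atlas_mask: SegmentationMask, t: BSplineTransform, target_grid=None
) -> ProbabilisticLabel:
    """Resample a binary atlas mask through ``t`` with linear interpolation."""
    grid = GridSpec.of(target_grid) if target_grid is not None else t.grid
    warped = apply_transform(atlas_mask, t, grid, mode="linear")
    return ProbabilisticLabel(warped.data, grid.spacing, grid.origin)


def lncc_map(
    target: Volume3D, warped_atlas_image: Volume3D, sigma_mm: float = 2.0
) -> SimilarityMap:
    """Pearson correlation of the two images under a Gaussian window.

    Windows where either image has (numerically) zero variance get the
    defined value 0.
    """
    target.require_same_grid(warped_atlas_image)
    a = np.asarray(target.data, dtype=float)
    b = np.asarray(warped_atlas_image.data, dtype=float)
    sigma_vox = [sigma_mm / s for s in target.spacing]

    def g(x):
        return ndimage.gaussian_filter(x, sigma_vox)

    mu_a, mu_b = g(a), g(b)
    var_a = g(a * a) - mu_a**2
    var_b = g(b * b) - mu_b**2
    cov = g(a * b) - mu_a * mu_b
    scale = float(max(np.ptp(a), 1.0)) * float(max(np.ptp(b), 1.0))
    tol = 1e-10 * scale
    denom = np.sqrt(np.clip(var_a, 0.0, None) * np.clip(var_b, 0.0, None))
    out = np.zeros_like(a)
    ok = (var_a > tol) & (var_b > tol)
    out[ok] = cov[ok] / denom[ok]
    return SimilarityMap(np.clip(out, -1.0, 1.0), sigma_mm)


def _check_votes(votes: list[ProbabilisticLabel]) -> np.ndarray:
    if len(votes) == 0:
        raise ValueError("at least one vote is required")
    shape = votes[0].probabilities.shape
    for v in votes[1:]:
        if v.probabilities.shape != shape:
            raise ValueError("all votes must share one grid")
    return np.stack([v.probabilities.reshape(-1) for v in votes])  # (J, N)


def staple_em(
    votes: list[ProbabilisticLabel],
    params: FusionParams | None = None,
    selection: np.ndarray | None = None,
) -> tuple[ProbabilisticLabel, RaterPerformance]:
    """STAPLE-style EM consensus from probabilistic votes.

    Alternates (E) the per-voxel truth posterior under current performance
    parameters with a global prior fixed to the mean vote rate, and (M)
    per-atlas sensitivity/specificity re-estimation, until the mean
    posterior changes by less than ``em_tol`` (relative) or ``em_max_iter``.

    ``selection`` optionally restricts, per voxel, which atlases inform the
    posterior (the STEPS per-voxel top-k mask); unselected atlases do not
    contribute at that voxel and their parameters are estimated only over
    voxels where they are selected.
    """
    params = params or FusionParams()
    d = _check_votes(votes)  # (J, N)
    J, n = d.shape
    sel = np.ones_like(d, dtype=bool) if selection is None else selection.reshape(J, n)
    if sel.shape != d.shape:
        raise ValueError("selection mask must match votes in shape")

    sel_counts = sel.sum(axis=1)
    prior = float(np.clip(d[sel].mean() if sel.any() else d.mean(), _EPS, 1 - _EPS))
    # initial posterior: mean of the selected votes (plain voting), then
    # alternate M (performance estimates) and E (truth posterior) steps
    denom = np.maximum(sel.sum(axis=0), 1)
    w = (sel * d).sum(axis=0) / denom
    p = np.full(J, 0.95)
    q = np.full(J, 0.95)
    for _ in range(params.em_max_iter):
        # M-step: re-estimate sensitivity/specificity over selected voxels
        sw1 = (sel * w[None, :]).sum(axis=1)
        sw0 = sel_counts - sw1
        with np.errstate(invalid="ignore"):
            p = np.where(sw1 > 0, (sel * (w[None, :] * d)).sum(axis=1) / sw1, 0.5)
            q = np.where(
                sw0 > 0, (sel * ((1 - w[None, :]) * (1 - d))).sum(axis=1) / sw0, 0.5
            )
        p = np.clip(p, *_PQ_CLIP)
        q = np.clip(q, *_PQ_CLIP)
        # E-step: truth posterior under the global prior
        lp, l1p = np.log(p), np.log1p(-p)
        lq, l1q = np.log(q), np.log1p(-q)
        ll1 = (sel * (d * lp[:, None] + (1 - d) * l1p[:, None])).sum(axis=0)
        ll0 = (sel * (d * l1q[:, None] + (1 - d) * lq[:, None])).sum(axis=0)
        logit = np.log(prior) - np.log1p(-prior) + ll1 - ll0
        w_new = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
        delta = abs(float(w_new.mean()) - float(w.mean()))
        w = w_new
        if delta <= params.em_tol * max(float(w.mean()), _EPS):
            break

    ref = votes[0]
    post = ProbabilisticLabel(w.reshape(ref.probabilities.shape), ref.spacing, ref.origin)
    return post, RaterPerformance(p, q)


def majority_vote(votes: list[ProbabilisticLabel]) -> SegmentationMask:
    """Plain per-voxel majority (mean vote >= 0.5, ties to foreground)."""
    d = _check_votes(votes)
    ref = votes[0]
    mean = d.mean(axis=0).reshape(ref.probabilities.shape)
    return SegmentationMask((mean >= 0.5).astype(np.uint8), ref.spacing, ref.origin)


def steps_fuse(
    target: Volume3D,
    warped_images: list[Volume3D],
    votes: list[ProbabilisticLabel],
    params: FusionParams | None = None,
    similarity_maps: list[SimilarityMap] | None = None,
) -> SegmentationMask:
    """Similarity-ranked fusion: per voxel keep the ``top_k`` atlases by LNCC
    against the target, then combine them by STAPLE EM (``em_enabled``) or by
    their average, and threshold the posterior at 0.5 (ties to foreground).

    ``similarity_maps`` may supply precomputed LNCC maps (one per atlas).
    Ranking ties are broken toward the lower atlas index.
    """
    params = params or FusionParams()
    if len(warped_images) != len(votes):
        raise ValueError(
            f"got {len(warped_images)} warped images but {len(votes)} votes"
        )
    d = _check_votes(votes)
    J, n = d.shape
    if params.top_k > J:
        raise ValueError(f"top_k={params.top_k} exceeds the number of atlases ({J})")

    if similarity_maps is None:
        similarity_maps = [
            lncc_map(target, img, params.lncc_sigma_mm) for img in warped_images
        ]
    sim = np.stack([np.asarray(s.values).reshape(-1) for s in similarity_maps])
    if sim.shape != d.shape:
        raise ValueError("similarity maps must share the votes' grid")

    if params.top_k == J:
        sel = np.ones((J, n), dtype=bool)
    else:
        # stable per-voxel ranking, descending similarity, ties -> lower index
        order = np.argsort(-sim, axis=0, kind="stable")
        sel = np.zeros((J, n), dtype=bool)
        cols = np.arange(n)
        for r in range(params.top_k):
            sel[order[r], cols] = True

    if params.em_enabled:
        post, _ = staple_em(votes, params, selection=sel)
        w = post.probabilities
    else:
        w = (sel * d).sum(axis=0) / sel.sum(axis=0)
        w = w.reshape(votes[0].probabilities.shape)

    if params.posterior_smoothing_sigma_vox > 0:
        w = ndimage.gaussian_filter(w, params.posterior_smoothing_sigma_vox)
    ref = votes[0]
    return SegmentationMask((w >= 0.5).astype(np.uint8), ref.spacing, ref.origin)
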