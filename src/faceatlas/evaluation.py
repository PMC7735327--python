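"""Experiment harnesses: leave-one-out validation of the atlas pipeline,
growing-atlas-size comparison, and the inter/intra-rater agreement study.

A leave-one-out (LOO) fold segments one bank member using all remaining
members as the atlas, then scores the result against that member's
ground-truth mask (Dice, ASSD, percent volume difference).  The growing-atlas
experiment repeats LOO while extra reference subjects are appended to the
bank; the held-out cases stay fixed (only the base members are ever held
out), so fold scores are comparable across atlas sizes.  Registrations are
cached per (target, atlas) pair and reused across sizes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bank import AtlasBank
from .core import SegmentationMask, Volume3D
from .fusion import (
    FusionParams,
    ProbabilisticLabel,
    SimilarityMap,
    lncc_map,
    propagate_label,
    steps_fuse,
)
from .metrics import MetricsReport, assd, compare_masks, dice, summarize, volume_difference
from .phantom import RaterNoiseParams, simulate_rater_mask
from .registration import (
    GridSpec,
    RegistrationParams,
    affine_register,
    apply_transform,
    ffd_register,
)
from .stats import (
    StatResult,
    friedman_test,
    icc,
    pairwise_posthoc,
    slope_ttest,
    standardized_effect,
)

__all__ = [
    "ExperimentResult",
    "RaterStudy",
    "RaterAgreementResult",
    "segment_with_atlas",
    "leave_one_out",
    "growing_atlas_experiment",
    "rater_agreement_study",
    "simulate_rater_study",
]

REGISTRATION_MODES = ("affine+ffd", "affine", "identity")


@dataclass
class ExperimentResult:
    """One LOO run: a per-held-out-case metrics report at a given atlas size."""

    atlas_size: int
    case_ids: list[str]
    reports: list[MetricsReport]
    refs_per_fold: int
    wall_time_s: list[float] = field(default_factory=list)

    def dice_values(self) -> np.ndarray:
        return np.array([r.dice for r in self.reports])

    def summary(self) -> dict:
        """median/IQR/min/max per metric, the Table-style summary."""
        out = {}
        for name in ("dice", "assd_mm", "vol_diff_pct"):
            med, iqr, lo, hi = summarize([getattr(r, name) for r in self.reports])
            out[name] = {"median": med, "iqr": iqr, "min": lo, "max": hi}
        return out


def _propagate_one(
    target: Volume3D,
    atlas_image: Volume3D,
    atlas_mask: SegmentationMask,
    reg_params: RegistrationParams,
    fusion_params: FusionParams,
    registration: str,
) -> tuple[Volume3D, ProbabilisticLabel, SimilarityMap]:
    grid = GridSpec.of(target)
    if registration == "identity":
        warped_img = Volume3D(np.asarray(atlas_image.data, float), grid.spacing, grid.origin)
        vote = ProbabilisticLabel.from_mask(atlas_mask)
    elif registration == "affine":
        aff = affine_register(target, atlas_image, reg_params)
        warped_img = apply_transform(atlas_image, aff, grid, mode="linear")
        warped_m = apply_transform(atlas_mask, aff, grid, mode="linear")
        vote = ProbabilisticLabel(warped_m.data, grid.spacing, grid.origin)
    elif registration == "affine+ffd":
        aff = affine_register(target, atlas_image, reg_params)
        ffd = ffd_register(target, atlas_image, aff, reg_params)
        warped_img = apply_transform(atlas_image, ffd, grid, mode="linear")
        vote = propagate_label(atlas_mask, ffd, grid)
    else:
        raise ValueError(f"unknown registration mode: {registration!r}")
    sim = lncc_map(target, warped_img, fusion_params.lncc_sigma_mm)
    return warped_img, vote, sim


def segment_with_atlas(
    target: Volume3D,
    atlas: AtlasBank,
    reg_params: RegistrationParams | None = None,
    fusion_params: FusionParams | None = None,
    registration: str = "affine+ffd",
    cache: dict | None = None,
    target_id: str | None = None,
) -> SegmentationMask:
    """Segment ``target`` with the full multi-atlas pipeline.

    Every atlas image is registered to the target, its mask propagated, and
    the votes fused by the similarity-ranked STAPLE fuser.  ``cache`` (a
    plain dict) memoises per-(target, atlas) propagation across calls.
    """
    if len(atlas) < 1:
        raise ValueError("atlas bank is empty")
    reg_params = reg_params or RegistrationParams()
    fusion_params = fusion_params or FusionParams()
    warped, votes, sims = [], [], []
    for entry in atlas:
        key = (target_id, entry.id, registration)
        if cache is not None and target_id is not None and key in cache:
            w, v, s = cache[key]
        else:
            w, v, s = _propagate_one(
                target, entry.image, entry.mask, reg_params, fusion_params, registration
            )
            if cache is not None and target_id is not None:
                cache[key] = (w, v, s)
        warped.append(w)
        votes.append(v)
        sims.append(s)
    fp = replace(fusion_params, top_k=min(fusion_params.top_k, len(atlas)))
    return steps_fuse(target, warped, votes, fp, similarity_maps=sims)


def leave_one_out(
    bank: AtlasBank,
    reg_params: RegistrationParams | None = None,
    fusion_params: FusionParams | None = None,
    registration: str = "affine+ffd",
    cache: dict | None = None,
    held_out_ids: list[str] | None = None,
    references: AtlasBank | None = None,
) -> ExperimentResult:
    """Leave-one-out cross-validation over ``bank``.

    Each entry is segmented using every other entry as reference and scored
    against its own ground truth.  ``held_out_ids`` restricts the folds (the
    growing-atlas experiment holds out only base cases); ``references``
    supplies a larger reference pool than ``bank`` itself.
    """
    pool = references if references is not None else bank
    if len(pool) < 2:
        raise ValueError("need a bank of >= 2 subjects for leave-one-out")
    fold_ids = held_out_ids if held_out_ids is not None else bank.ids
    reports, times = [], []
    refs_per_fold = len(pool) - 1
    for cid in fold_ids:
        entry = bank.subset([cid])[0]
        refs = pool.without(cid) if cid in pool.ids else pool
        t0 = time.perf_counter()
        seg = segment_with_atlas(
            entry.image,
            refs,
            reg_params,
            fusion_params,
            registration,
            cache=cache,
            target_id=cid,
        )
        times.append(time.perf_counter() - t0)
        reports.append(
            MetricsReport(
                pair=(cid, "auto"),
                dice=dice(entry.mask, seg),
                assd_mm=assd(entry.mask, seg) if not seg.is_empty else float("nan"),
                vol_diff_pct=volume_difference(entry.mask, seg),
            )
        )
    return ExperimentResult(
        atlas_size=len(pool),
        case_ids=list(fold_ids),
        reports=reports,
        refs_per_fold=refs_per_fold,
        wall_time_s=times,
    )


def growing_atlas_experiment(
    base: AtlasBank,
    additions: AtlasBank | list,
    step: int = 5,
    reg_params: RegistrationParams | None = None,
    fusion_params: FusionParams | None = None,
    registration: str = "affine+ffd",
    cache: dict | None = None,
    held_out_ids: list[str] | None = None,
) -> list[ExperimentResult]:
    """LOO at growing atlas sizes |base|, |base|+step, ...

    Only base members are held out; the added subjects act purely as extra
    references.  A shared registration cache makes the per-pair registrations
    run once across all sizes.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    extra = list(additions.entries) if isinstance(additions, AtlasBank) else list(additions)
    cache = {} if cache is None else cache
    results = []
    cut = 0
    while True:
        pool = base.extended(extra[:cut])
        results.append(
            leave_one_out(
                base,
                reg_params,
                fusion_params,
                registration,
                cache=cache,
                held_out_ids=held_out_ids,
                references=pool,
            )
        )
        if cut >= len(extra):
            break
        cut = min(cut + step, len(extra))
    return results


# ---------------------------------------------------------------------------
# rater study


@dataclass
class RaterStudy:
    """Masks indexed by (case id, rater id); every case has every rater."""

    case_ids: list[str]
    rater_ids: list[str]
    masks: dict  # (case_id, rater_id) -> SegmentationMask

    def __post_init__(self) -> None:
        missing = [
            (c, r)
            for c in self.case_ids
            for r in self.rater_ids
            if (c, r) not in self.masks
        ]
        if missing:
            raise ValueError(f"missing masks for {missing[:5]} ...")

    def mask(self, case_id: str, rater_id: str) -> SegmentationMask:
        return self.masks[(case_id, rater_id)]

    def volumes_table(self) -> pd.DataFrame:
        """Cases x raters table of physical volumes (mm^3)."""
        return pd.DataFrame(
            {
                r: [self.masks[(c, r)].physical_volume for c in self.case_ids]
                for r in self.rater_ids
            },
            index=self.case_ids,
        )


@dataclass
class RaterAgreementResult:
    per_pair: pd.DataFrame  # one row per (case, pairing) with the three metrics
    summaries: dict  # pairing -> metric -> (median, iqr, min, max)
    friedman: dict  # metric -> StatResult across pairings
    posthoc: dict  # metric -> list[StatResult] (intra vs each inter pairing)
    icc_volumes: StatResult
    volume_trend: dict  # metric -> StatResult (slope vs cube-root volume)
    effect_sizes: dict  # metric -> standardized inter-vs-intra difference


def rater_agreement_study(
    study: RaterStudy,
    pairs: list[tuple[str, str]] | None = None,
    intra_pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> RaterAgreementResult:
    """Pairwise agreement metrics and variability statistics for a rater study.

    For each named rater pairing and each case the three agreement metrics
    are computed, then: a Friedman test per metric across the pairings, a
    Bonferroni-corrected post-hoc comparison of the intra-operator pairing
    against each inter-operator pairing (alpha / m), an ICC on segmentation
    volumes across raters, and a t-test on the linear trend of the per-case
    mean Dice and ASSD against the cube root of the mean volume.
    """
    if len(study.rater_ids) < 2:
        raise ValueError("need >= 2 raters")
    if pairs is None:
        r = study.rater_ids
        pairs = [(r[i], r[j]) for i in range(len(r)) for j in range(i + 1, len(r))]

    rows = []
    for c in study.case_ids:
        for a, b in pairs:
            rep = compare_masks(study.mask(c, a), study.mask(c, b), pair=(a, b))
            rows.append(
                {
                    "case": c,
                    "pairing": f"{a}-{b}",
                    "dice": rep.dice,
                    "assd_mm": rep.assd_mm,
                    "vol_diff_pct": rep.vol_diff_pct,
                }
            )
    per_pair = pd.DataFrame(rows)
    pairings = [f"{a}-{b}" for a, b in pairs]

    summaries = {
        pairing: {
            m: summarize(per_pair.loc[per_pair.pairing == pairing, m])
            for m in ("dice", "assd_mm", "vol_diff_pct")
        }
        for pairing in pairings
    }

    metrics = ("dice", "assd_mm", "vol_diff_pct")
    tables = {
        m: per_pair.pivot(index="case", columns="pairing", values=m)[pairings]
        for m in metrics
    }
    friedman = {m: friedman_test(tables[m].to_numpy(), alpha=alpha) for m in metrics}

    posthoc: dict = {}
    effect_sizes: dict = {}
    if intra_pair is not None:
        intra = f"{intra_pair[0]}-{intra_pair[1]}"
        if intra not in pairings:
            raise ValueError(f"intra pairing {intra} not among the studied pairs")
        inter = [p for p in pairings if p != intra]
        m_comp = len(inter)
        for m in metrics:
            cols = {p: tables[m][p].to_numpy() for p in pairings}
            posthoc[m] = pairwise_posthoc(
                cols, [(intra, p) for p in inter], alpha / m_comp, paired=True
            )
            inter_vals = np.concatenate([cols[p] for p in inter])
            effect_sizes[m] = standardized_effect(inter_vals, cols[intra])

    vol_table = study.volumes_table()
    icc_volumes = icc(vol_table.to_numpy(), alpha=alpha)

    cbrt_vol = np.cbrt(vol_table.mean(axis=1).to_numpy())
    volume_trend = {}
    for m in ("dice", "assd_mm"):
        per_case_mean = per_pair.groupby("case")[m].mean().reindex(study.case_ids)
        volume_trend[m] = slope_ttest(cbrt_vol, per_case_mean.to_numpy(), alpha=alpha)

    return RaterAgreementResult(
        per_pair=per_pair,
        summaries=summaries,
        friedman=friedman,
        posthoc=posthoc,
        icc_volumes=icc_volumes,
        volume_trend=volume_trend,
        effect_sizes=effect_sizes,
    )


def simulate_rater_study(
    truths: list[SegmentationMask],
    jitter_mm: float = 1.0,
    intra_jitter_mm: float | None = None,
    volume_bias: float = 0.0,
    seed: int = 0,
    case_ids: list[str] | None = None,
) -> tuple[RaterStudy, list[tuple[str, str]], tuple[str, str]]:
    """Simulate the four-rater design: three operators plus one repeat.

    Raters ``op1_a``, ``op2`` and ``op3`` independently perturb each truth
    with boundary jitter ``jitter_mm``.  The repeat ``op1_b`` re-perturbs
    ``op1_a``'s mask with ``intra_jitter_mm`` (a within-operator session
    effect); when ``intra_jitter_mm`` is None the repeat is instead an
    independent perturbation at ``jitter_mm`` — the exchangeable null.

    Returns the study, the four studied pairings and the intra pairing.
    """
    case_ids = case_ids or [f"case_{i:02d}" for i in range(len(truths))]
    masks = {}

    def sub_seed(*key) -> int:
        return int(np.random.SeedSequence((seed,) + key).generate_state(1)[0] % (2**31))

    for i, truth in enumerate(truths):
        first = {}
        for j, rater in enumerate(("op1_a", "op2", "op3")):
            noise = RaterNoiseParams(
                boundary_jitter_mm=jitter_mm,
                volume_bias_fraction=volume_bias,
                seed=sub_seed(i, j),
            )
            first[rater] = simulate_rater_mask(truth, noise)
        if intra_jitter_mm is None:
            repeat = simulate_rater_mask(
                truth,
                RaterNoiseParams(boundary_jitter_mm=jitter_mm, seed=sub_seed(i, 3)),
            )
        else:
            repeat = simulate_rater_mask(
                first["op1_a"],
                RaterNoiseParams(boundary_jitter_mm=intra_jitter_mm, seed=sub_seed(i, 3)),
            )
        for rater, m in {**first, "op1_b": repeat}.items():
            masks[(case_ids[i], rater)] = m

    study = RaterStudy(
        case_ids=case_ids, rater_ids=["op1_a", "op1_b", "op2", "op3"], masks=masks
    )
    pairs = [("op1_a", "op2"), ("op1_a", "op3"), ("op2", "op3"), ("op1_a", "op1_b")]
    return study, pairs, ("op1_a", "op1_b")
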