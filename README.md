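# faceatlas

Multi-atlas segmentation of face-like structures in 3D ultrasound-style
volumes, with the agreement metrics and rater-variability statistics used to
validate such pipelines.

Extracting the fetal face from a 3D ultrasound sweep is a prerequisite for
quantitative analysis of craniofacial morphology, but manual delineation
takes hours per volume and automatic methods need validation: how variable
are human raters, and how does an atlas-based segmenter improve as its
reference bank grows?  `faceatlas` implements the full computational side of
that question — the segmentation pipeline, the metrics, the experiment
harnesses and the statistics — and, because clinical ultrasound volumes are
rarely shareable, ships a seeded generator of ultrasound-like face phantoms
on which everything can be exercised and tested end to end.

## What is inside

**Pipeline.** A target volume is segmented by registering every member of an
atlas bank (already-segmented reference subjects) to it — a 12-parameter
affine stage followed by cubic B-spline free-form deformation (FFD), both
maximising normalised mutual information NMI = (H(A)+H(B))/H(A,B), the FFD
penalised by bending energy — then propagating the reference masks through
the transforms and fusing the votes.  Fusion ranks the atlases per voxel by
locally normalised cross-correlation (LNCC) against the target, keeps the
`top_k` best, and runs a STAPLE-style EM that jointly estimates the
consensus probability and each atlas's sensitivity *p* and specificity *q*;
the posterior is thresholded at 0.5.

**Metrics.** For masks M₁, M₂ with surfaces S₁, S₂ (6-neighbour boundary
voxels, distances between voxel centres in world mm):

- Dice(M₁, M₂) = 2|M₁∩M₂| / (|M₁|+|M₂|), with 0.7 ("good") and 0.8
  ("acceptable") reference thresholds;
- ASSD(S₁, S₂) = ½ (mean_{x∈S₁} dist(x, S₂) + mean_{y∈S₂} dist(y, S₁));
- diffVol = 2|V₁−V₂| / (V₁+V₂), reported as a percentage.

**Experiments and statistics.** Leave-one-out cross-validation, a
growing-atlas-size comparison (held-out cases fixed, extra subjects only as
references), and an inter/intra-rater study (three operators plus one
repeat), analysed with a tie-corrected Friedman test, Bonferroni-corrected
post-hoc tests, a two-way absolute-agreement single-measure ICC from
repeated-measures ANOVA, Kruskal–Wallis, and a t-test on the OLS slope of
agreement against the cube root of segmentation volume.  Friedman and
Kruskal–Wallis p-values are exact (full permutation enumeration) for small
tables.

## Worked example

```python
import numpy as np
from faceatlas import (AtlasBank, PhantomParams, generate_population,
                       leave_one_out, RegistrationParams)

pop = generate_population(8, PhantomParams(grid_shape=(48, 48, 48),
                                           subject_deformation_scale=3.0, seed=1))
res = leave_one_out(AtlasBank(pop.entries),
                    RegistrationParams(pyramid_levels=2, min_pyramid_factor=2,
                                       max_iterations=40, histogram_bins=32),
                    registration="affine")
print("folds:", len(res.reports), "refs per fold:", res.refs_per_fold)
s = res.summary()
print("median Dice: %.3f  median ASSD: %.2f mm" %
      (s["dice"]["median"], s["assd_mm"]["median"]))
```

prints

```
folds: 8 refs per fold: 7
median Dice: 0.875  median ASSD: 0.93 mm
```

i.e. each of the 8 synthetic subjects was segmented from the other 7; the
consensus overlaps its ground truth with median Dice 0.88 (above the 0.8
"acceptable" bar) and the surfaces sit ~0.9 mm apart on average.  With more
references or the FFD stage enabled (`registration="affine+ffd"`) the
agreement rises further.

The same pipelines are exposed on the command line:

```bash
faceatlas phantom --n 8 --shape 48 --seed 1 --out bank/
faceatlas segment --target bank/image_000.nii.gz \
                  --atlas-manifest bank/manifest.tsv --out seg.nii.gz
faceatlas metrics --a seg.nii.gz --b bank/mask_000.nii.gz --out report.json
faceatlas loo --atlas-manifest bank/manifest.tsv --out results/
```

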