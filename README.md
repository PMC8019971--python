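# t2compart

Quantitative multicomponent T2 relaxometry of multi-echo brain MRI.

Conventional FLAIR imaging shows tissue abnormality qualitatively. A 32-echo
CPMG acquisition (TE = 10…320 ms) measures the full transverse decay, which
in brain tissue is multi-exponential: myelin-trapped water (T2 < 40 ms),
intra/extracellular water (IEw, 40–250 ms) and CSF/free water (> 250 ms).
`t2compart` inverts each voxel's decay into a non-negative T2 spectrum,
corrects for stimulated echoes caused by imperfect refocusing pulses, and
maps each pool's fraction and weighted T2. The quantitative IEw-T2 map acts
as a "quantitative FLAIR": regions with subtly elevated IEw T2 can extend
beyond the FLAIR-visible abnormality (the *mismatch*), and this package
quantifies that — threshold, volume, overlap — plus the phantom machinery to
validate every stage against known ground truth.

Intended users: researchers in quantitative MRI / radiation oncology imaging
who want a tested, reproducible implementation of this analysis for
simulation studies or pre-aligned NIfTI data.

## The method

Per voxel, the signal model is

    y_k = Σ_j x_j · EPG_k(T2_j; T1, α),   x_j ≥ 0,

with the dictionary built by the extended-phase-graph (EPG) recursion over
crusher-gradient dephasing orders, so each column is the echo train of a pure
T2 pool under refocusing angle α (at α = 180° it is exactly exp(−TE/T2)).
The spectrum is the minimum-curvature regularized NNLS solution on a 200-node
log grid over [1, 3000] ms:

    min_x ‖A x − y‖² + μ ‖D₂ x‖²,   x ≥ 0,

with μ chosen by a discrepancy principle (largest μ keeping the data misfit
within 1.02× the unregularized misfit). α is estimated per voxel by scanning
the unregularized misfit over a coarse angle grid with quadratic refinement.
Pools are labeled by the 40 / 250 ms cutoffs and summarized by relative
amplitude and amplitude-weighted T2.

Downstream, the hyper-T2 segmentation threshold is found where the kernel
density estimates of IEw T2 inside and outside the tumor volume (GTV)
intersect between their modes; voxels of the clinical target volume (CTV)
above it are segmented and compared with the FLAIR mask (exclusive volumes,
overlap, Dice). See `docs/methods.md` for assumptions, parameter defaults
and known limitations.

## Worked example

```python
import numpy as np
from t2compart import (
    PhantomSpec, make_phantom, PipelineConfig, fit_volume,
    roi_distribution, find_threshold, segment_hyper_t2, mismatch_report,
)

# A 24x24x12 phantom: white matter (IEw T2 = 80 ms) with a spherical lesion
# (IEw T2 = 110 ms) whose FLAIR-positive core is smaller than the lesion.
phantom = make_phantom(PhantomSpec(seed=1))
maps, log = fit_volume(phantom.data, phantom.masks["brain"],
                       PipelineConfig(), affine=phantom.affine)
iew_t2 = maps.volumes["iew_t2"]
print(f"fitted voxels: {log['n_fitted']}, "
      f"median flip angle: {log['flip_angle_deg']['median']:.1f} deg")

gtv = phantom.masks["gtv"]
outside = phantom.masks["brain"] & ~gtv
threshold = find_threshold(roi_distribution(iew_t2, gtv),
                           roi_distribution(iew_t2, outside))
seg = segment_hyper_t2(iew_t2, phantom.masks["ctv"], threshold,
                       phantom.voxel_volume_ml)
report = mismatch_report(seg, phantom.masks["flair"])
print(f"threshold: {threshold:.1f} ms, hyper-T2 volume: {seg.volume_ml:.2f} ml")
print(f"T2-only (mismatch) volume: {report.t2_only_ml:.2f} ml, "
      f"Dice vs FLAIR: {report.dice:.2f}")
```

Output (about two minutes on one CPU):

```
fitted voxels: 2608, median flip angle: 169.9 deg
threshold: 97.3 ms, hyper-T2 volume: 3.52 ml
T2-only (mismatch) volume: 2.25 ml, Dice vs FLAIR: 0.53
```

Reading it: 2608 brain voxels were inverted; the median fitted refocusing
angle (169.9°) reflects the phantom's 180°→160° B1 ramp. The inside/outside
GTV densities cross at 97.3 ms — between the tissue (80 ms) and lesion
(110 ms) IEw T2 — and segmenting the CTV at that threshold yields 3.52 ml of
hyper-T2 tissue, of which 2.25 ml lies *outside* the FLAIR-positive core:
the quantitative map sees abnormality that FLAIR does not, which is exactly
the mismatch the phantom builds in (Dice with the FLAIR mask is 0.53 because
the segmentation correctly covers the whole lesion, not just its core).

For sklearn-style composition, `T2SpectrumFitter` is a transformer mapping
`(n_voxels, 32)` echo trains to 8 compartment features per voxel.

### Command line

```bash
t2compart simulate --out phantom/ --seed 17
t2compart fit --input phantom/echoes.nii.gz --mask phantom/mask_brain.nii.gz --out maps/
t2compart segment --iew-t2 maps/t2compart_iew_t2.nii.gz --gtv phantom/mask_gtv.nii.gz \
                  --brain phantom/mask_brain.nii.gz --ctv phantom/mask_ctv.nii.gz --out seg.json
t2compart report  --iew-t2 maps/t2compart_iew_t2.nii.gz --ctv phantom/mask_ctv.nii.gz \
                  --flair phantom/mask_flair.nii.gz --threshold 97.3 --out report.json
```

Exit codes: 0 success, 2 input error, 3 configuration error.

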