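# mwikit

Multi-echo T2 relaxometry for **myelin water imaging (MWI)**: a tested
Python pipeline from raw multi-echo GRASE decays to brain-region aging
statistics, exercised end-to-end on synthetic cohorts with known ground
truth.

## The problem

T2 relaxation in brain tissue is multi-component: water trapped between
myelin bilayers relaxes fast (T2 < 40 ms), intra-/extra-cellular water
relaxes at 40–200 ms, and CSF at much longer T2. Decomposing a 48-echo
spin-echo decay into a T2 spectrum yields two scalar metrics per voxel:

- **MWF** (myelin water fraction): the fraction of spectrum amplitude with
  15 ms ≤ T2 < 40 ms — a histologically validated myelin biomarker;
- **IET2**: the amplitude-weighted geometric mean T2 of components with
  40 ms ≤ T2 < 200 ms, sensitive to tissue water and iron.

Group studies aggregate per-subject metric maps into voxel-wise atlases and
regress region-of-interest (ROI) means on age, where healthy myelin content
follows an inverted-U trajectory: rising through the third decade, peaking
around the fifth, declining later.

## The method

Per voxel, the measured decay `y` (48 echoes, 8 ms spacing) is decomposed
onto a dictionary of **extended phase graph (EPG)** decay curves — one per
T2 on a 40-point log grid spanning 15–2000 ms — which model the stimulated
and indirect echoes produced when the refocusing flip angle α deviates
from 180°:

1. **Stimulated echo correction**: the unregularized non-negative
   least-squares (NNLS) misfit is computed at 8 candidate angles spanning
   90–180°; a cubic-spline interpolant of the misfit-versus-angle profile
   is minimized to estimate the voxel's effective α.
2. **χ²-constrained regularized NNLS**: with the basis built at α̂, solve

       min ‖A(α̂)s − y‖² + μ‖s‖²,  s ≥ 0,

   tuning μ so the data misfit χ²(μ) equals **1.02 ×** the unregularized
   minimum (bisection on log μ against the monotone χ²(μ) curve).
3. **Metrics**: MWF and IET2 from the spectrum windows above; maps are
   aggregated across co-aligned subjects into voxel-wise mean / median /
   sample-SD atlases, excluding voxels not covered by every subject.
4. **ROI statistics**: Pearson age correlations (two-sided, P < 0.01),
   quadratic multiple regression `metric ~ age + age² [+ sex]` with
   adjusted r = √(adjusted R²), and decade-binned group summaries with ROI
   rankings.

Because no individual-subject imaging data are publicly available for this
protocol, `mwikit.simulate` generates digital-phantom cohorts — three-pool
tissue, smooth B1 (flip-angle) fields, age-dependent per-ROI MWF
trajectories, Gaussian/Rician noise — so every stage is validated against
known truth.

## Worked example

```python
import numpy as np
from mwikit import (SequenceParams, FitConfig, epg_decay_curve,
                    fit_voxel, compute_mwf, compute_iet2)

seq = SequenceParams()            # 48 echoes, ΔTE = 8 ms
rng = np.random.default_rng(0)

# simulate one white-matter-like voxel: 15% myelin water (T2=20 ms),
# 85% IE water (T2=80 ms), refocusing flip 150°, first-echo SNR 200
y = (0.15 * epg_decay_curve(20.0, 150.0, seq)
     + 0.85 * epg_decay_curve(80.0, 150.0, seq))
y = np.abs(y + rng.normal(0, y[0] / 200, y.shape))

sp = fit_voxel(y)
print(f"flip estimate : {sp.flip_angle_estimate:.1f} deg")
print(f"chi2 ratio    : {sp.chi2_reg / sp.chi2_min:.4f}")
print(f"MWF           : {compute_mwf(sp):.3f}")
print(f"IET2          : {compute_iet2(sp):.1f} ms")
```

prints

```
flip estimate : 150.0 deg
chi2 ratio    : 1.0200
MWF           : 0.114
IET2          : 76.5 ms
```

The flip angle is recovered to a tenth of a degree and the regularized
misfit sits exactly at 1.02× the minimum. The fitted MWF (0.114 vs 0.15
true) shows the known shrinkage of the χ²-constrained fit on a single noisy
voxel; averaged over many voxels the bias is ≈ −0.03 at this SNR and
vanishes as SNR grows (see `docs/methods.md`).

The same stages are available from the shell:

```bash
mwikit simulate --n 10 --seed 1 --out cohort/
mwikit fit --echoes cohort/sub001/echoes.nii --mask cohort/sub001/mask.nii \
           --out-prefix out/sub001
mwikit atlas --maps out/sub001_mwf.nii --maps out/sub002_mwf.nii \
             --metric MWF --out-prefix out/mwf_atlas
mwikit roistats --cohort-dir cohort/ --out stats/
```

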