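# Methods

## Signal model

A voxel's multi-echo spin-echo decay is modelled as a non-negative mixture
of single-T2 echo trains,

    y_n = Σ_j s_j · E_n(T2_j, α) + ε_n,   n = 1..48,

where `E_n` is the EPG-predicted amplitude of echo `n` for relaxation time
`T2_j` under effective refocusing flip angle α, and `s ≥ 0` is the T2
spectrum on a 40-point log-spaced grid from 15 to 2000 ms. Echo spacing is
8 ms (first echo at 8 ms), matching the 48-echo GRASE protocol the package
targets.

### EPG recursion

The recursion tracks transverse configuration states F(k) for
k = −K..K and longitudinal states Z(k) for k ≥ 0, with K = n_echoes + 1
(exact truncation for a 48-pulse train). Each inter-echo interval applies:
half-interval relaxation (F × exp(−ΔTE/2/T2), Z × exp(−ΔTE/2/T1)), one unit
of crusher dephasing (F(k) → F(k+1)), the CPMG refocusing rotation mixing
(F(k), F(−k)*, Z(k)), the second dephasing unit and half-interval
relaxation; the echo is read at F(0). Assumptions:

- ideal 90° excitation; only the refocusing flip is variable;
- perfect crusher spoiling (the idealized-gradient EPG picture);
- longitudinal regrowth neglected within the train (amplitudes are per unit
  excited magnetization, so the model is TR-independent);
- **T1 = 1000 ms** by default. T1 is not identifiable from the echo train
  and the predicted amplitudes are only weakly T1-sensitive over the
  physiological range; the sensitivity test in the suite verifies MWF
  changes are negligible for T1 ∈ [700, 1500] ms.

The recursion is validated against a brute-force Bloch isochromat
simulation (2000 uniformly dephased spins, matched crusher scheme): maximum
absolute deviation ~1e−15, i.e. machine precision, for flips 90–165° and
T2 20–500 ms, and exact collapse to `exp(−nΔTE/T2)` at 180°.

One property worth noting: echo amplitudes are *not* monotone in T2 at
fixed echo index for reduced flips. At late echoes the surviving signal of
a short-T2 species is carried by stimulated pathways that spent intervals
stored longitudinally (decaying with T1 rather than T2), so T2 = 20 ms can
out-survive T2 = 35 ms beyond echo ~23 at flip 140°. This is physical
(confirmed by the Bloch oracle), and the test suite asserts monotonicity
only where the direct pathway dominates.

## Fitting

### Flip-angle estimation (stimulated echo correction)

The unregularized NNLS misfit is computed at 8 equally spaced candidate
angles from 90° to 180° (the spacing is a package choice; only the count
and range are protocol-specified). A cubic spline of misfit versus angle is
minimized on a 0.05° grid, and the interpolated minimizer is *verified* by
evaluating its true misfit — if it does not improve on the best sampled
candidate (spline ringing near sharp minima, e.g. an exact 180° optimum),
the sampled candidate is returned. Voxels whose misfit profile is nearly
flat (relative spread < 0.2 across candidates; pure-noise profiles vary by
a few percent, tissue decays by an order of magnitude) carry no usable flip
information and are flagged low-confidence.

Recovery accuracy is flip-dependent: ∂signal/∂α → 0 as α → 180°, so the
estimator's RMSE at first-echo SNR 100 grows from ≈1.6° at α = 120° to
≈4.9° at α = 165°, while the estimate stays unbiased. The Monte-Carlo suite
quotes RMSE at the phantom's nominal mid-range α = 150° (≈2.8°).

### χ²-constrained regularized NNLS

The spectrum solves `min ‖As − y‖² + μ‖s‖², s ≥ 0`, implemented by
augmenting the design with √μ·I rows and solving with `scipy.optimize.nnls`.
μ is tuned so the *data* misfit χ²(μ) equals 1.02 × the unregularized
minimum: χ²(μ) is monotone in μ, so the target is bracketed by geometric
expansion from μ = 1e−8·‖Aᵀy‖∞ and located by bisection on log μ to 1e−3
relative tolerance on the ratio (typically ~15 NNLS solves). Choices:

- the penalty operator is the identity (minimum-energy Tikhonov); the
  χ²-ratio interface is operator-agnostic and a curvature penalty behaves
  near-identically in our experiments;
- `chi2_factor = 1` short-circuits to the plain NNLS solution with μ = 0;
- near-exact fits (χ²min ≤ 1e−12·‖y‖²) also return μ = 0, since any μ > 0
  overshoots a vanishing target;
- degenerate decays (all-zero or non-finite) yield flagged all-zero
  spectra, never exceptions, so volume-scale fitting is total;
- fits are deterministic given the decay; all randomness lives in the
  generator, so parallel or re-ordered execution is bit-reproducible.

**Known bias.** The 2% misfit budget is spent preferentially on the small,
poorly conditioned short-T2 lobe, shrinking MWF. At first-echo SNR 100 the
mean bias is ≈ −0.03 to −0.05 across true MWF 0.05–0.20, scaling roughly as
1/SNR (≈ −0.016 at SNR 400, ≈ −0.009 at SNR 1000). This is a property of
the χ²-factor criterion itself, not of the solver: an independently coded
constrained solver, a curvature penalty, a column-equilibrated penalty and
a denser grid all reproduce it. Cohort-level age-trajectory inference is
unaffected (the shrinkage is nearly level-independent), but absolute MWF
values at modest SNR should be read with this in mind.

## Metrics

MWF = Σ s_j over 15 ≤ T2 < 40 ms divided by the full-spectrum sum
(including long-T2 amplitude); IET2 = exp(Σ s_j ln T2_j / Σ s_j) over
40 ≤ T2 < 200 ms. Both windows are half-open `[lo, hi)`; a component at
exactly 40 ms belongs to the IE window. The default grid has no point at
exactly 40 or 200 ms, but boundary behavior is defined and tested with
custom grids. Zero total (or zero in-window) amplitude yields NaN plus an
invalidity flag.

## Maps and atlases

`fit_volume` applies the per-voxel fit within a mask and writes MWF / IET2 /
flip maps (float32 NIfTI-1, NaN = invalid, affine passed through).
`build_atlas` computes voxel-wise mean, median (midpoint for even counts)
and sample SD (n−1 denominator, the group-variability convention) over
co-aligned subject maps, keeping only voxels valid in *every* subject —
partial-coverage voxels are excluded entirely, with a per-voxel coverage
count reported. Registration is explicitly upstream of this package:
inputs must share a grid (synthetic cohorts are aligned by construction).

## ROI statistics

Per subject, ROI means are taken over valid voxels; left/right label pairs
are pooled at the voxel level before averaging (each voxel weighs equally,
not each hemisphere). Analyses mirror standard practice for aging studies
of quantitative maps:

- Pearson correlation of ROI mean with age, two-sided p, significance at
  P < 0.01, no multiple-testing correction across ROIs;
- OLS of the metric on (age, age²), optionally + sex coded F = 0 / M = 1
  (inference is coding-invariant); age enters uncentered — collinearity
  between age and age² inflates per-term standard errors but not the fit,
  and per-term p-values are reported exactly as fitted;
- adjusted r = √max(0, 1 − (1−R²)(n−1)/(n−p−1));
- decade bins [20,30) … [70,80) labelled third…eighth decade of life, with
  group mean, sample SD, n and a dense ROI ranking per bin.

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
validated:

- **Geometry**: ROIs are blocks tiling the phantom's x-axis — name-mapped
  to corpus-callosum-like (genu/body/splenium), internal-capsule-like
  (an L/R pair exercising voxel-level pooling), SLF-like and gray-matter-
  like compartments. No anatomical realism is claimed.
- **Tissue**: three pools per ROI — myelin water at T2 = 20 ms, an IE pool
  at 60–90 ms (ROI-dependent), a small CSF-like pool at 1500 ms; fractions
  sum to 1 and are validated over the whole age range.
- **Age model**: per-ROI quadratic MWF trajectories peaking at age 50 with
  peak values 0.06 (GM-like) to 0.195 (splenium-like), a rise of 0.025
  between ages 20 and 50, and between-subject SD 0.012. The rise and SD
  were fixed by an a-priori power analysis (detection of the quadratic
  term at P < 0.01 with n = 100 has power ≈ 1.0) and sit inside the range
  in-vivo cohorts report for these structures. Sex has zero effect by
  default, with an effect-size knob for power studies.
- **B1**: a smooth quadratic flip-angle bowl spanning 130–170°.
- **Noise**: Gaussian on magnitude (Rician available) at first-echo
  SNR 100 by default; SNR is defined as mean first-echo phantom signal
  over noise SD.
- **Seeds**: a master seed derives per-subject seeds by counter
  (`SeedSequence([master, index])`), recorded in the demographics CSV;
  generation is bit-reproducible. Ages are stratified-uniform across
  decade bins; sex counts follow the 58:42 ratio exactly.

`generate_roi_cohort` additionally draws ROI-*mean*-level cohorts directly
from the age model (trajectory + subject noise), skipping the imaging
chain. Replicate-heavy statistical validation (power, null calibration,
rank stability) uses this path; the imaging chain's fidelity is
established separately by a full simulate → fit → regress pass over a
compact 7×7×2 phantom with 100 subjects, sized so the whole suite runs in
minutes on one core.

**What passing does and does not show.** The phantom has piecewise-constant
tissue, no partial-volume mixing at boundaries, no through-plane flip
variation, no exchange between pools, no iron effects, and Gaussian rather
than fully Rician noise statistics. Passing demonstrates the estimator
chain is correct and well calibrated under its own model; it does not
certify accuracy on in-vivo data, where those confounds are active. Note
also that the symmetric quadratic peak at age 50 makes the *linear* age
correlation vanish by construction over ages 20–78, so the synthetic
Pearson r is near zero even where the quadratic term is strongly detected;
in-vivo cohorts with asymmetric trajectories show positive linear r as
well.

## Numerical and interface choices

- T2 grid validation enforces strict log-spacing to 1e−9 relative.
- EPG bases are cached per (grid, flip, sequence); per-voxel interpolated
  angles each incur one 40-column basis build (~ms).
- Monte-Carlo suite conditions: two pools at 20/80 ms, true flip 150°,
  first-echo SNR 100, true MWF ∈ {0.05, 0.10, 0.15, 0.20}.
- The YAML config rejects unknown keys at any level; defaults are the
  protocol constants (48 echoes, ΔTE 8 ms, 15–2000 ms × 40 grid, 8 flip
  candidates, χ² factor 1.02, windows at 15/40/200 ms).
- CLI commands are idempotent and seed-reproducible; `simulate` writes
  per-subject NIfTI volumes plus demographics, `roistats` writes Pearson,
  quadratic-regression and decade-summary CSV tables.

## Known limitations

- Absolute MWF underestimation at modest SNR, as quantified above.
- Flip-angle precision degrades near 180° (identifiability, not
  implementation).
- No slice-profile or through-plane B1 modelling; no spatial or joint
  multi-voxel regularization; no pathological 200–800 ms component metric.
- The atlas stage assumes co-aligned inputs; registration quality is the
  caller's responsibility.
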