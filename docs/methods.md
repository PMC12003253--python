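# Methods

## Phantom model

The NEMA IEC body phantom is modelled parametrically. The body
cross-section is a stadium (a 70 mm straight section capped by 115 mm
radius half-discs, ~300 × 230 mm overall) extruded over a 180 mm axial
length; the lung insert is a central cold cylinder of 50 mm diameter
running the full length; the six spheres (inner diameters 10, 13, 17, 22,
28, 37 mm) sit on a 57.2 mm-radius ring at 60° spacing in one transaxial
plane, 35 mm above the axial centre. Sphere positions on the ring are a
convention — the physical phantom fixes only the ring geometry — and are
configurable. The phantom wall and the cold sphere shells are not
modelled; compartments meet directly ("hot-edge" idealization), so cold-wall
effects on recovery coefficients are absent.

Rasterization assigns each voxel the compartment occupying at least half
of its `supersampling³` regularly spaced probe points (default 3³ = 27;
spheres and lung take precedence over background). This keeps each
compartment's voxelized volume within a fraction of a voxel shell of the
analytic value and converges as the grid is refined. The default grid uses
the (1.65 × 1.65 × 1.5) mm³ reconstruction voxel with a 6 mm margin.

## Acquisition model

Activity: background at 5.3 kBq/ml, spheres at SBR × background (SBR 4
and 10), lung and exterior at zero. The image surrogate is produced by

1. blurring the activity map with an isotropic Gaussian PSF (default FWHM
   4.0 mm, a typical reconstructed resolution for a digital SiPM scanner;
   zero-padding boundary, so total activity is conserved to <0.5%);
2. converting to a per-voxel Poisson mean
   λ = c · V_voxel · t · s · f_att, with c the blurred concentration
   (kBq/ml), V_voxel the voxel volume (ml), t the frame duration (s),
   s the scanner sensitivity and f_att the habitus factor
   (thin → 1, obese → 0.53, the midpoint of the observed 52–54% count
   fraction, applied as a global scalar rather than a spatial map);
3. drawing independent Poisson counts per voxel and dividing by
   V_voxel · t · s · f_att to return to concentration units
   (`expectation` mode skips step 3 and returns the blurred map exactly).

Sensitivity is calibrated so that total expected true counts at the
reference frame hit a target — by default 35 × 10⁶ at 180 s for SBR4-thin,
the count level the ground-truth frames correspond to. Expected counts are
then exactly linear in duration and proportional to f_att between habitus
variants. Radioactive decay within and across frames is ignored: frames
are treated as rebinnings of one list-mode stream sharing a single
concentration scale.

**What the noise model does and does not emulate.** Independent post-blur
Poisson noise reproduces the two properties the benchmark rests on — the
CoV ∝ t^(−1/2) power law in uniform regions and the monotone
noise/contrast orderings across durations, contrast ratios and habitus —
but not the spatially correlated noise texture of iterative (OSEM)
reconstructions. Consequences: absolute CoV_BG levels depend on voxel
size here (no noise correlation length), absolute SSIM values against the
ground-truth frame are lower than for scanner data with smooth correlated
noise, and all such values should be read as orderings, not as scanner
predictions. Passing tests demonstrate correctness of the metric
implementations and the scaling laws, not fidelity to any particular
scanner.

Per-scan seeds derive from a master seed via `numpy.random.SeedSequence`
with the (setup, duration) index pair as spawn key: reproducible,
collision-free, and independent across the grid.

## VOIs and segmentation

Three spherical background VOIs of 131 ml are grown voxel-by-voxel around
configurable centres (default: a 75 mm ring at 120° spacing, 70 mm below
the sphere plane, clearing spheres, lung and shell by ≥15 mm); a VOI that
would leave the background compartment is an error, never silently
clipped.

Sphere masks use a background-corrected 50% adaptive threshold,
T = b + 0.5·(max − b), where b is the mean over the three background VOIs
of the reference scan and the maximum is taken inside a search region (the
true sphere dilated by 2 × PSF FWHM) so that remote noise spikes cannot
hijack the threshold. The mask is the 26-connected component above T
containing the regional maximum, ties broken by lowest linear index.
Whether the background correction in the reference tooling subtracts
before or after the 50% scaling is not documented there; the formula above
is the standard adaptive variant and is flagged as an assumption. A region
whose maximum does not exceed the background mean (beyond a 1e-9 relative
float guard) raises a "not segmentable" error, which the study runner
records as a non-detectable sphere rather than aborting.

VOI sets are segmented once on each setup's ground-truth frame and frozen
for every other frame and denoised variant of that setup; per-frame
re-segmentation is deliberately not the default, matching how a single
physical filling is analysed.

## Metrics

- CoV_BG: mean over the three background VOIs of 100·SD/mean; sample SD
  (n−1) throughout.
- CNR: (sphere VOI mean − mean of the three background VOI means) /
  (mean of the three background SDs). Equal-volume VOIs make
  mean-of-means and pooled means agree to rounding. A noiseless image
  yields ±inf, reported distinctly. Visibility: CNR ≥ 5 (Rose criterion),
  boundary inclusive.
- RC_mean/RC_max: VOI mean/max divided by the true sphere concentration.
- SUV_peak: mean over a 1.0 ml spherical neighbourhood (the common EANM
  convention; the peak sphere must be centred inside the mask). Masks
  smaller than 1 ml fall back to the mask mean with a warning.
- ΔSUV: per-sphere absolute differences of SUV_mean and SUV_max versus
  the ground-truth frame, aggregated as mean ± SD across the six spheres.
  (A voxelwise-difference reading of the aggregate is possible; the
  per-sphere VOI-statistic variant is implemented because the study
  narrative is per sphere size.)
- SSIM: 3D, Gaussian window σ = 1.5 voxels, K1 = 0.01, K2 = 0.03, mean of
  the local map over the phantom mask; data range taken from the reference
  inside the mask so the comparison depends on the reference only.
- PSNR: 10·log₁₀(peak²/MSE) over the mask, peak = SUV_peak of the 37 mm
  sphere in the reference; zero MSE serializes as `inf`.
- MAE: mean absolute voxel difference over the mask.

All metrics operate in concentration units; for a phantom, SUV is a global
rescaling under which CoV, CNR and RC are invariant and SUV/ΔSUV values
scale transparently.

## Study runner

Defaults reproduce the reference protocol: 4 setups × 13 durations
(5, 10, 20…200 in 20 s steps, 900 s) = 52 scans. Ground-truth selection
is an explicit rule: `count_target` (default, 35 × 10⁶ expected true
counts, ties to the longer frame), `cov_target`, or `fixed_duration`.
Under the default calibration this selects 180 s for SBR4-thin and 200 s
for both obese setups; for SBR10-thin it selects 180 s, whereas the
physical experiment's 140 s choice was driven by a ~25% higher fill
activity in that session, which the simulator does not model (only the
SBR-driven sphere-activity difference distinguishes the fillings here).

Gaussian post-filters are specified by FWHM (σ = FWHM/(2√(2 ln 2)),
per-axis σ in voxels, nearest-neighbour boundary so the flat background
stays flat) and applied post hoc to the surrogate — equivalent to
in-reconstruction filtering under this linear image model. External
denoisers plug in through a NIfTI file contract with a timeout. By default
the configured denoisers are applied to the anchor scan (SBR4-thin, 10 s,
the post-filter comparison condition); `denoise_scope="all"` scores them
on every scan.

The power law CoV = a·t^b is fitted by OLS on (ln t, ln CoV) with r²
computed on the log axes; exact power-law inputs are reproduced to
machine precision, and a constant series returns b = 0 with r² flagged as
NaN. Failed stages are recorded per record and the run continues. CSV
outputs are written with a fixed 6-significant-digit float format, making
reruns under the same master seed byte-identical.

## Problem sizes and numerical choices

The native (1.65 × 1.65 × 1.5) mm³ grid (~3.6 M voxels) is used where the
claim depends on resolution (the power-law fit in the acceptance script);
the test suite and examples run the same code at 2–3× coarser voxels,
which preserves every property under test (orderings, scaling laws,
invariances) at a fraction of the cost. The full metric battery in the
acceptance script runs at (3.3 × 3.3 × 3.0) mm³.

Known limitations: no scatter/randoms/attenuation physics, no TOF or OSEM
convergence effects, no noise correlations, no decay, no cold sphere
walls, no CT; absolute SSIM/CoV levels are resolution-dependent under
this noise model. These bound what the simulator can validate: metric
implementations, scaling behaviour, and relative denoiser comparisons.
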