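# Methods

## Scope and model

`cdtikit` post-processes cardiac diffusion tensor imaging (cDTI) data of
the left ventricle: multi-repetition short-axis diffusion-weighted stacks
(one b = 0 reference plus ≥ 6 encoding directions) are cleaned, averaged,
fitted voxelwise to a rank-2 diffusion tensor, and summarized as fractional
anisotropy (FA), mean diffusivity (MD) and helix angle (HA) maps with
regional statistics and interstudy (initial vs repeat scan) agreement
measures. Because no patient images are available to this package, a
synthetic left-ventricle phantom with fully known ground truth plays the
role of the acquisition; every stage is validated against that truth.

The signal model is the Stejskal–Tanner mono-exponential attenuation

    S_i = S0 · exp(−b · g_iᵀ D g_i),

with `D` the 3×3 symmetric positive-definite diffusion tensor, `b` in
s/mm² and `g_i` unit encoding directions. With six directions plus the
reference the log-linearized system

    −ln(S_i/S0) = b · [g_x², g_y², g_z², 2g_xg_y, 2g_xg_z, 2g_yg_z] · d

is exactly determined for the six unique components `d`; more directions
are handled by least squares (`numpy.linalg.lstsq` over all voxels at
once). No weighting or iterative refinement is used: with the minimal
6-direction protocol the weighted and unweighted solutions coincide.

## Phantom

Each slice is an annulus: a circular cavity (endocardial radius
`endo_radius`) inside an epicardial disk (`epi_radius`), on a
`grid_size`² grid at `pixel_spacing` mm. Defaults emulate a hypertrophic
end-systolic left ventricle imaged with a breath-hold STEAM-EPI protocol:

| parameter | default | why |
|---|---|---|
| grid_size | 48 px | covers a 54 mm epicardial disk at 2.7 mm with margin for shifts |
| pixel_spacing | 2.7 mm | acquired in-plane resolution of the emulated protocol |
| n_slices | 3 | three short-axis slices, 8 mm thick + 4 mm gap |
| endo_radius / epi_radius | 11 / 27 mm | small end-systolic cavity, 16 mm hypertrophied wall |
| b_value | 350 s/mm² | protocol diffusion sensitivity |
| directions | 6, dual-gradient set | the protocol's direction count; the published set is unknown, so a standard rank-6 scheme is used (configurable via bvec sidecar) |
| target_fa / target_md | 0.613 / 0.750·10⁻³ mm²/s | global patient values of the emulated study |
| ha_endo / ha_epi | +38.9° / −34.3° | transmural helix ramp endpoints (see below) |
| n_repetitions | 10 | repetitions per slice/direction before averaging |
| s0 / noise_sigma | 1000 / 50 | Rician noise at SNR ≈ 20, typical for this protocol |
| shift_sd | 0.3 px (~0.8 mm) | residual in-plane displacement between compliant breath-holds |
| corrupt_prob | 0.05 | occasional signal-dropout frames (artefact model) |

Per myocardial voxel the local cardiac frame is radial `r̂` (from the
slice centroid), longitudinal `ℓ̂` (apex → base) and circumferential
`ĉ = ℓ̂ × r̂`. The principal diffusion axis is
`e1 = cos(HA)·ĉ + sin(HA)·ℓ̂` with the helix angle varying **linearly in
transmural depth** from `ha_endo` to `ha_epi`; the tertiary axis is radial
(`e3 = r̂`, the histological sheet-normal convention) and `e2 = e3 × e1`
completes a right-handed frame. Eigenvalues are the axially symmetric
(prolate, λ2 = λ3) triple realizing the target FA and MD:
δ = FA/√(3 − 2 FA²), λ1 = MD(1 + 2δ), λ2 = λ3 = MD(1 − δ).

Note that because the configured angles are ramp *endpoints*, the
equal-thickness layer means of the phantom (≈ +23°, +2°, −20° at the
default geometry) sit inside the endpoints — by roughly one sixth of the
ramp — rather than reproducing the patient layer means numerically. The
ramp endpoints themselves are recovered exactly by depth regression of the
fitted HA map (the acceptance script reports both).

The transmural depth used by the ramp is the **same** distance-transform
depth the analysis pipeline computes (below), so noiseless recovery is
exact rather than limited by mask discretization.

Acquisition defects are simulated in this order: one integer-rounded rigid
translation per repetition (`round(Normal(0, shift_sd))`, applied to all
frames of that repetition — a breath-hold-level effect), a signal-dropout
band (a quarter of the rows zeroed) per frame with probability
`corrupt_prob`, then Rician noise (`|x + n1 + i·n2|`, n1,n2 ~
Normal(0, σ)). All randomness flows through one seeded
`numpy.random.Generator`; identical configs and seeds give bit-identical
series.

## Preprocessing

1. **Rejection.** Each frame is scored by normalized cross-correlation
   (NCC) against the pixelwise median of its (slice, channel) repetition
   group; frames below the threshold (default 0.90) are dropped. This is a
   reproducible stand-in for the visual artefact review used in practice.
   If every repetition of a group falls below threshold the run aborts
   with an unusable-data error naming the group. The threshold interacts
   with the shift distribution: translations ≳ 1 px blur the group median
   and depress all scores, so a harsh threshold can reject shifted-but-
   intact frames (the 0.90 default rejects many ±1 px frames at the
   phantom's sharp edges — conservative but safe; real images, with
   smoother edges, score higher).
2. **Registration.** Translation-only (no rotation): each accepted frame
   is aligned to the per-slice median of accepted b = 0 repetitions by the
   integer shift (within a search radius, default 10 px) maximizing the
   zero-mean cross-correlation, evaluated by FFT. Shifted-in pixels are
   zero-filled. Integer shifts keep registration exactly invertible,
   which is what makes the noiseless roundtrip testable to machine
   precision; sub-pixel refinement is deliberately omitted.
3. **Averaging.** Pixelwise mean over the accepted repetitions of each
   (slice, channel).

## Tensor fit and scalar maps

Voxels with `S0 < s0_floor` (default 5% of the 99th-percentile S0) are
masked out; DW intensities are clipped below at `1e-6·S0` before the
logarithm. The eigensystem is computed with `numpy.linalg.eigh`,
eigenvalues sorted descending, eigenvector signs fixed by making each
vector's largest-magnitude component positive (outputs are then
deterministic; HA is invariant to this choice anyway).

Noise can produce negative eigenvalues. Repair is a single pass: each
negative eigenvalue of rank k is replaced by the mean of the rank-k
eigenvalues over the in-plane 8-connected masked neighbours whose own
rank-k value is non-negative, or by 0 if there is no such neighbour.
Cross-slice neighbours are excluded (slices are 12 mm apart).
FA = √(3/2)·‖λ − λ̄‖/‖λ‖ (clipped to [0, 1], 0 for an all-zero triple) and
MD = (λ1+λ2+λ3)/3 are computed after repair.

## Helix angle and regions

HA is the angle between the short-axis plane and the projection of e1
onto the local tangent (ĉ–ℓ̂) plane: `v = e1 − (e1·r̂)r̂`, sign-flipped so
`v·ĉ ≥ 0`, `HA = atan2(v·ℓ̂, v·ĉ)` in degrees ∈ [−90°, +90°], with
HA := +90° at `v·ĉ = 0`. Right-handed (endocardial) helices are positive,
left-handed (epicardial) negative — Streeter's convention. Voxels with a
vanishing projection (‖v‖ < 1e-9) or degenerate leading eigenvalues
(λ1 − λ2 < 1e-12 mm²/s) are masked unreliable. The tangent plane uses the
centroid-radial approximation of the endocardial tangent; a true
contour-normal refinement would matter for non-circular geometries but is
an extension, not implemented.

Transmural depth is `d = EDT_endo/(EDT_endo + EDT_epi)` from per-slice
Euclidean distance transforms (distance to the cavity and to the outside
of the epicardial disk). Layers are thirds with half-open boundaries
(endo: d < 1/3; meso: 1/3 ≤ d < 2/3; epi: d ≥ 2/3). Walls are four 90°
azimuthal sectors anchored on a user-supplied RV (septal) azimuth, the
septal sector centred on it and the lateral sector opposite; papillary
exclusion is delegated to the input masks.

## Reproducibility statistics

Per region (global, per slice, per wall; for HA crossed with layers) the
per-subject mean is the unweighted voxel mean. Paired initial/repeat
cohorts are compared per region by: mean difference (scan1 − scan2), SD of
the difference (n − 1 denominator), Bland–Altman 95% limits of agreement
(bias ± 1.96·SD), and CoV = 100·SD-of-difference/pooled-mean, where the
pooled mean averages all values from both scans. The CoV is flagged
incalculable when |pooled mean| < 10% of the largest regional mean in the
table — the mesocardial helix angle is the canonical case, its mean
approximating zero as the helix crosses from right- to left-handed.
CoVs are compared with a two-sided variance-ratio test on mean-normalized
variances, F = (SD₁/mean₁)²/(SD₂/mean₂)² on (n−1, n−1) degrees of
freedom; whether such a test should normalize by the mean at all is
ambiguous for angle-valued maps, which is one reason HA CoVs are not
reported.

The simulated paired cohort adds, per scan, a global offset ~
Normal(0, between_scan_sd) to every regional mean — the day-to-day
component (physiology, slice positioning, calibration) that dominates
interstudy variation in practice. Its defaults are calibrated so the SD of
the between-scan difference matches the values reported for this protocol
in patients (0.045 for global FA, 0.135·10⁻³ mm²/s for global MD, ≈3.4°
for HA layers): per-scan SD = reported SD/√2. Without this component the
phantom's regional means are far more reproducible than any real scan
(voxel noise averages out over ~800 myocardial voxels), and the relative
ordering of FA and MD reproducibility would be left to chance rather than
reflecting MD's greater sensitivity to global scan-to-scan effects.

## What the phantom does and does not emulate

Captured: the attenuation physics and protocol parameters, Rician
magnitude noise, breath-hold translations, dropout artefacts, the
transmural helix structure, and day-to-day regional variation at reported
magnitudes. Not captured: EPI/k-space artefacts (ghosting, distortion,
GRAPPA residuals), cardiac strain and through-plane motion, coil
sensitivity profiles (so no spatially varying SNR), non-circular LV
cross-sections, papillary muscles, and true subject-to-subject anatomical
variation. Passing tests therefore demonstrate the correctness of the
*post-processing arithmetic and conventions* under controlled conditions,
not the clinical robustness of the acquisition.

## Numerical choices and degenerate inputs

- Signal floor 1e-6·S0 before the log; S0 mask 5% of robust max.
- Eigenvalue-repair fallback to 0 when a voxel has no valid neighbour.
- FA of an all-zero eigensystem is 0 by convention; FA clipped to [0, 1].
- HA tie `v·ĉ = 0` → +90°; degenerate λ1 ≈ λ2 voxels masked, not guessed.
- Registration search limited to ±radius; ties broken by first maximum
  (deterministic row-major order).
- Limits-of-agreement multiplier fixed at 1.96; SDs use n − 1 throughout.
- Problem sizes: the default cohort analyses use 10 subjects at the full
  protocol and 50 subjects for the noise-free variance-recovery check;
  one full-protocol study takes ~0.15 s, keeping suites and the
  acceptance script in the seconds-to-minutes range.

## Known limitations

- The rejection threshold/shift-amplitude interplay described above: NCC
  against a blended median under-scores large shifts; registering before
  rejection would avoid it but inverts the established order (reject,
  then co-register, then average).
- Layer statistics average voxel HA within equal-thickness thirds; with a
  linear ramp this under-represents the endpoint angles, and equal-
  thickness rings of a thick annulus have distinctly unequal areas (outer
  rings are longer), so the three layers do not hold equal voxel counts.
- The centroid-radial frame assumes near-circular cross-sections.
- CoV-based comparisons are undefined for zero-mean quantities; the
  variance-ratio construction on CoVs is one documented choice among
  several.
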