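# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `xpct` pipeline, in the order data flows through it.

## Acquisition geometry

All derived optics quantities are pure functions of five inputs: photon
energy E, physical detector pitch dx, binning, source–sample distance z01
and source–detector distance z02. Wavelength uses hc = 12.3984 keV·Å.
Cone-beam magnification is M = z02/z01; the Fresnel scaling theorem maps a
cone-beam recording onto a parallel one at effective pixel dx_eff = dx·bin/M
and effective distance z_eff = z12/M, so every downstream filter is written
in terms of the single dimensionless Fresnel number F = dx_eff²/(z_eff λ).
Regime thresholds (F < 0.1 holographic, F < 10 direct contrast, else
absorption) are package conventions: the physics only pins down F ≪ 1 and
F ≈ 1, and the classifier is advisory — retrieval methods are selected per
instrument preset, not from the classifier.

Lab microCT presets store full distances and derive everything; synchrotron
presets store published effective pixel sizes and Fresnel numbers directly
and are marked `verified: false`, because their source distances are
reported in mixed conventions upstream and do not re-derive cleanly.
Polychromatic lab sources are represented by one effective energy.

## Synthetic phantom

The phantom reproduces the geometric and statistical structure the
operators care about, not cochlear anatomy: a conical spiral channel
(scalae) split into three sub-channels by two thin membranes (≤ 2 voxels,
enforced by a nearest-centreline assignment so sheets cannot stack), a
bone-like shell, and non-overlapping spherical blobs standing in for SGN
somata, placed by rejection sampling in the modiolar region with minimum
centre separation r₁ + r₂ + 1 voxel. Soma radii are drawn from
N(10 µm, 3 µm) truncated below at half the mean — cell bodies have a
biological size floor, and sub-resolution blobs would say nothing about the
detector. Every blob is recorded with centre, radius, analytic volume and
sphericity 1 in a ground-truth table.

Optical constants are tabulated at 10 keV with δ ~ 1e-6 (soft-tissue scale)
and scaled by 1/E². Within one embedding preset **all materials share one
δ/β ratio** (methanol 15, stained/resin 27, cleared/DBE 45, matching the
ratios used for single-material CTF retrieval of these preparations). This
makes the homogeneous-object assumption of the retrieval filters exact for
the contrast against the embedding medium — deliberately so: it lets the
matched-retrieval tests measure algorithmic error rather than model-mismatch
error. Real tissue violates homogeneity; the tests therefore do not bound
retrieval error on real heterogeneous samples. Decalcified bone is given
near-soft-tissue contrast (the imaged cochleae are demineralized).

Grids are (z, y, x), 0-based, voxel centres on integer coordinates. The
in-plane rotation centre for projection and reconstruction is (n//2, n//2).

## Forward model

Projection approximation (rotate by trilinear interpolation, integrate
along x) followed by single-FFT paraxial Fresnel propagation with the
transfer function exp(−iπ(fx²+fy²)/F), f in cycles/pixel. Propagation pads
reflectively to 2× per axis by default; pad = 1 gives periodic propagation,
which conserves energy exactly for pure-phase objects and is used when a
test needs exact unitarity. Detection multiplies by an illumination field,
scales by a photon budget and Poisson-samples; read noise and detector blur
are not modelled. Continuous-rotation blur is not modelled: each angle is
instantaneous. Multi-distance plans derive one Fresnel number per distance
through the geometry; tiled plans shift the sample laterally and record
flat/dark sessions per tile plane, mirroring stitched-scan protocols.

An analytic cone-beam projector for uniform spheres (closed-form chord
lengths) serves as an independent oracle for the cone reconstruction tests.

## Preprocessing

Plain flatfielding is (p − dark)/(flat − dark) with degenerate pixels set
to 1 and counted. PCA flatfielding builds the mean flat plus the leading
SVD modes of the flat stack and fits per-projection coefficients by least
squares on a sample-free margin band (default 5% of each edge) — the
sample-agnostic variant. Ring removal subtracts, per detector column, the
difference between the angle-averaged profile and its moving-median
smoothing, preserving the sinogram mean; it removes isolated miscalibrated
columns exactly when the underlying profile is locally smooth.
`reference_to_margin` pins the arbitrary offset of retrieved phase maps to
sample-free detector rows, which also makes sinograms consistent with a
compactly supported reconstruction.

## Phase retrieval

All filters are diagonal in Fourier space with χ(f) = π(fx²+fy²)/F.

- **ctf_single**: φ̂ = D·FT[I−1]/(2D² + α(f)), D = sin χ + (β/δ)cos χ.
  The regularizer is two-band: α_low below the first CTF maximum
  (χ = π/2), α_high above, blended by a logistic in radial frequency of
  width 10% of the transition radius. Defaults (1e-3, 1e-1).
- **ctf_multi_cg**: multi-distance least squares
  φ̂ = ΣDⱼFT[Iⱼ−1]/(2ΣDⱼ² + α) as the initial estimate, then conjugate
  gradients on the quadratic objective Σⱼ‖Cⱼφ − (Iⱼ−1)‖² + α_low‖φ‖²
  (Cⱼ the linearized CTF operator). The objective is monotonically
  non-increasing; an increase triggers rollback and stop. A defocus series
  is judged free of common CTF zeros by min over the band above the first
  CTF maximum of Σⱼ sin²χⱼ (below that band no distance has crossed a zero
  and the absorption coupling carries the signal).
- **paganin / gpm**: single-material filter 1/(1 + (δ/β)χ) followed by
  −ln(·)/μ, μ = 4πβ/λ. The generalized variant replaces χ by the discrete
  Laplacian symbol (1 − cos averaged over axes appropriately), which
  converges to χ at O(dx²) and suppresses less near Nyquist.
- **bac**: modified-Bronnikov phase φ̃ = IFT[FT[I−1]/(f² + α)] (f in
  cycles/pixel, prefactors absorbed into α), then division of I by
  1 − γ∇²φ̃ with a 5-point Laplacian, clipped at ε with a clip count.
  α and γ are free parameters; `tune_bac_gamma` picks γ by total-variation
  minimization as a deterministic surrogate when no reference is available.

Method selection per instrument follows the published per-configuration
table (holographic cone beam → multi-distance CTF CG; single-distance
synchrotron scans → CTF; white-beam wiggler → GPM; liquid-metal-jet
direct-contrast microCT → BAC; high-energy absorption scans → none). The
nano-imaging preset expands its published Fresnel number into a nominal
4-plane defocus series (geometric spread ×1…×2.6) whose CTF zeros do not
coincide.

## Reconstruction

Parallel FBP delegates to scikit-image's `iradon` (Ram-Lak, linear or
cubic interpolation, `circle=True`) behind `fbp_parallel`, with the angle
convention matched to the package's projector. FDK is implemented here
(no FDK in the installed stack): cosine pre-weighting, the band-limited
spatial ramp kernel (identical to the FBP filter, so the two agree in the
parallel limit), and voxel-driven bilinear backprojection with U² distance
weighting on a virtual detector through the rotation axis; full-circle
scans only. Inside the inscribed reconstruction cylinder the parallel limit
of FDK matches FBP to ~1e-6 relative. Binning is k³ block averaging.

## Stitching

Rigid translations only — the synthetic tiles are undeformed, so a
non-rigid model would fit nothing. Pairwise offsets maximize normalized
cross-correlation of mean-subtracted overlaps over integer offsets within a
search radius (ties toward the nominal offset; optional parabolic sub-voxel
refinement); global positions solve the least-squares consistency system
with tile (0,0,0) anchored at the origin; fusion uses linear feathering
with weights that sum to one wherever tiles cover. The 4-fold binned fused
volume is the low-resolution overview/look-up volume.

## Morphometry

Seeds are local maxima of scale-normalized (negative) Laplacian-of-Gaussian
responses (σ = r/√3), non-maximum-suppressed within the detected radius and
ordered deterministically. Watershed splitting is marker-controlled on the
smoothed inverted intensity; unlabeled foreground (disconnected from all
seeds) is assigned to the nearest label so labels always partition the
foreground. Surface area comes from a marching-cubes isosurface after mild
Gaussian pre-smoothing (σ = 0.6) of the binary mask: unsmoothed marching
cubes overestimates curved surface area by ~9% (staircase), while σ = 0.6
recovers digital-ball sphericity to within 2% and large-cube sphericity to
within 2% of the analytic 0.806. Sphericity of objects below roughly 30
voxels remains unreliable (discretization biases it high); classification
windows should use a volume floor alongside the sphericity band. Mask
keyframes interpolate by signed-distance blending; region growing is
26-connected with a running-region-mean acceptance rule.

## Problem sizes used in validation

The validation suite runs at desk scale by design: 64³ phantoms for unit
tests, a 128³ phantom with 360 angles over 180° for end-to-end recovery
(≥ ~200 angles satisfy the sampling condition for a 128-pixel detector),
20 noise realizations for the multi-distance comparison, and the default
256³ / 200-soma phantom for morphometry. The end-to-end recovery runs at
F = 0.05: on a 128² detector grid the CTF zero rings of smaller Fresnel
numbers are wide relative to the spectrum (ring width scales with 1/n) and
single-distance retrieval irreversibly loses the object band they cover;
at F = 0.05 the zeros sit above the phantom's spectral content. On real
2560²-class detectors this discretization effect is far weaker.

## Known limitations

- No partial coherence, source size, detector PSF, or polychromatic
  forward model; one effective energy per scan.
- CG refinement operates on the linearized CTF model, not the nonlinear
  propagator; strongly non-weak objects are outside its regime.
- Rigid stitching only; no intensity harmonization beyond feathering.
- The phantom's homogeneous-ratio materials make matched-retrieval tests
  optimistic relative to heterogeneous real tissue (see above).
- Sinogram-level ring removal assumes rings arise from per-column gain
  offsets; scintillator blotches with angular dependence are out of scope.
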