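# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `pclar`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Forward scattering model

Homogeneous spheres are treated with Lorenz–Mie theory. The size parameter
uses the wavelength in the medium, x = π d n_medium / λ_vacuum, and the
relative refractive index is m = n_particle / n_medium (Im m ≥ 0 =
absorption). Expansion coefficients a_n, b_n are computed with the
logarithmic derivative D_n(mx) by downward recurrence started 16 orders
above max(N, ⌈|mx|⌉), with Riccati–Bessel ψ_n(x), χ_n(x) by upward
recurrence — the standard numerically stable route for x up to a few
hundred. Truncation follows the Wiscombe criterion
N = ⌈x + 4.05 x^{1/3} + 2⌉; a guard rejects x > 10⁴. An index-matched
sphere (m = 1) short-circuits to zero coefficients.

Amplitude functions and Mueller elements follow Bohren & Huffman:
S11 = ½(|S1|²+|S2|²), S12 = ½(|S2|²−|S1|²), S33 = Re(S2S1*),
S34 = Im(S2S1*). All Stokes vectors are expressed in the scattering-plane
frame; "45° linearly polarized" illumination means 45° to that plane, i.e.
incident [1, 0, 1, 0], so the scattered linear parameters are q = S12/S11
and u = S33/S11. The fourth Stokes component V = −S34/S11·I is physically
present but never measured (the sensor has only three linear analyzer
rows); consequently the correct full-polarization identity is
q² + u² + v² = 1 — **not** q² + u² = 1, which fails badly wherever S34 is
large. The test suite asserts the three-term identity (equivalently
S11² = S12²+S33²+S34², which holds to ~1e−15 relative) and keeps
q² + u² ≤ 1 as an inequality.

Verification is two-route: the recurrence implementation is compared
against coefficients evaluated independently with arbitrary-precision
Riccati–Bessel functions (mpmath at 30 significant digits, direct Bessel
evaluation rather than recurrences) and against Rayleigh closed forms at
x = 0.01.

### Angle grid

1458 pixels map linearly onto [60°, 120°], both endpoints included, i.e.
60/1457 ≈ 0.0412°/pixel. (A nominal per-pixel resolution of ~0.08° is
sometimes quoted for such sensors; it is geometrically inconsistent with
1458 pixels over 60° and the consistent value is used.) Pixel index is
1-based; pixel 1 → 60°, pixel 1458 → 120°, fractional indices interpolate.
Whether pixel index ascends or descends with angle is configurable
(`DetectorConfig.angle_ascending`, default ascending).

## Virtual instrument

The detector model has 4 × 2048 pixels, rows filtered at 0°, 135°, 90° plus
an unfiltered row (generated but unused downstream), frame rate up to
70 kHz (default 20 kHz), 12-bit quantization, and a centered 1458-pixel
active window (indices 296–1753). A polarizer row at angle φ with per-pixel
angle error δ and extinction ratio e registers

  counts = gain · ½[(1 + 1/e)·I + (1 − 1/e)(Q cos2(φ+δ) + U sin2(φ+δ))],

so an ideal detector inverts exactly under the three-row reconstruction.
The noise model is the minimal physical one: Poisson shot noise on expected
counts, additive Gaussian read noise (default σ = 2 counts), then uniform
quantization with saturation logged (not fatal). Randomized "production
deviations" draw gains uniformly in 1 ± 10%, polarizer-angle errors in
± 3°, extinction 200:1 — the perturbation ranges used throughout the
calibration studies.

Particle transits have Gaussian temporal envelopes with FWHM = transit
duration (default 4 ms — the observed transit scale; only the pulse shape
is qualitative, so a smooth two-parameter envelope is used). An event's
`peak_amplitude` is defined as the pulse height of the pixel-averaged
intensity trace in multiples of the background level (default background
50 counts), which makes the detection threshold analysis exact. The event's
angular intensity profile (S11, normalized to unit pixel mean) and its
(q, u) polarize the signal; the background is unpolarized. Events may not
overlap in time (single-particle regime) unless explicitly allowed.

Long-duration detection studies use `generate_mean_trace`, which produces
the pixel-averaged trace Ī(t) directly with the equivalent statistics
(background + envelopes + pixel-averaged shot/read noise); full 4×2048
frame synthesis is exercised on short streams where the per-pixel path
matters. This keeps hundred-seed, 10-second studies at 20 kHz tractable
while testing the identical detection code path.

## Calibration

The linear Stokes vector is reconstructed from the three analyzer rows as
I = I0 + I90, Q = I0 − I90, U = I0 + I90 − 2·I135. Calibration uses a
rotating-polarizer sweep of 18 fully linear states (0°..170° in 10° steps);
the reference states are the ideal rotating-polarizer model (a commercial
reference polarimeter is emulated, not required). Per pixel,
A = S_meas · pinv(S_ref) is fitted by pseudoinverse. The correction applies
pinv(A) to measured vectors — the direction that returns the training sweep
to its reference (the fit direction alone does not define the correction;
this is the only consistent choice). Corrected vectors violating
√(Q²+U²) ≤ I are clipped to the physical cone with a logged warning;
condition numbers are recorded and a configurable bound (default 1e8)
rejects ill-conditioned matrices. Sweeps are averaged over 64 exposures at
~2000-count intensity, enough that residual noise in the validation beam is
a small fraction of the tolerance bands used in the recovery studies.

DoLP = √(Q²+U²)/I; AoP = ½·atan2(U, Q) in degrees mapped to [−90°, 90°)
(the two-argument form resolves the Q < 0 ambiguity of a naive
arctan(U/Q); the 90° boundary maps to −90°). AoP of an unpolarized beam is
an error, not a number.

## Pulse pipeline

Per frame and per active pixel the Stokes triple is reconstructed,
calibrated (identity matrix in uncalibrated mode), and split into a
detection intensity (background kept) and a signal triple (per-pixel
temporal median subtracted). The median subtraction matters: the
unpolarized background otherwise dilutes q and u wherever the particle
signal is weak. q and u are ratios of the background-subtracted Q, U to the
background-subtracted I, clipped to [−1, 1], with a small intensity floor
guarding the division.

Detection operates on Ī(t), the arithmetic mean over the 1458 active
pixels. The background estimate is the trace median (pulses are sparse;
a fixed value is available), and the threshold is 8× the background —
multiplying the background mean, not a noise floor. Contiguous
supra-threshold runs separated by ≤ 10 samples (configurable) merge; each
run yields one pulse with boundaries at the run's first/last samples and
the peak at its maximum. Sub-threshold pulses are excluded by construction.

Within a pulse window, Ĩ(n), q̃(n), ũ(n) are plain unweighted time means
of the per-frame values; an intensity-weighted mean (equivalent to
averaging Q and I separately before dividing) is available behind a flag
and reduces noise at deep intensity minima. At the signal levels studied
(peak ≥ 10× background) the plain mean reproduces the forward model with
RMSE < 0.01, so the simpler rule is the default. Relabelling pixel 1..1458
to 60°..120° yields the particle's profile.

## Classification

q and u concatenate to a 1 × 2916 vector, are mapped affinely from [−1, 1]
to [0, 1] (fixed map, not per-image min–max, so absolute polarization
levels stay informative) and reshaped row-major into a 54 × 54 image — an
exact bijection. Angular selection strategies subset the pixels before the
same affine map: single 120° (2 values), discrete 60°/90°/120° (6),
half-ranges partitioned at 90° by angle (θ ≤ 90° → pixels 1–729;
729 + 729 = 1458, no shared pixel), and the full range.

The classifier is a compact dense network (scikit-learn MLP: one hidden
layer of 128 ReLU units, adaptive-moment optimizer, ≤ 60 epochs,
cross-entropy), operating on the flattened feature image; low-dimensional
strategies feed the same head directly. It is deterministic for a fixed
seed. A deeper convolutional architecture adds nothing measurable on the
synthetic benchmark, where the dense head already saturates well above the
0.90 target — the feature realignment, not the network family, carries the
method.

The six-class synthetic benchmark (the laboratory specimens are not
publicly available) mirrors the specimens' property spread: PS 5 μm and
10 μm (n = 1.598), SiO2 10 μm (1.451 + 0.003i), microalgae effective-sphere
proxies 20 μm (1.37 + 0.004i) and 30 μm (1.35 + 0.004i), and a porous
proxy derived from PS10 by ≈2° boxcar smoothing plus a random amplitude
damping in [0.7, 0.9] — emulating the weaker angular oscillations of a
structured particle. Per-particle log-normal size jitter (CV 3%) and
additive N(0, 0.02²) noise on q and u emulate population spread and
measurement error. These are the study conditions; they are not tuned per
test. What passing shows: the pipeline separates size/index/structure
differences of this magnitude under this noise. What it does not show:
performance on real biological shape/internal-structure variability, which
no effective-sphere proxy reproduces.

Mixture composition classifies each extracted profile and reports counts,
proportions and multinomial standard errors √(p(1−p)/n).

## Inversion

The objective is the angle-mean of (q_obs−q_sim)² + (u_obs−u_sim)², q and
u equally weighted; intensity is excluded because its absolute scale is
uncalibrated in the measurement. An optional boxcar smoothing of the
simulation mimics pulse-averaged angular blurring. Fitting is exhaustive
over a (d, Re n, Im n) grid — the full objective surface is retained for
identifiability diagnostics — followed by optional Nelder–Mead refinement
from the best node, clipped to the grid hull. A minimum on the grid
boundary raises a warning recommending range extension.

The documented default grid (d 2–40 μm step 0.25; Re n 1.33–1.65 step
0.002; Im n 0–0.01 step 0.0005) spans all specimen families at ~10⁶
forward evaluations; the recovery studies use focused grids around the
target family with a prebuilt `ForwardGrid` cache (float32, q and u only)
so that repeated noisy retrievals amortize the forward cost. With σ = 0.02
noise the objective floor is 2σ² = 8×10⁻⁴; retrieval of a 30 μm,
n = 1.359 + 0.0045i sphere is exact in the noiseless case and
median-accurate to well under 2% in diameter across seeds. For
non-spherical particles the result is an effective sphere only.

## Porous-sphere geometry

The porous model starts from a solid 10 μm sphere and iteratively (50×)
subtracts 200 spheres of 0.4 μm diameter centered on the *current* surface.
"Surface" is operationalized as boundary voxels (occupied, ≥ 1 empty
6-neighbor) of a working lattice at spacing = small_diameter/4 = 0.1 μm;
centers are drawn uniformly from boundary-voxel centers using integer RNG
draws only, so a fixed seed reproduces the build bit for bit across
platforms. Duplicated draws within an iteration are permitted (they are
measure-zero physically and keep the draw purely integer). Subtraction is
lazy in continuous space — a point is inside the model iff inside the host
and outside every subtracted sphere (KD-tree nearest-center query) — so
voxelization at any spacing is exact with respect to the model; membership
uses squared-distance comparisons for bitwise consistency across code
paths. Porosity is reported as void fraction of the host sphere counted on
a common lattice; it is zero without erosion, monotone in iteration count,
and stable to < 0.02 between 0.1 and 0.05 μm spacings. The export format
is a commented ASCII dipole list (`ix iy iz` per occupied voxel) that
round-trips losslessly; the electromagnetic DDA solve itself is out of
scope (x ≈ 79 requires cluster-scale solvers).

## Numerical and engineering choices

- Text artifacts (profiles, pulse tables, calibration matrices) use '.'
  decimals, UTF-8, LF endings, floats at 17 significant digits; profile
  reading uses round-trip float parsing, so file round trips are exact.
- Raw streams persist to chunked HDF5 (a runtime artifact only).
- Study sizes in the test suite (e.g. 300 images/class for the
  classification benchmark, 10-second traces for detection studies,
  focused inversion grids) are chosen as the smallest populations at which
  the measured quantities are stable; the generators scale to larger runs
  unchanged.
- Degenerate inputs fail loudly: empty angle grids, rank-deficient
  calibration sweeps, all-supra-threshold traces, eroded-to-empty
  geometry, out-of-range pixels, overlapping transits.

## Known limitations

- No optical ray tracing of the collection optics or cylindrical-lens PSF;
  the pixel-to-angle map is ideal and linear.
- No coated spheres, size-distribution averaging, or T-matrix/non-spherical
  exact solvers; biological particles enter only as effective spheres.
- The experimental study's measured accuracies cannot be reproduced here —
  its raw data are not deposited — so classification/mixture results on
  the synthetic benchmark are surrogates for behavior, not reproductions
  of reported numbers.
- Coincident (overlapping) transits are rejected, not deconvolved.
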