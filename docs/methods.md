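# Methods

This note records the models behind each analysis, the synthetic-data
generators used to validate them, the numerical choices, and what passing
tests do and do not demonstrate.

## Data model and units

A trajectory is a static topology (particles with species DOPC/RHB/WATER/ION,
role, molecule id, leaflet label, charge, mass) plus a dense
`(frames, particles, 3)` coordinate array with per-frame box edges and times.
Internal units are Å, ns, elementary charge and amu everywhere; conversions
live in `memprobe.units` (1 μm²/s = 0.1 Å²/ns; e/(ε₀·Å) = 180.95 V;
1 e·Å = 4.803 D). Coordinates are stored wrapped; analyses that need
continuous paths unwrap explicitly. All distances under periodic boundaries
use the minimum-image convention.

Leaflets are assigned from the sign of each lipid's time-averaged phosphate
offset from the instantaneous midplane (the mean z of all phosphates).
Transbilayer flip-flop is not modelled — phosphocholine flip-flop times are
orders of magnitude beyond the hundreds of nanoseconds these analyses
target — so a lipid that disagrees with its label in more than 10% of frames
only triggers a warning.

## Synthetic bilayer generator

The generator emulates the statistical structure the analyses assume, not
the mechanics that produce it:

* Phosphates sit at z = ±thickness/2 with independent per-frame Gaussian
  jitter (default thickness 38.6 Å, jitter 1 Å).
* Lateral motion is an independent 2D Brownian walk per lipid with
  per-species D (defaults: DOPC 8.4, RHB 6.7 μm²/s; steps
  σ = √(2D·dt) per axis), wrapped into the box. With `aggregate_rhb` the
  upper-leaflet dye lipids rigidly share a single walk — a persistent
  cluster diffusing as one object.
* The optional cage model makes each lipid an Ornstein–Uhlenbeck
  displacement (relaxation rate `trap_strength`, stationary variance
  D_local/k per axis) about a tether that itself diffuses with `cage_D`.
  This reproduces the qualitative sub-linear MSD below ~10 ns seen in
  bilayers without claiming a molecular mechanism; it is off by default,
  and the generator makes no claim about the anomalous exponent.
* If an order-parameter profile is requested, each lipid carries one C/H
  pair per chain carbon whose CH vector lies on the cone
  cosΘ = √((2S+1)/3) about the normal (so ½(3cos²Θ−1) = S exactly), with
  the azimuth uniform and resampled every frame. Chain vectors are
  attached statistical objects, not mechanically coupled degrees of
  freedom; the analyses decouple in exactly this way.

Defaults are the study conditions the estimators are meant for: 200 lipids
per leaflet in a 116.79 Å box (ApL 68.2 Å²), 2% dye fraction, 1001 frames at
0.1 ns.

## Water, ions and charges

Water oxygens follow a z-profile that is bulk density (default 0.0334 Å⁻³)
outside the membrane and drops sigmoidally across each interface (width
4 Å, measured from distance to the bilayer center minus half the
thickness). A localized excess of amplitude A is supported inside a stated
z-band and lateral cylinder; it is implemented as a multiplicative band-flat
excess A·ρ_base(z), so the band-averaged enhancement equals A by
construction. The total molecule count is fixed at the profile's expectation
(a canonical rather than grand-canonical sample, keeping the particle count
constant across frames) and a per-frame binomial split allocates molecules
between the base slab and the enhancement component, which keeps both
expected occupancies exact even when the cylinder holds only a few
molecules. Positions are resampled independently every frame: the slab is an
equilibrium ensemble with no water dynamics, sufficient for every profile
analysis here and deliberately useless for water transport questions.

Each water gets two hydrogens at rigid 3-point geometry (0.9572 Å,
104.52°, q_H = 0.417 e, dipole 2.35 D). Dipole orientation is sampled per
z-band from the linear density (1 + 3b·cosθ)/2, whose mean cosine is b;
this representation requires |b| ≤ 1/3, enough for the interfacial biases
of interest. Ions are uniform with charge +1 e; the default box height
(100 Å) leaves ~30 Å of water beyond each phosphate plane so the bulk
normalization band (+22 to +28 Å from the P plane) is genuinely bulk.

## Structural estimators

* **ApL** divides the mean lateral box area by the lipids in one leaflet;
  with a constant box the standard error is exactly zero.
* **Thickness** averages the difference of per-frame leaflet phosphate
  means, so it is invariant under global z-translation.
* **RDF** uses lateral (XY) minimum-image distances with 2D annulus
  normalization against the leaflet's areal density, computed per leaflet
  and then averaged — matching the quasi-planar geometry. A 3D
  spherical-shell variant sits behind a flag. Defaults dr = 0.1 Å,
  r_max = 20 Å; r_max must stay below half the lateral box edge.
* **S_CD** pairs C and H particles by (lipid, chain, carbon) and averages
  ½(3cos²Θ−1) over lipids and frames. Values are reported signed, not
  clamped to the typical 0–0.5 magnitude range.
* **Coordination numbers** count neighbours within a 3D cutoff, averaged
  over centers and frames. An empty neighbour selection counts zero; an
  empty center selection is an error.
* **Cluster detection** declares two dye lipids in contact when any
  inter-particle distance falls below the cutoff (default 4.5 Å — "contact"
  has no standard definition, so it is configurable) within the same
  leaflet, and reports connected components per frame.

Scalar uncertainties use standard errors over 8 contiguous frame blocks,
the common block-averaging practice for correlated MD series.

## Diffusion pipeline

Unwrapping adds ±L to frame-to-frame lateral displacements that exceed half
a box edge; a raw displacement of half an edge or more is an undersampling
error because the correction would be ambiguous. The MSD is time-origin
averaged over all origins at every multiple of the frame spacing, computed
per particle with the FFT correlation identity (verified against the O(N²)
double loop to 1e-10). Before averaging, the mass-weighted lateral center of
mass of the whole system is subtracted frame by frame; with a single mobile
species this removes only ensemble-mean noise, but it protects against
collective drift.

D comes from an ordinary least-squares line on the 11–50 ns lag window with
a free intercept: a caged short-time transient shifts the linear regime
upward, and a free intercept absorbs that offset without biasing the slope
(the cage test checks that caged and pure-Brownian ensembles fit to the
same D within noise). Whether to force a zero intercept was an open choice;
free is the robust reading of "linear fitting", and the intercept is
reported. Uncertainties come from refitting partitions: contiguous time
blocks (each must still cover the window — the error message suggests a
rescaled window otherwise), particle groups, or leaflets; the estimate is
the partition mean and the error the sample SD/√n. Single-path estimates
(e.g. one rigid aggregate) are intrinsically noisy — the OLS window fit on
one 100 ns path has a relative spread near unity, which is why aggregated
diffusion values carry large error bars; averaging over seeds or replicas
is the only remedy.

The dye-drag correction D×(1+f), default f = 0.20, maps a labeled-lipid
measurement to an unlabeled estimate.

## Solvation and electrostatics

Density profiles are counts per bin volume normalized by a bulk density
measured from the unrestricted selection in a configurable far-field band.
The lateral-cylinder restriction recomputes bin volumes as πR²·dz and takes
its per-frame center from a fixed point, a callable, or a reference
selection's centroid (e.g. a dye cluster). Dipole profiles report the mean
z-component of the molecular dipole Σqᵢ(rᵢ−r_O) in Debye, binned by oxygen
position; whether to report the mean moment or the mean cosine was
ambiguous, so the moment is the primary output and the cosine is recoverable
by dividing by the model dipole.

The 1D potential integrates φ'' = −ρ/ε₀ twice (cumulative trapezoid), with
φ = 0 and dφ/dz = 0 at a bulk-water boundary (default the topmost bin). A
non-neutral system yields a tilted potential and a warning, not an error.
The 2D (x,z) map applies the same 1D integration column by column after
averaging the charge density over y and frames — a slab approximation, not
a 2D Poisson solve; it reproduces the 1D profile exactly for x-independent
charge distributions and is flagged as such. Delta-like charges on bin
edges alias between neighbouring bins; profile comparisons should use
mid-bin placements or smooth densities. Defaults dz = 0.5 Å, dx = 2 Å.

## FCS

The intensity-trace generator moves point diffusers on a periodic plane and
detects F(t) = ΣB·exp(−2rᵢ²/w²) about the plane center (optional Poisson
shot noise). The default plane edge is 40 waists: the 2D model's 1/τ tail
is truncated once particles wrap around, and smaller planes measurably bias
τ_D down (a 16-waist plane inflates recovered D by several percent).

The correlator is FFT-based with the unbiased (N−k) normalization,
returning either every lag or a multi-tau-style quasi-logarithmic grid
(8 points per octave). A constant trace is flagged zero-variance rather
than fitted. Fitting uses the single-component 2D model G₀/(1+τ/τ_D) by
nonlinear least squares, iteratively restricted to lags ≤ 100·τ_D so the
long-lag noise floor (slightly negative after mean subtraction) cannot
drag τ_D; no triplet or photophysics term is included, matching the
membrane application. D = w²/(4τ_D) with the waist supplied by the caller
(default 0.25 μm — instrument waists are calibration-specific and never
claimed). Recovery is unbiased within seed scatter at 60 s trace duration;
short traces (≤15 s) of slow diffusers show a skewed, high-tailed estimate
distribution, which the tests accommodate by averaging seeds.

GP masks pixels whose summed two-channel intensity falls below a threshold
(default 3× the median of the dimmer half, a background proxy for images
that contain both membrane and background; explicit thresholds are
preferred for synthetic data) and reports per-pixel GP plus the mean over
the mask. FRET suppression is an experimental step; the computation assumes
FRET-free channels.

## What the tests show — and do not

All validation is parameter recovery on the generators above plus
closed-form and brute-force oracles (O(N²) MSD and RDF loops, Poisson
coordination expectation, the polarized-slab potential step P/ε₀, GP
arithmetic). Passing shows the estimators are correct for data with the
assumed statistical structure: ideal Brownian motion, uncorrelated lipids,
equilibrium water, point-charge electrostatics without polarization or
Ewald consistency. It does not show that a real force field or instrument
satisfies those assumptions — in particular the generators say nothing
about inter-lipid correlations, genuine aggregation kinetics, anomalous
diffusion exponents, photobleaching or detector artifacts.

Problem sizes in the test suite and acceptance script (400 walkers × 1001
frames, 60 s traces at 10 μs sampling, 200-frame water slabs) are the
package's chosen desk-scale study conditions; they match the generator
defaults and keep every run on a single CPU.
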