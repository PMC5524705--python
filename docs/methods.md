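# Methods

`cryopxct` implements, at desk scale, the full computational chain of
quantitative cryo ptychographic X-ray computed tomography (cryo-PXCT) of
thick frozen-hydrated tissue: a synthetic tissue block and diffraction
simulator stand in for the beamline, so every stage — phase retrieval,
projection alignment, tomographic reconstruction, density calibration,
resolution and dose estimation — can be verified against known ground
truth.

## Physical model

X-ray refraction in soft matter is described by the refractive index
n = 1 − δ + iβ.  The decrement is proportional to electron density,

    δ = r_e λ² n_e / (2π),

with r_e the classical electron radius and n_e in electrons per volume;
absorption is modelled as β = (β/δ)·δ with a fixed small ratio (default
0.005 — phase contrast dominates absorption by orders of magnitude at
multi-keV energies).  Mass density follows from the molar mass per
electron of a water/lipid/protein/chromatin mixture,

    ρ_m = n_e · (M/e) / N_A,     M/e = 1.86 g/mol,

so water (0.3344 e/Å³) maps to 1.033 g/cm³ (≈3% above its true density:
pure water's ratio is 1.80 g/mol; the soft-matter value is a compromise
across tissue constituents and is the source of the few-percent
uncertainty inherent in the conversion).

Under the projection (multiplicative) approximation, the sample at
tomography angle θ acts on the beam as a 2-D complex transmission

    T(y, x) = exp(−(2π/λ)∫β dz) · exp(−i(2π/λ)∫δ dz),

with the integral along the beam.  Sign convention, fixed repo-wide:
denser material → more negative phase.  Coordinates: y is the vertical
rotation axis, the beam travels along +z at θ = 0, grids are indexed
(y, x, z), angles are degrees in [0, 180).  The validity range of the
2-D approximation is the depth of field DOF = 5.2·(resolution)²/λ;
`quant.depth_of_field_check` flags configurations that exceed it
(advisory only).

## Tissue phantom

The phantom emulates the feature classes visible in cryo-PXCT of
sucrose/PVP-infused brain tissue, with piecewise-constant electron
densities (e/Å³, all overridable):

| class           | default n_e | rationale                                   |
|-----------------|------------|----------------------------------------------|
| medium          | 0.40       | 1.8 M sucrose + PVP cryoprotectant, densest bulk phase |
| cytoplasm       | 0.37       | cell body, below infused medium              |
| axoplasm        | 0.36       | axon interior                                |
| nucleus         | 0.35       | below cytoplasm (observed contrast)          |
| myelin          | 0.34       | lipid multilayer, below surrounding tissue   |
| vacuole lipid   | 0.31       | pigmented autophagic vacuole body, lowest    |
| vacuole pigment | 0.45       | dense (iron-bearing) sub-inclusion           |

These values honour every qualitative ordering reported for this kind
of tissue (myelin < medium, vacuole < myelin, nucleus < cytoplasm)
while staying in the physically plausible 0.3–0.45 e/Å³ range for
hydrated organics.  Axons are vertical cylinders (axoplasm core +
myelin annulus of randomized thickness), nuclei are ellipsoids inside
cytoplasm spheres, vacuoles are ~3 µm spheres with an internal pigment
sub-sphere.  Overlaps resolve by precedence (pigment > vacuole >
nucleus > myelin > axoplasm > cytoplasm > medium) — label codes are
ordered so a voxelwise maximum implements this.

The block cross-section (the trimmed sample footprint) is a **cylinder
by default**.  A flat face parallel to the beam produces an inter-pixel
phase jump of several radians (>π) at normal incidence — with desk
densities ≈4.9 rad — which wrap-safe derivative processing cannot
represent; this is precisely the grazing-incidence streak pathology
known for rectangular-pyramid samples, and the reason cylindrical
samples are the stated ideal for this technique.  A rectangular support
remains available in `PhantomSpec` for studying exactly that artifact.

Projections rotate the volume about y with bilinear interpolation
(zero padding, grid sized so the support's circumscribing circle stays
inside at all angles) and sum along z.  Total projected δ is
angle-invariant to <1e−3 at the 128² grid (tested).

## Measurement simulation

The probe is a cosine-tapered disc (taper 10% of diameter) with a
quadratic defocus phase, normalized so Σ|P|² equals the photons per
exposure.  Only probe extent and overlap matter for pipeline
verification — the solver retrieves the actual probe — so the
diffractive structure of the real zone-plate illumination is not
reproduced.  Scan positions follow a Fermat spiral (r = c√k,
θ = k·137.508°, c = step/√π so the mean area per point is step²),
clipped to the rectangular field of view; nearest-neighbour spacing has
CV < 0.3.  Positions are quantized to integer reconstruction pixels:
the solver retrieves one shared probe, and per-position sub-pixel probe
shifts would make that model inexact while a ≤0.5 px quantization is
negligible against the multi-micron step.  Photon budget: per-exposure
photons = fluence × scanned area / number of positions, so overlap is
inside the fluence accounting.  Far-field intensities are |DFT(P·O)|²
with orthonormal scaling (photon number conserved, Parseval); detector
noise is pure Poisson, seeded per (run seed, angle, position).

## Phase retrieval

Difference map on the stack of per-position exit waves,
ψ_j ← ψ_j + P_F(2P_O(ψ_j) − ψ_j) − P_O(ψ_j), with:

* P_O: alternating least-squares object/probe factorization
  O = Σ_j P*ψ_j / (Σ_j|P|² + ε), probe update symmetric (2 inner
  alternations, ε = 1e−12·max of the denominator);
* P_F: replace Fourier amplitudes by √I keeping phase;
* probe update frozen for the first 10 iterations;
* relaxation β = 1 (classic difference map).

Two readout subtleties.  (1) The data fix only the product P·O; the
scale split is anchored by requiring mean |O| = 1 over well-illuminated
air pixels (coverage ≥30% of max).  With this gauge, retrieved probe
power matches the simulated photon count to ~1%; without it the split
drifts freely.  (2) On probe-retrieving problems the DM settles into a
small limit cycle rather than a fixed point; `average_last` averages
the overlap-consistent estimates over the final iterations (with
global-phase alignment), the standard way to read out a DM solution.
Probe retrieval needs a well-overlapped scan: the 40-position desk scan
supports it, the 12-position unit scan does not (the unit profile keeps
the known probe fixed).

Maximum-likelihood refinement minimizes the Poisson negative
log-likelihood L = Σ|Ψ|² − I ln(|Ψ|²+ε) (ε = 1e−8·max I) by
Polak–Ribière conjugate gradient with analytic Wirtinger gradients and
a parabolic line search with backtracking; accepted steps never
increase L, and a failed line search returns the current state flagged
rather than raising.  Comparisons against ground truth always remove
the inherent ptychographic ambiguities first (global phase offset +
linear ramp), estimated from the weighted product recon·conj(truth).

## Alignment

All processing is derivative-domain (wrap-safe finite difference
d = arg(T(x+1)·conj(T(x)))); a true inter-pixel jump of exactly 2π is
invisible — the known limitation of avoiding 2-D unwrapping.  The
integration back to phase prepends a zero (the forward difference
telescopes to φ(x) − φ(0)); taking the raw cumulative sum instead
displaces every profile one pixel and the aligner chases a spurious
global shift.  The per-projection phase offset/ramp ambiguity is
removed by a least-squares plane fit over the air strips flanking the
sample.

* **Vertical**: the row sum of the integrated phase is an
  angle-invariant mass profile (the row sum of the *derivative* would
  telescope to ≈0, hence the integration); profiles are iteratively
  registered to their mean, sub-pixel, zero-mean gauge.
* **Horizontal**: centre-of-mass pre-alignment (projected COM follows
  A·cosθ + B·sinθ + c; residuals are misalignment) initializes a
  tomographic-consistency loop: reconstruct a central slab → reproject
  → register each measured projection to its reprojection.
  Registration is a joint sub-pixel block correlation over the slab
  rows in the derivative domain (row-wise cross-correlations summed
  before peak finding; peak refined on a 0.01 px grid).  Each update
  has the translational gauge A·cosθ + B·sinθ + c projected out — that
  component merely translates the reconstruction and would otherwise
  accumulate as drift.  Recovery accuracy on injected shifts
  (|dy|≤3 px, |dx|≤4 px, 90 angles): ≲0.03 px vertical, ≲0.08 px
  horizontal modulo gauge.
* **Rejection**: projections with a localized transmissivity loss
  (grazing-incidence artifact) are flagged automatically when the
  minimum 5×5 boxcar amplitude falls >k·MAD (k = 5) below the
  across-angle median; a manual override list exists in the run config.
  Remaining angles get gap-compensating weights
  w_i ∝ (θ_{i+1} − θ_{i−1})/2, periodic over 180°, normalized Σw = n.

Shifts are applied as Fourier phase ramps on 10%-edge-padded arrays.

## Tomographic reconstruction

Filtered back-projection formulated for phase derivatives: the ramp
filter |w| divided by the derivative transfer i2πw gives
H(w) = −(i/2π)·sign(w), applied per projection row in the Fourier
domain, followed by weighted linear-interpolation back-projection with
π/n scaling, slice-by-slice along the rotation axis (exact for
parallel beams).  Two numerical choices matter:

* the filter carries an extra e^{−iπw}: the forward difference samples
  the derivative on the half-integer grid, and without this half-pixel
  compensation the whole reconstruction is blurred by a 0.5 px ring;
* projections are zero-padded to ≥8× width before filtering.  H(w)
  nulls w = 0, so the DC level of the slice is carried entirely by the
  lowest sampled frequencies; with supports filling most of the grid,
  2× padding leaves the interior several percent low (≈6% measured on
  the desk phantom), 8× keeps the bias below 0.4% at negligible cost.

Calibration: phase-per-voxel v → δ = −v·λ/(2π·voxel) →
n_e = 2πδ/(r_e λ²), the exact algebraic inverse of the phantom's
forward map.  On the analytic cylinder oracle the interior is within
2% of truth and air within 2% of zero (3-voxel edge band excluded);
azimuthal CV < 3%.

## Quantitative analysis

**FSC**: even/odd angle-split half reconstructions (the split is
configurable; whether the original analysis split by angle or by scan
is not knowable from published information), shared Hann apodization,
correlation per integer-radius shell, half-bit threshold
T = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n), resolution at the first
downward crossing (linear interpolation), floored at 2 voxels
(Nyquist).  A curve that never crosses reports no resolution rather
than a number.  The published beamline resolutions (hundreds of nm on
real tissue) are functions of the real data and are *not*
desk-reproducible; the FSC machinery is validated by its properties:
FSC ≡ 1 for identical volumes, pure noise below 3/√n, and resolution
degrading monotonically as the simulated photon budget drops from 1e4
to 1e3 photons per frame (unit-scale scan; the acceptance script
reports the two resolutions for its seed).

**Dose**: surface dose of a weakly absorbing medium,
D = Φ·E·(1/Λ)/ρ·n_proj, with water optical constants at 6.2 keV
(Λ = 451 µm, ρ = 1000 kg/m³): ≈22 kGy per projection at 1e7 ph/µm²,
hence ≈9.8/19.7/17.3 MGy for 446/894/785 projections.  These agree
with the published 11/21/20 MGy to within 25% — exact agreement is not
possible because the published fluence is itself approximate.

**Segmentation**: voxels binned into disjoint density bands,
26-connected components, minimum-size filter, per-component
equivalent-sphere diameter d = (6V/π)^{1/3}; per-class mean ± sd and
count.  On the desk run the four generated vacuoles are recovered as
four components.

## Pipeline, profiles and problem sizes

`run_pipeline` executes phantom → simulate → per-angle ptycho → align
→ FBP → quant, persisting every intermediate as HDF5; each stage
derives its seed as sha256(master:stage:index) mod 2³¹, so inserting a
stage never changes another stage's stream.  The ptycho object grid
exceeds the scanned area by half a frame so every probe window fits;
before alignment the reconstruction is cropped back to sample + air
margin, because the phase in that outer band is only weakly illuminated
and meaningless.

Profiles (angle count, detector size and iterations scale together so
runs finish in minutes):

* **unit** — 16×32×32 phantom, 600 nm voxels, 32-px frames, 15-px
  probe, ~12 positions, 16 angles, 40 DM + 5 ML, frozen probe; ~2 s.
* **desk** / **noisy-desk** — 64×128×128 phantom, 305 nm voxels, 64-px
  frames, 31-px probe, 40 positions, 60 angles, 150 DM + 30 ML, probe
  retrieved; ~4 min single-core.  Median reconstructed n_e per feature
  interior (2-voxel erosion) lands within 5% of the assigned values.
* **paper-A/B/C** — the published optics exactly (6.20 keV, 7.33 m,
  452 px of 75 µm → 43.25 nm pixel; 446/894/785 angles; 800+150 or
  600+100 iterations) for geometry/dose reporting; their full-size
  simulation is far beyond desk scale and they are not run end-to-end
  here.

## What the synthetic data does and does not show

The simulator reproduces the measurement geometry, the multiplicative
interaction, photon statistics, projection ambiguities (offset/ramp),
misalignment, and grazing-incidence-like amplitude loss (by injection).
It does **not** model partial coherence, detector point-spread or gaps,
wavefront defects, position errors beyond pixel quantization,
multiple scattering (no multi-slice), ice contamination, or radiation
damage.  Passing tests therefore demonstrate the correctness of the
reconstruction chain, not the attainable image quality on real tissue;
published resolutions and real-data artifact levels cannot be
reproduced from simulation alone.

## Known limitations

* Derivative-domain processing is blind to true ≥π inter-pixel jumps;
  rectangular supports at grazing angles violate this (by design the
  default phantom avoids it).
* No position refinement, single probe mode, no multi-slice: thick
  samples at resolutions finer than the depth of field are out of
  scope.
* The automatic bad-projection detector is a stated stand-in for what
  is, in practice, manual curation; its MAD threshold assumes most
  projections are clean.
* The mass-density conversion inherits the composition assumption in
  the 1.86 g/mol ratio; the package reports the conversion but does not
  re-derive its uncertainty bound.
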