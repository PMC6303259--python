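# Methods

This note documents the models, algorithms and numerical choices behind
`camtrace`, what the synthetic benchmarks do and do not establish, and the
problem sizes the test suite runs at.

## 1. Tracer imaging model

The imaging premise: in transmission, flowing erythrocytes are dark,
compact absorbers on a bright quasi-uniform field.  Over a long enough
registered movie, the pixelwise minimum records the darkest column ever
seen at each pixel — the vessel lumen — and the pixelwise mean records mean
tracer occupancy — a qualitative flux map.  Averages (not sums) are used
throughout; a sum is the same image times the frame count.

### Absorption and the saturated regime

Each cell under a pixel multiplies the background by (1 − c), c the
per-cell contrast, so *k* stacked cells transmit (1 − c)^k (Beer–Lambert;
overlapping tracers darken sub-linearly).  A column of lumen can hold at
most thickness/cell-height cells, so the generator caps the exponent at
that packing limit.  In the **saturated regime** — tracer density high
enough that every column is packed at least once during the movie — the
minima image's optical density approaches

    OD(x) = −log(I_min/I₀) ≈ ln(1/(1−c)) · t(x)/h_cell  ∝  t(x),

the chord thickness of the lumen.  This proportionality is what absorption
profilometry rests on: a cylindrical vessel yields OD ∝ 2√(R² − x²), a
flattened one a plateau.  Below saturation the minima OD follows
max-of-occupancy statistics instead and systematically flattens the
profile shape; the profilometry benchmarks therefore run at packing-level
density (see §6).

## 2. Stack processing

**Shuffle.**  The permutation interleaves the two stack halves:
slot order 0, ⌈N/2⌉, 1, ⌈N/2⌉+1, …  Adjacent output slots are acquired at
least ⌊N/2⌋ − 1 frames apart (for odd N the final frame simply closes the
interleave).  The permutation object carries its own inverse; unshuffling
orders surviving frames by acquisition index, so frames discarded between
shuffle and unshuffle are skipped without bookkeeping errors.

**Why shuffle at all.**  Sequential registration (each frame to its
predecessor, transforms accumulated — the behaviour of standard
stack-alignment tools) sees, between consecutive frames, the static scene
plus a *coherently displaced* tracer population.  The tracer term biases
each pairwise estimate a fraction of a pixel in the flow direction; over
hundreds of frames the bias integrates into a drift of tens of pixels that
ruins both projections.  After shuffling, consecutive slots hold
decorrelated tracer patterns, the bias loses its common direction, and the
accumulated error stays at the random-walk level.  The benchmark suite
demonstrates both halves of this claim (drift without shuffle, none with).

**Blur ranking.**  Frames are ranked by the gray level of a dark crisp
feature: the mean of the darkest 1% of pixels inside the operator's ROI.
A low quantile rather than the ROI mean makes the measure insensitive to
the feature wandering inside the ROI under jitter and to tracer turnover;
defocus raises it sharply because diffusion fills in the darkest cores.
The darkest `ceil(keep_fraction · N)` frames are kept in original order
(default keep_fraction 0.5 — with heartbeat defocus roughly half the
frames are usable).  A whole-frame gradient-energy (Tenengrad) criterion
is available for unattended time-lapse runs; on the benchmark both agree
with the ground-truth blur schedule on ≥ 90% of frames.

**Aberrant frames** are removed by normalized cross-correlation against a
reference frame (default threshold 0.1 — between jittered-but-real frames,
which correlate at ~0.2–0.6 on tracer-dominated scenes, and saturated
camera glitches at ~0).

**Registration** is subpixel phase correlation (upsampled cross-power
spectrum), translation-only by default; the rigid model adds a ±3° coarse
rotation search with refinement.  Two passes:

1. chain (sequential) or direct (reference) phase correlation;
2. a refinement pass against the pixelwise **median** of the aligned stack
   (the median suppresses moving tracers, leaving the static scene),
   phase correlation for gross residuals, then a weighted Lucas–Kanade
   step for the subpixel remainder.  The LK weights exclude resampling
   borders and pixels departing > 4 MAD from the template — i.e. passing
   tracers — so only static structure drives the estimate.  Replacing or
   clipping tracer pixels with template values instead of *weighting them
   out* was tried and rejected: any substitution injects a spurious
   zero-displacement correlate.

On the benchmark movie this recovers the applied jitter + drift to
~0.1–0.2 px (median); the refinement cannot rescue a stack whose first
pass drifted, which preserves the shuffle ablation contrast.

Frames are resampled bilinearly once with the final transform;
out-of-frame pixels are filled with the background median and masked
invalid, and projections exclude invalid pixels (otherwise the dark fill
would corrupt the minima at the borders).

**Background flattening** subtracts a grayscale-closing estimate (disc
footprint) of the illumination; the disc must be larger than the widest
vessel or the vessels are flattened away (a hint parameter triggers a
warning).  Closing is exact on affine illumination, hence the operation is
idempotent up to border effects.

## 3. Vessel profilometry

A profile line crosses one vessel.  Intensity is sampled bilinearly at
≤ 1 px steps; the per-profile background I₀ is the median of the outermost
20% of samples on each flank (the field outside the vessel is assumed
homogeneous); OD = −log(I/I₀) clipped at 0.  Width is the FWHM of the OD
peak with interpolated half-maximum crossings.  The flatness score is the
fraction of the FWHM span where OD ≥ 0.9 · peak: ~1 for a plateau
(flattened vessel), √(0.19)/√(0.75) ≈ 0.50 for a semicircular chord.
Note the FWHM of a chord profile is √3/2 of its support while a plateau
keeps ~all of it, so FWHM *ratios* between differently-shaped sections
exceed their geometric width ratios (≈1.65 vs 1.43 for the fully flattened
member); ratios between same-shape sections equal the geometric ratio.
Light-diffusion blunting is not modelled — at the optical densities and
vessel sizes of interest it is a second-order effect, and nothing in the
pipeline depends on it.

## 4. Axial flow in the circle → stadium family

Fully developed laminar flow of a homogeneous Newtonian fluid obeys
∇²w = (dp/dz)/µ with w = 0 on the wall.  The cross-section family is the
perimeter-preserving stadium: gap h ∈ (0, D], flat-wall length
L = π(D − h)/2, width L + h, perimeter πD always; h = D is the circle and
h → 0 the fully squeezed slit of width πD/2.  This parametric family
replaces an elastic contact computation: it matches the printed geometric
invariants exactly and is analytically checkable, at the cost of ~±10–20%
on resistance ratios versus a contact-deformed shape (the acceptance bands
reflect that).

Numerics: the Poisson problem is solved once with unit forcing on a
regular grid (default 48 cells across the gap) and rescaled — the problem
is linear, so dp/dz = −µQ/∫u dA.  Near-wall nodes use Shortley–Weller
unequal-arm differences with the exact axis intercepts of the stadium's
signed distance function, keeping the discretisation second order despite
the curved boundary; the circular member then reproduces closed-form
Poiseuille dp/dz, wall shear and centerline velocity to ≲ 0.5% and
refinement 48 → 96 moves dp/dz by ~0.01%.  Wall shear rate is the normal
derivative at the wall from a 3-point one-sided difference (samples at
2.5h and 5h along the inward normal, bilinear interpolation, the wall
value being exactly zero), evaluated at 720 boundary points partitioned
into semicircular caps and flat walls; medians summarise each class
(maxima are also exposed).  The independent oracle for the flattened
member is the Boussinesq eigen-series for a rectangular duct of the same
1.42D × D/4 envelope, which gives a ratio ≈ 15.0 — a slight underestimate
of the stadium (≈ 15.3), as expected since the rectangle has the larger
area for the same envelope.

A lubrication viewpoint is taken throughout: each station of the tapering
vessel is treated as a 2-D cross-sectional problem.  The printed end-state
quantities are cross-sectional, so no 3-D Stokes solve of the taper is
needed.

## 5. Lattice flux map

The plexus is a 26 × 41 lattice of node conductivities σ: 0.4 in the
flattened capillary pocket around the arteriole tip, 1.0 in cylindrical
capillaries (2.5×), 4.0 on the flat distal half of the arteriole path,
10.0 on the cylindrical proximal half (2.5× again).  The flux is the
backward-difference form jx[i,j] = σ[i,j](V[i,j] − V[i−1,j]) (likewise
jy); the sign convention is kept as-is — it flips J relative to the
physical −σ∇V but leaves |J| maps unchanged.  The conservation law
div J = 0 uses the conservative pairing jx[i+1,j] − jx[i,j] (+ y terms),
the standard discrete divergence for backward-difference fluxes.

Boundary conditions are a modelling choice: Dirichlet V = 1 at the
arteriole inlet node, V = 0 along the venous (right) edge, no-flux
elsewhere; the arteriole path runs along the central row to 2/3 of the
lattice width, its distal half flat (configurable).

**Stability.**  The explicit update V ← V + C·div J with C = 0.05 is
outside the von Neumann stability region wherever C·Σ_face σ > 1 (e.g. on
the σ = 10 path, where the face sum reaches 22).  The potential of
div(σ∇V) = 0 with Dirichlet data is invariant under a global rescaling of
σ, so the solver rescales σ internally to 90% of the stability limit
(only ever downward) and iterates; fluxes are computed on the original σ.
With this rescaling the default scenario converges in ~99 000 sweeps to a
per-sweep update below 10⁻¹⁰ — tolerances looser than ~10⁻¹⁰ leave the
iterate measurably short of the fixed point, since the terminal error is
roughly the residual divided by the slowest decay rate.  Correctness is
defined by agreement with a direct sparse solve of the identical discrete
system (≤ 10⁻⁶ max abs difference), discrete conservation at free nodes
(< 10⁻⁶) and the maximum principle.  A divergence guard aborts with a
suggestion to lower C if max |V| grows for 1000 consecutive sweeps.

The headline qualitative result — the exclusion zone — is scored as the
mean |J| over the flattened pocket versus the mean |J| over the
cylindrical corridor flanking it at the same columns; softening the pocket
strictly lowers the flux through it.

## 6. Synthetic movies: what they emulate, and what not

The generator renders dark tracer discs (radius 2 px) advected along a
vessel network over a bright field, with:

* per-segment geometry from the same stadium family as §4 — flattening
  f maps to gap h = D(1 − 0.75 f), so f = 1 gives the h = D/4, 1.43 D-wide
  terminal section — and tracer speed scaled by (1 − 0.8 f), so flattened
  tips carry visibly less flux;
* lateral tracer offsets drawn from the thickness-weighted stationary
  distribution (cells fill the cross-section uniformly) and re-drawn with
  mean period 20 frames — cell–cell interactions redistribute cells across
  the lumen without changing the stationary occupancy profile;
* a static scene: gentle illumination tilt (~2%), a seeded smooth tissue
  texture (σ 3%, correlation length ~6 px), and faint static plasma/wall
  absorption (OD 0.06 at the deepest point).  Transmission images of live
  tissue always carry static structure; it is what anchors registration,
  while the moving tracers are the content that biases it — without it the
  registration problem the pipeline solves would not exist in the movie;
* rigid sinusoidal jitter (default amplitude 6 px, period 12 frames,
  seeded phase — heartbeat), slow linear drift (0.02, 0.01 px/frame),
  Bernoulli(0.5) per-frame Gaussian defocus (σ 3 px), rare aberrant
  near-saturated frames (rate 0.005), additive camera noise (σ 0.003);
* everything driven by one seed: identical seeds give bit-identical
  stacks, and the ground truth records the mask, thickness map, per-frame
  transforms, blur/aberrant flags, tracer tracks, realized mean-occupancy
  map and the static background.

Not modelled: red-cell deformation and shape, hematocrit segregation
(plasma skimming), pulsatile speed modulation, out-of-plane vessel
geometry, elastic tissue deformation, photon/shot-noise statistics.
Passing the synthetic benchmarks therefore shows the *algorithms* recover
known ground truth under the stated nuisance processes; it does not
validate the biological measurements on real tissue, where those omitted
effects (notably segregation, which is why profiles use minima rather than
average) matter.

## 7. Benchmarks and problem sizes

Chosen once as the package's standard desk-scale study conditions:

* **Pipeline benchmark**: 3-segment Y network (radii 9/8/6 px, one fully
  flattened branch) in 220 × 260 frames, 300 frames, jitter 6 px, 50%
  blur, density 8 tracers/100 px.  Scored: blur-filter agreement ≥ 0.9
  with exactly ⌈N/2⌉ kept, registration error ≤ 0.5 px vs ground truth,
  Otsu-minima vessel-mask Dice ≥ 0.85 (projections mapped back to scene
  coordinates through the known jitter of the reference frame), average
  projection OD rank-correlates with realized mean flux (Spearman ≥ 0.8,
  using the ground-truth static background for normalisation), and Dice
  with shuffle ≥ Dice without.
* **Coverage**: same network at 20 tracers/100 px, 300 frames — ≥ 99% of
  lumen pixels visited (at the default density the slow flattened branch
  is not fully explored in 300 frames; that is flux starvation, not a
  bug).
* **Profilometry benchmark**: single straight vessel (R = 12 px) in
  120 × 260, motion-free, 400 frames at packing density (2400/100 px, the
  saturated regime of §1): chord-model fit with < 10% relative RMS over
  |x| < 0.8R, flatness 0.94 (flat) vs 0.44 (round), AUC 1.0.
* **Hemodynamics**: default 48 cells across the gap (~12 700 unknowns for
  the flattened section; sweeps and linearity checks at 16–24).
* **Flux map**: the 26 × 41 default scenario; the conductivity sweep runs
  at a 10⁻⁹ tolerance, the acceptance solve at 10⁻¹⁰.

## 8. Known limitations

* Rotation search is coarse (0.25° refinement) and intended for the small
  rigid rotations of a stabilised preparation; large rotations or
  non-rigid deformation are out of scope (areas under strong deformation
  cannot be processed by rigid alignment at all).
* The stadium family is a geometric idealisation of contact flattening;
  resistance ratios inherit ~±20% model error relative to an elastically
  deformed section.
* The lattice flux model is dimensionless and topological; it shares no
  units with the axial-flow module.
* PIV is single-pass ensemble correlation for quasi-steady flows; it does
  not window-deform and will underestimate strong in-window shear.
* The blur filter's keep-fraction is a fixed quota, not a quality
  threshold: on a movie with little defocus it still discards half the
  frames (the conservative choice the imaging protocol assumes).
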