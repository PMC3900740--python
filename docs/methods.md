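# Methods

## Forward model

A transmembrane helix viewed down the membrane normal is modelled as a 2D
Gaussian density: center (Å, cell frame), 2×2 covariance (Å²), scattering
mass, and an order parameter in [0, 1] scaling the amplitude.  Isotropic
width defaults to σ = 3.0 Å, which resolves neighbouring helices as discrete
peaks at the 6 Å resolution cutoff; a tilted helix is represented by an
anisotropic covariance (elongated projection).  One protomer is a list of 15
projected rods (TMHs 1–13 with the discontinuous helices 5 and 12 split into
cytoplasmic/exoplasmic halves); the dimer mate is generated by an in-plane
twofold (plane group p2).  The layout is schematic — an interface row
(TMH 1–3, 7–10) and a six-helix bundle (4/11/12c, 5c/12e, 6, 13, 5e) with
~8–12 Å spacings — not atomic-model coordinates.  The plane group and cell
angle γ are not constrained by the source data; γ = 90° and p2 are defaults
and both are configurable (`DimerOp` supports any involution).

Structure factors of a Gaussian mixture are available in closed form
(F(h,k) = Σ w·exp(−2π² qᵀΣq)·exp(−2πi(hx+ky))), which makes the generator
independent of the FFT-based map synthesis it is used to test.

## Two conformational states

The Na⁺-bound state differs from the apo state by:

| change | default | note |
| --- | --- | --- |
| 5c/12e lateral shift | 2.0 Å toward TMH 10/13 | the headline helix movement |
| TMH 6 | 4:1 → 1:1 anisotropy + 1.6 Å centroid shift | helix straightens |
| TMH 13 | 1:1 → 2:1 anisotropy + 2.0 Å centroid shift | helix tilts |
| 5e order | 0.2 → 1.0 | unpaired positive difference peak |
| unit cell | 81.2 × 104.2 → 80.6 × 107.9 Å | linear in occupancy |

The cell change is treated as uniform lattice drift: bound-state rods keep
the apo fractional coordinates and only the conformational shifts move
density relative to the lattice.  This is the convention implied by excising
maps into a common cell before subtraction; without it, the 3.5% cell change
masquerades as a ~1.5 Å apparent movement everywhere in the protomer.  The
anisotropy magnitudes and centroid shifts accompanying the TMH 6/13 tilt
changes are free calibration knobs; they were fixed once so that the three
peak sets reach comparable saturating difference amplitudes (set 1
strongest), matching the qualitative record.  A helix that tilts or
straightens genuinely moves its projected centroid, so these shifts are
physically motivated rather than ad hoc.

Occupancy follows the single-site competition isotherm θ = c/(c + K_app),
K_app = K_Na·(1 + 10^(pK−pH)).  The ground-truth (K_Na, pK) are solved
exactly from the two apparent anchors (30 mM at pH 8, 280 mM at pH 4),
giving K_Na ≈ 30.0 mM and pK ≈ 4.92.  Non-transported control ions
("Mg2+", "K+") pin θ = 0 at any concentration; "Li+" behaves as substrate.

## Noise model and calibration

Each simulated lattice multiplies the ideal structure factors by a
log-normal scale (σ_log = 0.15), applies a uniform random phase origin, and
adds independent zero-mean Gaussian noise (σ = `NOISE_SIGMA`, default 0.06)
to the real and imaginary parts of every reflection — the simplest model
whose merged statistics behave like real data (Rician amplitude bias,
√n error reduction, wrapped-Gaussian phase residuals).

Two facts governed the default noise:

* The half-split control background is **±2 contour levels at the 1.5σ step
  for any noise level** — the maximum of a smooth zero-mean control field
  over ~10³ resolution elements sits near 3–3.5σ, and ⌊3.4σ/1.5σ⌋ = 2.  The
  background criterion therefore cannot pin the noise amplitude.
* The counting arithmetic (integer floors, per-region subtraction of the
  half-split control counts) costs a roughly constant ~2 contour levels
  regardless of the signal scale.  If the noise is set so peaks saturate
  near 15 levels, that overhead biases fitted constants by ~+20% (pH 8) to
  ~+50% (pH 4); at the default noise the peak sets saturate near 50–60
  levels and the fits recover the generating constants to within ~1% (pH 8)
  and ~+12% (pH 4).  The package prioritizes unbiased parameter recovery
  over reproducing the absolute count scale of any particular experiment;
  users wanting coarser contouring can raise `noise_sigma`.

## Pipeline numerics

* **Reflections** to 6 Å in one half-plane (h > 0, or h = 0, k > 0; ~370 for
  the default cell), Friedel mates implied; (0,0) excluded so maps have zero
  mean and σ-contouring is well defined.
* **Maps** on a 128 × 160 grid (~0.65 Å/pixel, ≥4× oversampling of 6 Å
  data); synthesis ρ = (1/A)ΣF·e^{2πi(hx+ky)} with Parseval checked in the
  tests.
* **Origin search** maximizes the amplitude-weighted phase correlation on a
  240 × 240 fractional grid via one FFT, then polishes with Nelder–Mead on
  the weighted mean |Δφ|; ties break toward the smallest shift.  Merged
  references are registered onto the ground-truth apo projection so the
  declared peak regions line up — the simulation analogue of settling the
  crystallographic origin before plotting; for user data the regions are
  supplied relative to the user's own maps instead.
* **Scaling** is reciprocal-space least squares (k = ΣA_ref·A_lat / ΣA_lat²),
  chosen over real-space map scaling for independence from the grid.
* **Half-split controls** partition one condition's lattices 3/3, merge both
  halves against the registered reference, subtract, and set the absolute
  contour step to 1.5σ of the result.  A control whose σ falls below 10⁻⁴ of
  the parent maps' σ is treated as empty (noise-free degenerate case) with a
  nominal minimum step of 10⁻¹².
* **Counts** are floors — a contour line at level n exists only if the
  density reaches n·step — and the same absolute step is applied to every
  difference map of the analysis.  Background correction is
  max(0, raw − control) per region, with the zero-concentration point 0 by
  construction.
* **Displacements** come from the state maps, not the difference map: within
  the region, pixels above mean + 1σ mark the peak, the dominant connected
  component is kept, and the centroid weights only density above half the
  in-region maximum so truncation by the region boundary does not bias the
  estimate.  Centroids are compared in fractional coordinates (mean-cell
  frame), making the estimator blind to uniform lattice drift.
* **Fits** use a 1D log-grid over K_D with the conditionally-linear h_max,
  then bounded least squares; the bootstrap resamples titration points with
  replacement (degenerate resamples skipped) and reports the 16–84%
  interval.  A fit whose interval spans >100× or whose constant escapes the
  measured concentration decade is flagged not well determined.  The Hill
  coefficient is fixed at 1; integer counts are fitted directly, with
  quantization error absorbed into the residuals.

## What the generator does and does not emulate

Emulated: population mixing on the lattice, per-lattice noise/origin/scale,
cell drift with occupancy, merging statistics, control-map noise floors,
count quantization.  Not emulated: micrograph-level effects (CTF, lattice
distortions, unbending), resolution anisotropy, per-reflection
figure-of-merit weights, the pH 6 "fully active" regime (a conformational
continuum; representable only crudely here as lowered rod order), and any
real structural coordinates.  Passing tests therefore validate the analysis
machinery and its statistical behaviour, not biological conclusions about
any particular protein.

## Problem sizes

The recovery studies simulate 6 lattices × 6 concentrations per titration,
20 replicate titrations per pH, 3 fitted regions (60 fits per pH), with a
50-resample bootstrap inside each fit; this keeps a full acceptance run
around a minute on one CPU while the medians are stable to a few percent.
The `reproduce` pipeline uses a 500-resample bootstrap by default.

## Known limitations

* The counting pipeline's fixed ~2-level overhead makes recovered constants
  scale-dependent: coarse contouring (saturation ≈ 15 levels) inflates
  K_D,app, most strongly when the ladder does not reach saturation (acidic
  conditions).  This is a property of the counted-contour method itself.
* Region ellipses are declared, not discovered; badly placed regions
  silently count noise.  `PeakRegion.overlaps` guards overlap but not
  coverage.
* The displacement estimator assumes one dominant peak per region and both
  states above 1σ; heavily disordered states (order ≪ 1) can fail the
  detection precondition.
* p2 symmetry is generated but never imposed on merged data; phases are
  treated as general.
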