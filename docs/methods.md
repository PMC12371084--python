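# Methods

## Scientific setting

The vacuolar-type H⁺-ATPase (V-ATPase) acidifies secretory organelles. Its
membrane-embedded V₀ region and cytosolic V₁ region associate reversibly,
and this assembly is the principal regulatory switch of the pump. In the
Golgi, the a-subunit of V₀ is the a2 isoform; its cytosolic *head* domain
can engage the d1 subunit, and while engaged it sterically blocks V₁
docking. The conformational landscape of the a2 head/arm relative to the
body/d1/c-ring — and how membrane lipids (PI(4)P, cholesterol) shift the
population of the *assembly-promoting* head-disengaged state — is the
object of this package's analysis pipeline.

The pipeline operates on conformational ensembles (frames × atoms × 3, Å,
plus a topology labelling atoms by subunit/region/species) and runs:

1. **Membrane system realization** — mol% compositions to symmetric integer
   per-leaflet lipid counts (largest-remainder rounding per leaflet; exact
   leaflet totals, minimal mol% distortion). Four standard systems are
   built-in: POPC/PI(4)P/cholesterol at 100/0/0, 80/20/0, 70/20/10 and
   70/10/20 mol%, 980 lipids, 150 mM KCl, 8 × 750 ns bookkeeping metadata.
2. **Rigid-body alignment** — Kabsch superposition (SVD, proper rotation
   enforced) of every frame onto a reference structure, computed on the
   protein Cα selection and applied to all atoms.
3. **Dimensionality reduction** — a denoising autoencoder maps flattened
   Cα coordinates to a 2D latent space.
4. **State detection** — a Bayesian Gaussian mixture with full 2×2
   covariances over the latent space; a Dirichlet-process concentration
   prior regularizes the number of components.
5. **Functional identification** — the assembly-promoting cluster is the
   one whose a2 head forms the fewest contacts with d1.
6. **Discriminant analysis** — PLS regression of coordinates onto the 0/1
   assembly label, with validation R² and a 0→1 structural interpolation.
7. **Lipid–protein analytics** — contact counting, salt-bridge
   frequencies (E81–R436, D76–R126), lipid occupancy density maps and
   pocket occupancy.
8. **Assembly compatibility** — superposition of each frame onto a labeled
   holo (V₀+V₁) reference and steric-clash counting against V₁.

## Autoencoder

Architecture: input → 1024 → 128 → 2 (encoder), mirrored decoder, ReLU on
hidden layers, linear latent and output. The latent dimension is 2 by
design. Training uses:

* **L1 reconstruction loss** on uncorrupted targets, with additive Gaussian
  input corruption (σ_corrupt = 0.3 Å, matching the thermal-noise scale) —
  the denoising component;
* **20% inverted dropout** on every hidden layer;
* a **3×3 grid L2 term** (weight λ = 0.1): grid nodes are a 3×3 lattice
  spanning the training latent range, refreshed every epoch. Each node
  exerts a local influence on the latent codes in its cell through a
  Gaussian window `w = exp(−‖z − g‖² / τ)` with τ set by the lattice
  spacing, multiplied by a centered input-similarity score: frames whose
  input lies closer to the node's member centroid than the typical
  within-node deviation are drawn onto the node (condensing clusters of
  alike structures — the "preformed clusters"), frames farther than
  typical are pushed off it until the window decays. Both effects
  saturate within about one lattice spacing, so the latent stays bounded,
  mixed nodes resolve instead of locking, and the gradient acts on the
  encoder only — the reconstruction objective is never distorted. A pure
  input-space deviation penalty would carry no gradient (the nearest-node
  assignment is piecewise constant); this windowed form is the package's
  resolution of that ambiguity. With λ = 0 the model reduces to a plain
  denoising autoencoder. The term activates after a warmup (30% of the
  epochs): at initialization the latent range is degenerate and every
  frame shares one node, where the term is meaningless.
* **Restart selection**: a 2D bottleneck can, at unlucky initializations,
  project two distinct conformational states onto the same latent point
  and sit on that plateau indefinitely (a plain-DAE failure mode,
  independent of the grid term). Three candidate initializations are
  therefore trained for a 10% pilot phase and the one with the lowest
  *training-half* reconstruction loss is continued; selection never sees
  holdout frames, and the whole procedure is deterministic given the
  seed.
* **Adam** (lr 1e-3), batch 64, 500 epochs, single fixed seed; the
  implementation is plain NumPy (dense matmuls, manual backprop), fully
  deterministic on CPU.

Half of the shuffled frames train the model; the **holdout MAE** is the
mean absolute per-coordinate reconstruction error (Å) on the uncorrupted
other half. The second encoder width (128) is a design choice (a reducing
funnel to 2D); optimizer, learning rate and batch size are likewise design
choices recorded in the configuration.

A precondition check rejects ensembles with per-frame Cα-centroid drift
above 8 Å: genuine conformational change moves the centroid by a few Å,
residual global translations by tens.

## Bayesian Gaussian mixture

`fit_bgmm` wraps a variational Gaussian mixture (full covariance,
Dirichlet-process weight-concentration prior of 1/K_max, K_max = 9).
Components with weight > 0.02 are *effective*; the threshold is a design
choice recorded in every report. Responsibilities downstream are the
standard Gaussian posterior over the effective components; a frame is a
*boundary* frame when its maximum responsibility is ≤ 0.5 (+1e-9). Each
cluster's representative frame minimizes the latent Euclidean distance to
the component mean. One mixture is fitted on the pooled compositions
(shared clusters across compositions); per-composition fitting is possible
by running the pipeline per composition.

Cluster naming is functional, never fit-order dependent: clusters are
ordered by descending mean head–d1 contacts, and the minimum-contact
cluster is tagged assembly-promoting. A tie within 1e-9 raises an
ambiguous-identification error.

## PLS-DA

Features are the same flattened aligned Cα coordinates the autoencoder
consumes — the only representation consistent with structural
interpolation. Labels are 1 for the assembly-promoting cluster, 0
otherwise; a fresh shuffled half/half split (own seed) trains a
six-component PLS regression; validation R² = 1 − SS_res/SS_tot on the
continuous predictions of the held-out half. For interpolation, the
coordinates are regressed on the in-sample prediction, giving a linear map
t ↦ structure whose endpoints approximate the class-conditional mean
structures.

## Contacts, salt bridges, occupancy, clashes

* An **interaction** is an atom pair across two disjoint selections within
  4.0 Å (heavy-atom center-to-center); counts are per atom pair per frame,
  computed with a k-d tree and exactly equal to the all-pairs count. The
  counting rule and cutoff are recorded in all outputs.
* A **salt bridge** is present in a frame when the minimum distance between
  the pair's charged-group N/O beads is ≤ 4.0 Å (common convention).
* **Occupancy maps** are top-view 2D grids (1 Å spacing) over the
  cytosolic leaflet slab, accumulating per-voxel visit counts of one lipid
  species over frames in the aligned frame of reference; raw-count
  conservation is exact. Pocket occupancy integrates the map over the
  lateral disc of the a2/c-ring pocket.
* **Clashes**: each frame is Kabsch-fitted onto the holo reference on the
  conformationally stable V₀ core (c-ring + d1 — the parts not involved in
  the head/arm rearrangement), and atom pairs between the mobile selection
  (a2 arm by default; head optional) and V1 within 3.0 Å (bead
  center-to-center on the toy fixture; 2.0 Å would suit heavy-atom
  all-atom inputs) are counted. Dispersion in grouped tables is the
  standard error of the mean.

## Synthetic ensembles: what they emulate, and what they do not

No trajectories are deposited for the simulations the analysis was designed
around, so the generator plants a fully known ground truth at desk scale:

* a bead-model V₀ (~200 Cα pseudo-residues: 10-subunit c-ring spanning the
  membrane, d1 blob above the ring, a2 body beside the ring, arm and head
  hinged at the body/pocket edge), with residue numbering that places the
  salt-bridge residues 76/81 (arm), 436 (body) and 126 (c-ring);
* up to **four rigid-body states** of the head+arm: state 0 head-away
  (assembly-promoting: zero head–d1 contacts, both salt bridges formed at
  exactly 3.0 Å), states 1–3 docked toward d1 with increasing proximity
  (increasing contacts, bridges broken). Pairwise pose separations are
  ≥ 10× the noise σ (≥ 3.3 Å Cα-RMS), so recovery is unambiguous by
  construction;
* **isotropic Gaussian coordinate noise** (σ = 0.3 Å), giving an analytic
  reconstruction floor of σ·√(2/π) ≈ 0.239 Å for the holdout MAE;
* optional **random global rigid motion** per frame (uniform rotations,
  ±15 Å translations), drawn from an RNG stream independent of the noise
  stream, so regenerating with motion off reproduces the motion-free
  coordinates exactly — the alignment oracle;
* **leaflet lipid layouts** at the exact integer counts of a membrane
  specification (one headgroup bead per lipid, jittered grid, ≥ 3 Å from
  all protein beads), with an optional pocket bias forcing PI(4)P or
  cholesterol into the a2/c-ring pocket and keeping the other species out;
* **composition-dependent state weights**: the default pipeline plants the
  assembly-promoting state at 25% (pure POPC), 8% (20% PI(4)P), 24%
  (20% PI(4)P + 10% cholesterol) and 40% (10% PI(4)P + 20% cholesterol),
  emulating suppression by PI(4)P and rescue by cholesterol.

The toy holo reference shares the generator's V₀ geometry (state-0 pose)
with a V1 bead block docked above d1, positioned so head-docked poses
clash with it and the head-away pose does not.

What the generator does **not** emulate: physical force fields and
dynamics, side-chain chemistry, water/ions as particles, continuous
conformational transitions (states are discrete rigid poses), lipid
diffusion (layouts are static per ensemble plus thermal noise), or
realistic contact-count magnitudes. Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery on data whose
statistical structure matches its assumptions — not that real membrane
simulations would yield the same numbers.

## Problem sizes and numerical choices

Default study conditions: 2000 frames per ensemble, ~200 Cα beads
(600-dimensional feature space), 980 lipid beads; the full training
protocol is 500 epochs. The multi-seed recovery checks and the
multi-composition pipeline tests use half-length (250-epoch) or
quarter-length (100-epoch) schedules and 500 frames per composition;
state recovery is insensitive to this (the planted separations dominate),
and the shorter schedules are the package's own desk-scale choice.

Other numerics: Kabsch fits reject <3 atoms or collinear selections
(singular-value check at 1e-12); PDB output is fixed-width (coordinates
must fit |x| < 10⁴ Å, round-trip precision 1e-3 Å); mixture
responsibilities are renormalized in log space; boundary tolerance is
1e-9; ties in largest-remainder rounding break by species order
(POPC, PI(4)P, cholesterol) for determinism.

## Known limitations

* The autoencoder latent geometry depends on initialization; only the
  *partition* of frames (not latent positions) is stable across seeds, and
  all cross-seed checks are therefore label-permutation invariant (ARI).
* The grid L2 term contracts within-cluster latent variance strongly;
  latent distances between frames of one state can be near zero, which is
  intended (pre-formed clusters) but makes latent distances unsuitable as
  a continuous order parameter.
* With asymmetric per-leaflet overrides the leaflet-symmetry invariant is
  deliberately relaxed; the standard systems never use them.
* The clash measure is a bead-count proxy; it ranks conformations, it does
  not estimate binding energetics.
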