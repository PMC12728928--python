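# Methods

This note documents the models and procedures implemented in `tmca`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show
about real MD data.

## Data model and units

Coordinates are Å throughout (GRO nm input is converted on read), times
ns, angles degrees. Boxes are orthorhombic only; triclinic input raises an
explicit unsupported-feature error. Residue numbering is taken verbatim
from the input file and never renumbered, so author numbering (e.g. K186,
D50) survives every analysis. Chain identity comes from the chain/segment
field when present; files without one (common for coarse-grained exports)
are split into chains wherever the residue numbering restarts. "Heavy
atom" means element ≠ H; hydrogens are kept when present because the
hydrogen-bond angle needs them. File parsing, writing and minimum-image
distances are delegated to MDAnalysis; the analysis operates on in-memory
NumPy arrays.

Two resolutions are supported: atomistic (or the generator's "aa-lite"
approximation) and coarse-grained with one backbone bead (`BB`) per
residue, the Cα analogue. Contact maps, positioning metrics and the
clustering pipeline run at either resolution; the four geometric
interaction classifiers are atomistic-only and raise `ResolutionError` on
bead models rather than silently returning nothing.

## Contact maps and persistence tiers

A residue pair is in contact in a frame when the minimum distance between
their mode-filtered atoms (default: heavy atoms) is ≤ the cutoff
(default 3.0 Å, minimum-image). The per-pair frequency is the mean of the
binary matrix over frames, so frequency × n_frames is always integral.

The default mode is heavy-atom at 3.0 Å. A Cα–Cα interpretation of the
same cutoff is geometrically near-empty (Cα atoms of residues in contact
sit ~5–6 Å apart), so heavy-atom is the reading that produces meaningful
maps; both mode and cutoff are exposed in the config for sensitivity
checks.

Persistence tiers are assigned by the highest threshold a frequency
*strictly* exceeds — the thresholds (0.6, 0.7, 0.8, 0.9) give the nested
tiers interacting ⊃ t70 ⊃ t80 ⊃ important. "Over 60 %" is read as strict,
so a pair at exactly 0.60 falls below the tier; with integral counts the
distinction is well defined.

The adaptor dimer's two chains are tracked separately; a merged view
(max frequency over chains per residue id) is provided for single-axis
interface plots. Signed difference maps (`overlay_maps`) compare two
systems on identical residue axes.

## Interaction classifiers

* **Hydrogen bond** — donor–acceptor ≤ 3.0 Å and donor–hydrogen–acceptor
  angle ≥ 150° for at least one hydrogen covalently bonded to the donor.
  When the topology carries no bond table, donor–hydrogen bonding is
  inferred geometrically: each hydrogen belongs to its nearest N/O within
  1.2 Å. Donors without any hydrogen are skipped with a warning when
  passed explicitly, and silently treated as acceptor-only in the
  residue-level convenience functions.
* **π–π stacking** — ring centroid = mean of ring atoms; the plane normal
  comes from the first three noncollinear ring atoms. Pairs with centroid
  distance ≤ 6.5 Å are parallel-displaced when the interplanar angle is
  ≤ 30° and T-shaped when ≥ 60° after folding the angle to [0°, 90°]
  (normals are sign-ambiguous, so the nominal 60–120° T-band maps to
  ≥ 60°); 30–60° inside the distance cutoff is deliberately "none".
  Tryptophan contributes both its 5- and 6-membered rings; a frame is
  classified by the best-scoring ring pair with precedence
  parallel > T-shaped > none, ties broken by centroid distance.
* **Hydrophobic contact** — any side-chain carbon–carbon pair ≤ 4.5 Å,
  with backbone N, Cα, C, O excluded. Glycine has no side-chain carbon;
  the contact is defined False with a warning rather than an error.
* **Salt bridge** — minimum N···O ≤ 3.2 Å over the basic-group nitrogens
  (Lys NZ; Arg NH1/NH2/NE; His ND1/NE2 only when the residue name
  indicates protonation, HSP/HIP; the N-terminal backbone N) and acidic
  oxygens (Asp OD1/OD2; Glu OE1/OE2; C-terminal O/OXT). Any listed pair
  suffices. pH handling beyond the residue-name convention is out of
  scope.

Occupancy is the per-pair frame fraction. When several replicas are
supplied, occupancies are averaged per replica first and then across
replicas (mean ± SD). The receptor→dimer hydrogen-bond statistic counts,
per frame, how many adaptor chains (0/1/2) are bonded to the donor
residue; the three fractions sum to 1 and any-bond occupancy is p₁+p₂.

## Flexibility and positioning

* **Alignment** is an optimal rigid-body (Kabsch) superposition of each
  frame onto the first frame's reference selection (default: the adaptor
  chains' Cα/BB atoms). It assumes the complex is whole, i.e. not split
  across the periodic boundary — true for the generator and for typical
  post-processed MD output.
* **RMSF** follows the square-root-of-time-averaged-squared-displacement
  definition per atom, reported per residue through its Cα (BB at CG
  resolution). The mean position is accumulated relative to frame 0,
  which avoids cancellation error and makes a static trajectory yield
  exactly zero. A single frame is rejected (fluctuation undefined).
  Note that aligning to a *jittered* reference inflates RMSF slightly
  (the reference pose carries its own noise); the closed-form validation
  therefore measures an unaligned single-state trajectory, which is
  rigid-motion-free by construction.
* **COM traces** are mass-weighted; depth is reported relative to the
  membrane midplane, which defaults to the box z-center (the synthetic
  slab convention) and accepts an explicit z when lipid positions are
  known. Lateral separation is the x–y projection of the COM difference,
  minimum-image in x and y.
* **Helix tilt** is the angle between the selection's first principal
  axis (SVD of centered coordinates) and the membrane normal, folded to
  [0°, 90°]. Nearly isotropic selections give NaN with a warning instead
  of a meaningless angle.

## Conformational-state discovery

Features: backbone beads every 5 residues along each helix (anchored at
the first helix residue; anchor and stride configurable), receptor × each
adaptor chain distance matrices computed independently per frame,
flattened row-major and concatenated. Embedding: UMAP to 2D with
`min_dist = 0.1` (the algorithm's conventional default; the choice is
config-exposed) and a fixed `random_state` (default 42) recorded in the
output metadata — with a seed the whole pipeline is deterministic, and
across seeds labels agree up to permutation. Clustering: HDBSCAN on the
embedding with `min_cluster_size = 50` and a flat-cut
`cluster_selection_epsilon` (2.0 with `n_neighbors` 50, or 1.5 with
`n_neighbors` 10, in the two default parameter sets).

`allow_single_cluster` is enabled by default: HDBSCAN's default tree
selection never returns the hierarchy root, so a system genuinely
sampling one state would otherwise come back as all noise. With the flag,
a unimodal embedding yields one cluster and multimodal embeddings are
unaffected.

Noise frames (label −1) are counted in the population fractions (they
are real frames) but excluded from representative-structure selection.
The representative of a cluster is its embedding-space medoid — the
member minimizing summed distance to co-members, ties broken by earliest
frame. Medoid selection is a package convention; no claim is made that it
reproduces any particular external snapshot-selection rule.

The estimator (`ConformationalStates`) follows scikit-learn conventions
(`fit`, `fit_predict`, `get_params`/`set_params`, trailing-underscore
fitted attributes) so it composes with sklearn tooling; the surrounding
stages are plain functions over trajectories.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
membrane physics:

* three ideal α-helices (rise 1.5 Å/residue, twist 100°/residue, Cα
  radius 2.3 Å) in a slab geometry — a receptor-like chain A (default
  author numbering 181–219 with Lys/Trp/Glu motif positions) and two
  identical adaptor-like chains B/C (41–75 with Asp/Tyr/Arg positions);
* "aa-lite" residues carry backbone N/H/Cα/C/O plus exactly the named
  side-chain atoms the classifiers read (charged-group N/O, aromatic ring
  atoms including the fused Trp rings, side-chain carbons, polar
  hydrogens) at plausible but idealized geometry — sufficient because
  every classifier is a distance/angle rule over named atoms, and full
  rotamer realism is explicitly not modelled;
* metastable states are rigid poses (lateral separation, depth, tilt) of
  the receptor against a fixed vertical adaptor dimer, with exact
  mass-weighted COM placement so planted separations and offsets are
  ground truth before jitter. Switching follows a seeded Markov chain;
  the default transition matrix keeps a state with probability 0.8 per
  frame (uniform otherwise). Frames emulate sparsely saved snapshots of
  long coarse-grained runs, so successive frames are weakly correlated;
  the ~5-frame dwell keeps states metastable while 2000-frame empirical
  fractions concentrate near the stationary law;
* planted interactions override the minimal atom set of a residue pair
  per frame, placing on-geometries well inside the cutoffs (salt bridge
  2.9 Å, H-bond 2.8 Å at 180°, rings at 3.8 Å parallel or 5.0 Å
  perpendicular, side-chain carbons at 4.0 Å) and off-geometries well
  outside. Schedules are deterministic with exact counts
  (largest-remainder rounding spread by a golden-ratio ordering), so an
  occupancy with an integral frame count is recovered *exactly* at zero
  jitter;
* jitter is isotropic Gaussian per atom per frame, applied after the
  interaction overrides; correlated motions are out of scope;
* the dissociation preset is a two-state chain with an absorbing
  transition from a bound pose (6 Å, 10°) to a displaced, nearly
  horizontal, leaflet-shifted pose (11.2 Å, 80°, −8 Å).

Same seed → bit-identical output. Every planted quantity is recovered by
the corresponding analysis module; this is the package's principal
validation surface.

**What passing these tests does not show:** the generator has no lipids,
no force field, no correlated dynamics, idealized side-chain geometry and
literal (not thermodynamic) state switching. Agreement on synthetic data
validates the *bookkeeping and geometry* of the analyses — cutoff logic,
periodic imaging, mass weighting, tier boundaries, pipeline determinism —
not their behavior on the rough energy landscapes of real trajectories.

## Problem sizes and numerical choices

Validation runs use 100 jittered frames (≤ 500 atoms) for the
classifier-vs-brute-force suite, 10⁴ frames for the RMSF closed form
(σ = 0.5 Å/axis per atom gives RMSF → σ√3 ≈ 0.866 Å), and 2000 frames for
schedule recovery, state recovery (k ∈ {1,2,3} under both default
parameter sets) and the dissociation scenario. Distance comparisons
happen in float32 (the MDAnalysis distance backend); boundary tests
probe cutoffs at ±0.05–0.1 Å and ±1°, comfortably above that precision.
Degenerate inputs are defined rather than left to chance: collinear ring
triples fall through to the next atom, all-collinear rings error,
zero-mass COM groups error, empty selections warn.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum-image.
* Alignment and COM metrics assume molecules are whole across the
  periodic boundary (no automatic unwrapping).
* No cation–π, water-mediated bridges, or interaction energetics.
* His protonation is read from residue names only.
* Cluster labels are arbitrary across seeds (matched by population, not
  identity); representative frames are medoids by convention.
* The contact-kinetics domain (on/off rates, transition rates between
  states) is explicitly out of scope.
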