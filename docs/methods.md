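# Methods

## Scope and model

The package analyses the structural integrity of guanine-quadruplex (G4)
conformational ensembles, with strand-break lesions treated as an
annotation + connectivity layer rather than a chemical rebuild. The
working model is the intramolecular parallel G4 of the human telomeric
repeat `AGGGTTAGGGTTAGGGTTAGGG`: three stacked tetrads, each taking one
guanine from each of the four G-tracts (tetrads {2,8,14,20}, {3,9,15,21},
{4,10,16,22}), three TTA propeller loops (residues 5–7, 11–13, 17–19), a
5′ adenine overhang, and K⁺ ions in the central channel.

## Strand breaks

A break severs one phosphodiester O3′(i)–P(i+1) bond between residues i
and i+1 (1-based, written "i–(i+1)"). Chemistry determines the termini:
CA leaves 3′-OH upstream and 5′-PO₄⁻ downstream (bridging phosphate
assigned downstream); NC leaves 3′-PO₄⁻ upstream and 5′-OH downstream
(phosphate assigned upstream). `apply_breaks` removes exactly one
connectivity edge per break and never moves an atom; atom-level
reconstruction of the terminal groups (and any force-field or charge
work) is out of scope. The standard damage scheme enumerates 6 single
and 6 double breaks in the tetrad-connecting backbone in both
chemistries plus 3 loop breaks in CA only — 27 configurations. The loop
positions are not uniquely fixed by convention; the default (5–6, 11–12,
17–18, the first junction inside each TTA loop) is a documented choice
and is configurable.

## Tetrad detection

A directed Hoogsteen pair i→j is recorded when both heavy-atom
donor–acceptor distances, N1(i)–O6(j) and N2(i)–N7(j), are at most
`hoogsteen_dmax` (default 3.5 Å). A pure distance criterion (no
hydrogen positions, no angle term) is used deliberately: lesioned
termini change hydrogen counts, and heavy-atom distances are robust to
that. Tetrads are the simple directed 4-cycles of the pair graph; when
a guanine appears in several candidate cycles the cycle with the
smaller mean donor–acceptor distance wins, ties broken by residue
indices, so detection is deterministic. Tetrads are sorted along the
principal axis through their centroids, the axis sign fixed 5′→3′ along
the strands, and cyclic orders are rotated so that column k of every
tetrad lies on the same strand wherever strand continuity allows.

Membership is detected once and then *tracked*: per-frame descriptors
re-evaluate only the geometry of the fixed membership, which makes every
descriptor invariant under rigid motion of a frame. Detection runs on
the rigid-aligned mean of the first `detection_window` frames (default
20): aligning each frame to frame 0 by Kabsch superposition and
averaging shrinks coordinate noise by √n, giving a low-noise stand-in
for the reference geometry. This is robust where single-frame detection
on a thermally fluctuating frame is not, and a window at the start of
the trajectory keeps later destabilization events from contaminating the
reference. Per-frame re-detection remains available explicitly.

## Descriptors

- **Guanine angles.** The angle subtended at the tetrad centroid (mean
  of the four base centres of mass; base heavy atoms, mass-weighted) by
  two base COMs. Adjacent pairs are cyclic neighbours (90° in an ideal
  quartet), opposite pairs are diagonals (180°).
- **Rise / COM distance.** Euclidean distance between the mass-weighted
  COMs of all heavy atoms of the two tetrads' guanine residues.
- **Twist.** For each tetrad, the four C1′→C1′ edge vectors between
  cyclically adjacent strand columns are projected onto the plane
  perpendicular to the channel axis; the twist between two tetrads is
  the circular mean of the four signed angles between corresponding
  projected vectors, positive for a right-handed rotation looking down
  the axis. The C1′ convention is the default; glycosidic N9 vectors
  are offered as an alternative (the two agree exactly on ideal
  geometry). This definition is normative for this package.
- **RMSD.** Kabsch superposition (proper rotations only; reflections
  excluded; collinear inputs flagged as non-unique). The single-pair
  API uses `scipy.spatial.transform.Rotation.align_vectors` with the
  residual re-evaluated explicitly — the closed-form residual loses
  ~1e-7 Å to cancellation near zero, which matters for invariance
  checks. Series and 2D maps use a batched SVD implementation
  (cross-checked against the scipy path in tests). The "tetrads only"
  selection is base+sugar heavy atoms of tetrad guanines; "whole DNA"
  is all nucleic heavy atoms; both configurable. 2D maps auto-stride to
  at most 2000 frames per side.
- **Angles are reported in degrees** and all angle aggregation
  (means, distribution widths, mode shifts) uses circular statistics;
  twist histograms default to 2° bins.

## Ions and events

The channel is a cylinder around the per-frame tetrad axis: an ion is
inside when its axial-distance ≤ `channel_radius` (3.0 Å) and its axial
projection lies within the first/last tetrad centroids ± `channel_margin`
(2.0 Å). A leakage event is an in→out transition persisting at least
`leak_min_out` frames (10; hysteresis against flicker); re-entry is
recorded. A tetrad guanine that loses both of its cycle Hoogsteen bonds
for at least `event_min_frames` frames (20) is a tetrad-disruption
event; it is promoted to guanine expulsion when its base COM moves more
than `expulsion_dist` (8 Å) *beyond its attached baseline distance* from
the centroid of the three remaining guanines. Measuring the excess over
the baseline (median over attached frames) makes the threshold a true
displacement, independent of the quartet's intrinsic radius — an
absolute distance would misclassify small displacements because the
resting base COM already sits several Å from the centroid.

**Verdict.** A structure is destabilized iff at least one
disruption-class event persists to the final frame. Cation leakage is
always recorded but flips the verdict only through its structural
consequence (a persistent disruption/expulsion), mirroring the
observation that cation loss destabilizes a G4 only when the quartet
itself comes apart. "Stable" in the source literature is a qualitative
call; this persistent-event rule is the package's operationalization,
with every threshold exposed in `Thresholds` (TOML-loadable). Replicas
are analysed independently and reported side by side.

## Synthetic data

The builder places an idealized planar guanine base (standard
reference-frame geometry) at exact 4-fold rotations per tetrad; tetrad k
is rotated k·twist about the axis and translated k·rise (defaults 30°,
3.3 Å). The in-plane base orientation and C1′ radius were calibrated
numerically once — solving for both Hoogsteen heavy-atom distances equal
to 2.9 Å — and frozen as constants (`TETRAD_PHI`, `TETRAD_ALPHA`,
`DEFAULT_C1_RADIUS` ≈ 8.21 Å; derivation script in `scripts/`). The
resulting channel O6 radius is 2.3 Å, consistent with K⁺ coordination.
Every tetrad guanine, backbone included, is an exact rigid image of one
template, which is what makes twist/rise recovery exact (to 1e-6) at
zero noise. Loop residues are laid on smooth outward-bulged arcs; their
junction O3′–P contacts with the rigid core sit slightly beyond bonding
distance, which is why connectivity inference (gated at 2.0 Å) is a
fallback and explicit CONECT records are always written. One K⁺ sits on
the axis midway between consecutive tetrad planes.

The ensemble generator adds i.i.d. Gaussian per-coordinate noise —
`sigma_core` (default 0.4 Å) on tetrad residues and ions, 4× that on
loops — plus an optional global random rigid motion per frame (on by
default so invariance bugs surface in tests), and deterministic injected
events (radial cation displacement; radial guanine translation with
Hoogsteen partners left in place) from their onset frame. All
randomness flows from a single mandatory seed. The noise is a variance
model, not a physical one: it emulates the rigid-core/flexible-loop
statistical structure of a stable ensemble and the package's estimators
and thresholds against it, but it has no kinetics, no correlated modes,
and no force field — passing tests demonstrate correctness of the
estimators and event logic, not the physical stability of any real
sequence.

## Numerical choices and problem sizes

- Plane fits and axes via SVD; degenerate (collinear/coincident) inputs
  raise or are flagged rather than silently resolved.
- Twist recovery tolerances: exact (1e-6) at zero noise; within 1° at
  0.3 Å core noise over 100 frames. Rise: 0.1 Å under the same noise.
- The stable-core reference ensemble is 500 frames at 0.4 Å core noise;
  its tetrad-selection RMSD 95th percentile is ≈1.0 Å, comfortably
  below the 3 Å band used as the qualitative "intact core" bound.
- The 27-structure verdict batch uses 150-frame ensembles per
  configuration — enough for the 20-frame persistence windows and exact
  onset recovery of injected events while keeping the batch fast.
- PDB round trips are exact to the 3-decimal fixed-width PDB precision
  (max coordinate error ≤ 5×10⁻⁴ Å plus float32 read quantization).

## Known limitations

Only PDB (multi-model) I/O is supported; mmCIF and binary trajectory
formats are out of scope. Topology classification (parallel vs
antiparallel/hybrid by glycosidic angles), bulges, groove widths and
duplex-style helicoidal parameters are not computed. The synthetic
loops are geometric placeholders, not conformationally realistic TTA
loops. Folding propensity — whether a damaged sequence would fold in
the first place — is explicitly outside the model: the pipeline always
starts from a folded reference.
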