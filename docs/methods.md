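# Methods

tmdkit analyses multi-frame Cα (or full-atom) ensembles of transmembrane
helix bundles with the stages used in comparative studies of elevator-type
SLC transporters: fluctuation/equilibration bookkeeping, a conformational
landscape (RMSD → MDS → mixture clustering), persistence-weighted residue
interaction networks, gate-aligned core shift/tilt descriptors, and ion
binding-event detection.  This note records the models, the parameters
that matter, and the choices made where the methodology is genuinely open.

## Coordinate and indexing conventions

Right-handed axes with z along the membrane normal; positive z points to
the extracellular side, so a positive core shift Δz is an "upward"
elevator movement.  All lengths are in Å, times in ns, residue indices
1-based as in PDB files.  The membrane normal is taken as the z-axis of
the input frame; no bilayer fitting is performed (lipids are out of
scope), so trajectories must be oriented accordingly (as OPM-placed
membrane systems are).

## Superposition and RMSD

Rigid superposition is the Kabsch least-squares fit with reflections
excluded (the smallest singular direction is sign-flipped when needed, so
det R = +1 always).  Single pairs go through
`scipy.spatial.transform.Rotation.align_vectors`; frame stacks use an
equivalent batched 3×3-SVD path, and the two are cross-checked in the
tests.  Collinear selections degrade gracefully: the rotation about the
degenerate axis is arbitrary but the RMSD is still minimised.

The all-vs-all RMSD matrix superposes **each pair independently** (no
common reference).  This matches the idea of a distance between
conformations, at the cost of the triangle inequality: the matrix need
not be Euclidean, which is why the MDS spectrum can contain small
negative eigenvalues (truncated to zero, with a logged warning).

## Fluctuation filtering and equilibration

RMSF is computed on Cα after iterative superposition onto the ensemble
mean (tolerance 1e-6 Å on the mean).  Because superposition absorbs six
rigid degrees of freedom, the RMSF of pure isotropic noise is biased
down by the factor √(1 − 6/3N); tests account for this.

The loop filter retains residues below a configurable RMSF cutoff; the
default rule is the 80th percentile of the profile, standing in for the
visual "drop the floppy loops" step of interactive analysis.  The filter
runs before the RMSD matrix (filter first, then matrix).

Equilibration is declared by a sliding-window plateau rule on the
RMSD-to-reference series: the first frame index from which consecutive
window means (window 25 frames, tolerance 0.1 Å by default) differ by
less than the tolerance *through to the end of the series*.  This is a
reproducible, conservative replacement for judging equilibration from an
RMSD-matrix picture; for a trajectory that hops between conformational
basins block-wise it flags the start of the final stable block.  A series
that never plateaus yields `None` plus a diagnostic rather than a guess.

## Conformational landscape

Classical (Torgerson) MDS: double-centre −½·J·D²·J and embed with the top
two eigenpairs.  Classical scaling was chosen over metric-stress (SMACOF)
because it is deterministic and exactly reproduces Euclidean
configurations, which gives sharp test oracles.

Clustering is a full-covariance 2-D Gaussian mixture fitted by EM (best
of n kmeans++-seeded restarts; convergence at relative log-likelihood
change < 1e-8, at most 500 iterations; covariance ridge 1e-6).  The EM is
implemented in the package so the per-iteration log-likelihood trail is
available and monotonicity is asserted in the tests;
`sklearn.mixture.GaussianMixture` is the independent cross-check, not the
implementation.  Restarts whose converged responsibilities give any
component less than d+1 points of support are treated as likelihood
singularities (a collapsed component with ridge-floor covariance can
inflate the likelihood without describing structure) and are discarded in
favour of the best non-degenerate restart; if every restart degenerates,
the best one is returned with a warning.

Model selection minimises BIC = p·ln(F) − 2·logL with
p = (K−1) + 2K + 3K free parameters for K full-covariance components in
2-D; ties resolve to the smaller K.  The default scan is K = 1..10.

Essential-dynamics PCA: frames are aligned to the last frame, averaged,
then re-aligned to the mean until self-consistent; the 3N×3N covariance
of the aligned Cα coordinates is eigendecomposed.  Projection of a second
ensemble aligns each of its frames to the PCA mean and dots the
displacement with the eigenvectors; overlap of projected clouds is
quantified by a Gaussian Bhattacharyya distance.

## Interaction networks

Edges are typed residue-residue interactions weighted by persistence
(percentage of frames in which the geometric criterion holds).  Full-atom
criteria follow the PyInteraph conventions:

| type        | criterion                                             | default |
|-------------|-------------------------------------------------------|---------|
| hydrophobic | side-chain COM distance, residues in the hydrophobic set {ALA VAL LEU ILE MET PHE TRP PRO} | ≤ 5.0 Å |
| H-bond      | donor-acceptor heavy-atom (N/O) distance; D-H-A angle ≥ 120° when hydrogens are present | ≤ 3.5 Å |
| salt bridge | minimum charged-group distance, Asp/Glu vs Lys/Arg (His only if the protonated-His flag is set) | ≤ 4.5 Å |

All cutoffs and the residue sets are configurable.  Cα-only systems (the
synthetic bundles) use Cα-proxy criteria with the same cutoffs and
residue-name gating.  Sequence-adjacent pairs (|i−j| ≤ 1) are excluded to
avoid trivial backbone contacts.  A residue's degree counts each
pair-and-type edge separately (two typed interactions between the same
pair count twice); hub tables list residues at or above `hub_min_degree`
(default 7, the regime of published full-atom TMD hub tables; the toy
bundles in `analysis/` use 3, since a Cα-only 6-helix bundle cannot reach
side-chain contact degrees).

The persistence threshold is selected by the largest-hydrophobic-cluster
criterion: scan thresholds (0..100 in 0.5 steps), track the size of the
largest connected component of the hydrophobic subgraph, and take the
first scan point after the steepest single-step drop (ties → lowest
threshold; a flat curve returns the scan midpoint with a warning).

Core/gate hub percentages are rounded with the largest-remainder rule so
they always sum to 100.  Shortest paths are unweighted BFS paths on the
thresholded graph, all returned when degenerate.

## Core/gate geometry

Helix axes use the gmx-bundle half-COM convention: the unit vector from
the COM of the N-terminal half of the helix Cα trace to the COM of the
C-terminal half (odd counts put the middle residue in both halves).  The
tilt is arccos(axis·ẑ) ∈ [0°, 180°].  For a finite ideal α-helix the
half-COM axis deviates from the geometric axis by a few degrees because
the helical phase does not average out over a half — differences of tilt
between two states of the same helix are unaffected, which is what the
reports use.  An SVD-based principal axis is provided as an alternative.

The shift/tilt report superposes every outward-state frame onto a single
representative inward structure **using the gate Cα only**, then records
per core TM the mean ± sd of Δz (core-TM COM z minus its value in the
reference) and Δtilt (signed, outward minus inward).  Any rigid transform
applied uniformly to the outward ensemble cancels exactly.  Extra regions
declared in the domain map (e.g. a binding-site β-sheet, "BS") get their
own rows.  The representative inward structure is the medoid of the most
populated mixture cluster (smallest mean Cα RMSD to the other members,
first frame on ties); averages are taken over every post-equilibration
outward frame rather than cluster representatives.

## Ion binding events

An ion contacts a residue when it is within the cutoff (default 4.0 Å) of
the residue's nearest heavy atom (Cα on Cα-only systems).  A binding
event is a maximal run of frames with at least one site-residue contact,
with interruptions up to `gap_tolerance` frames bridged and merged runs
shorter than `min_duration` dropped.  There is no community-standard
quantitative definition of a residence event, so both knobs are exposed
and recorded in every report; the analysis defaults are min_duration 5
frames and gap_tolerance 1 frame ("several frames" of sustained residence,
"one frame" of allowed flicker — at a typical 0.5 ns frame spacing these
read as 2.5 ns and 0.5 ns).  Event counts are monotone non-increasing in `min_duration`
unconditionally; in `gap_tolerance` they are monotone non-decreasing only
while the tolerance stays below the separation between genuine episodes
(beyond that, merging two valid events reduces the count) — the tests
exercise the qualified form.  Anchor residues are ranked by total
ion-contact frames, ties broken by residue index.

## Synthetic data: what it emulates, and what it does not

The generators build Cα-only ideal helix bundles (2.3 Å radius,
100°/residue twist, 1.5 Å rise) on a circle, and plant:

* **basins** — block-ordered metastable states, each a rigid displacement
  of a chosen residue set plus iid isotropic Gaussian noise per atom per
  frame;
* **contacts** — typed pairs held inside/outside their cutoff in an exact
  number of frames (a residue may anchor several planted edges but be
  moved for at most one);
* **elevator pairs** — the outward state is the inward state with each
  core helix translated along z and tilted about the in-plane axis
  perpendicular to its own axis-z plane, so the planted tilt change is
  exact by construction;
* **ion schedules** — scripted residence episodes within 3 Å of the
  binding-site Cα centroid (placed so a 4 Å contact cutoff is
  simultaneously satisfied; this requires the nearest site residue within
  6 Å of the centroid), with off-schedule random-walk positions kept ≥8 Å
  from the centroid and clear of site contact.

The noise model is white in time and isotropic in space: there are no
kinetics, no solvent, no force field, and no correlated motions beyond
the planted ones.  Passing recovery tests therefore demonstrates that the
estimators extract planted structure at realistic fluctuation amplitudes
(0.1–0.3 Å noise, Å-scale conformational offsets); they say nothing about
sampling convergence or force-field realism of real trajectories.

The four-system study in `analysis/` fixes the conditions: basin counts
rI 4, rO 5, zI 7, zO 5 (the inward counts are the reported range
endpoints; the outward counts are an intermediate choice, since no
outward counts are published); elevator parameters (Δz, Δtilt) of
(+1 Å, 4°) for the r pair versus (+3 Å, 12°) for the z pair (a marginal
versus a clear elevator signature); ion schedules of 3 versus 22 episodes
(10 frames each, 20 clean frames apart).  These values are set once in
`analysis/common.py` and are not tuned per run.

## Numerical and degenerate-input policy

* XTC output is written at 1e-4 nm fixed-point precision so coordinates
  round-trip within 1e-3 Å (the format default of 1e-3 nm would allow
  1e-2 Å errors); DCD is float32-exact.
* PDB parsing treats only standard amino acids as protein, resolves
  alternate locations by highest occupancy (first on ties), and requires
  globally unique residue indices across chains (duplicate numbering is
  rejected with instructions rather than silently renumbered).
* A protein residue without a Cα, an atom-count mismatch between topology
  and trajectory, selections below the minimum sizes (3 atoms for
  superposition, 3 residues for an RMSD matrix, 6 residues for a helix
  axis, 3 gate residues for alignment) are hard errors; an empty RMSF
  filter result is a warning.
* Mixture covariances carry a 1e-6 ridge; non-SPD updates get a further
  1e-6 bump with a warning.

## Known limitations

* Cα-proxy contact criteria compress the geometric diversity of real
  side-chain interactions; on full-atom inputs the H-bond angle term is
  only applied when hydrogens are present.
* The pairwise-superposition RMSD matrix is O(F²) in frames; use the
  stride argument for long trajectories.
* Degree is the only centrality; no betweenness or eigenvector measures,
  no energy- or correlation-weighted networks.
* The equilibration rule and the threshold knee are heuristics with
  configurable parameters; both report their inputs so runs are
  comparable.
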