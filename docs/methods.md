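# Methods

## Scope and data model

`canonloop` analyses the backbone conformations of the six
complementarity-determining regions (CDRs) of T-cell receptors and
antibodies. A loop is the CDR window in IMGT numbering — CDR1 27–38,
CDR2 56–65, CDR3 105–117 — plus five framework anchor residues on each
side. Each residue carries the four backbone atoms N, CA, C, O with
coordinates and B-factors; the CDR sequence excludes the anchors.
IMGT numbering is consumed, never computed: inputs are either
pre-renumbered structures (the STCRDab/SAbDab convention) or plain PDB
files with a sidecar TSV mapping author numbering to IMGT positions.
Receptor class (TCR / antibody / nanobody) and chain type (α/β or
light/heavy) are metadata supplied by the caller; they are not inferred
from sequence. α and light chains (and β and heavy chains) are treated
as equivalent for joint clustering, reflecting their shared V(D)J
recombination origin.

## Quality filters

A loop is kept only if

- the parent structure's resolution is ≤ 2.8 Å (a missing resolution,
  e.g. an NMR model, fails this filter — the method is calibrated on
  crystallographic coordinates);
- every residue of the CDR-plus-anchors span has all four backbone
  atoms, with finite coordinates;
- no backbone atom in the span has a B-factor above 80;
- every consecutive C–N peptide bond in the span is below 1.37 Å
  (chain continuity).

Each rejection carries a machine-readable code (`RESOLUTION`,
`MISSING_BACKBONE`, `HIGH_BFACTOR`, `CHAIN_BREAK`, `MISSING_ANCHORS`)
identifying the one filter that failed. Alternate-location atoms keep
the highest-occupancy conformer (ties: first encountered). Residues
sort by integer IMGT position with a stable sort, so insertion codes
keep file order — which is the IMGT chain order, with descending
insertion letters on the C-terminal side of the loop apex.

## Structural distance

Two loops are compared by (1) least-squares superposition (Kabsch, SVD
with reflection correction, so the rotation is always proper) of the 40
backbone atoms of the ten anchors, then (2) dynamic time warping over
the CDR residue series. The local cost of matching residue *i* of one
loop to residue *j* of the other is the root-mean-square of the four
backbone-atom distances. The DTW path runs boundary-to-boundary with
diagonal/horizontal/vertical steps; the score is the total path cost
divided by the path length, giving an Å-scale, length-independent
RMSD-like measure. The dynamic program minimises (total cost, path
length) lexicographically — the secondary criterion is needed because
path-length normalisation otherwise leaves ties ambiguous; the
lexicographic rule is monotone under path extension, so the DP is
exact (verified against exhaustive path enumeration for short loops).

The backbone atom set {N, CA, C, O} is used throughout superposition,
RMSD and DTW cost. `backbone_rmsd` superposes either on the CDR
backbone itself (`fit_on="loop"`, the default for conformational
comparisons) or on the anchors (`fit_on="anchors"`, which measures
deviation in the framework frame); both are exposed because published
loop-RMSD figures do not always state the fit.

## Clustering and class designation

DBSCAN runs on the precomputed distance matrix. A core point has at
least `min_pts` neighbours within `eps` (inclusive, self counted);
clusters are connected components of core points; a border point joins
the cluster of the first core point within `eps` in input order, after
a stable sort of loops by id — this border rule is pinned so catalogs
are bit-reproducible, which is why the clustering is implemented
in-package rather than delegated (an external DBSCAN is used as an
independent oracle in the tests).

Defaults: TCR-only clustering uses `eps` = 1.0 Å and `min_pts` = 5 per
CDR type. Joint TCR/antibody clustering uses per-pair thresholds
α1/L1 0.82, α2/L2 1.0, α3/L3 0.91, β1/H1 0.80, β2/H2 0.63 Å (all in
config). Designation then applies the validity rules: in TCR-only mode
a cluster with ≥ 5 structures and ≥ 2 unique sequences is a canonical
class, with ≥ 5 structures but a single unique sequence a pseudo-class,
anything else is unclustered; in joint mode a valid class needs ≥ 6
unique sequences and everything else is unclustered (pseudo-classes
are a TCR-only concept here — the joint rule subsumes them). The
minimum cluster size is enforced both as DBSCAN `min_pts` and at
designation; the two coincide on all fixtures used.

Names follow the `α1-6-B` convention: CDR label(s), observed loop
length(s), then a letter ranking classes of the same label and length
set by unique-sequence count (ties: member count, then smallest member
id); pseudo-classes get a trailing `*`; joint names carry both labels
and all observed lengths (`α1,L1-11,12-A`). Class representatives are
medoids (minimum summed distance; ties to the smallest id). Catalogs
from different datasets are matched by shared member structure:chain,
or failing that by a sequence-identical proxy whose backbone RMSD to
the foreign representative is ≤ 1.0 Å.

## Sequence-based prediction

Each canonical class yields a position-specific scoring matrix over the
IMGT positions observed in its unique training sequences:
`s(a,i) = log2(p_a,i / b_a)` with a flat background `b_a = 0.05`.
Probabilities are estimated from unique sequences only (duplicates
carry no weight) and there is no smoothing; a residue never observed at
a position scores −1 at lookup. A query of length *l* is scored against
the same-length PSSMs; `P_c = Σ_i s(a,i)`. The best class is assigned
if `P_c > 1`, except CDRα3 where `P_c ≥ l` is required (a stricter rule
for the most diverse loop). Ties break by larger training set, then
name. Exact sequence identity to any class short-circuits scoring and
is the *only* route into a pseudo-class.

Leave-one-out cross-validation rebuilds all PSSMs without the held-out
sequence and counts: true positive = assigned to its own canonical
class; false positive = assigned to any other class; true negative =
unclustered and unassigned; false negative = from a class but
unassigned. Blind-test predictions count as correct when any member of
the assigned class is within 1.0 Å backbone RMSD (inclusive) of the
native loop. Repertoire-sequencing records are pre-filtered to
productive rearrangements with CDR1 and CDR2 of at least five residues
and CDR3 of at least eight.

## CDR3 torso geometry

The torso (base) of CDR3 is characterised by four measures:

- **τ116**: the interior angle at the Cα of IMGT position 116, formed
  with the Cα of the residues immediately before and after (chain
  order, so insertion codes are handled naturally);
- **α116**: the pseudo dihedral over the Cα atoms of the residue before
  116, 116 itself, and the two following residues (IUPAC sign, cis =
  0°); the loop is classified *kinked* iff α116 > 0, else *extended*
  (the α = 0 boundary goes to extended);
- **LAT** (loop anchor transform): at residues 105 and 117 a local
  frame is built with origin Cα, z toward the carbonyl C, y
  perpendicular to z in the N–Cα–C plane, x = y × z; the 6-DOF
  transform (translation X, Y, Z in the 105 frame; intrinsic z-y-z
  Euler angles φ, ψ, θ) carries frame(105) to frame(117). Any fixed
  Euler convention is equivalent up to relabeling; z-y-z is recorded in
  the API and validated by round-trip (applying the transform to
  frame(105) reproduces frame(117)) and by invariance under global
  rigid motion.
- **torso φ/ψ**: backbone torsions of the first three (T1–T3) and last
  four (T4–T7) CDR3 residues; φ of a chain start, ψ of a chain end and
  torsions across a broken (≥ 1.37 Å C–N) junction are undefined.

## Synthetic data

The generator builds idealised loops from per-residue (φ, ψ, ω)
torsion profiles by sequential internal-coordinate construction with
fixed bond lengths/angles (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O
1.231 Å; N–CA–C 111.0°, CA–C–N 116.2°, C–N–CA 121.7°, CA–C–O 120.8°),
so chains are exactly continuous and measured torsions reproduce the
profile to machine precision. Anchors are β-strand-like; B-factors are
set to 30 and resolution metadata to 2.0 Å, so a clean fixture passes
every filter.

Planted cluster sets use torsion profiles whose pairwise DTW distances
exceed 3× the clustering threshold, per-member torsion noise (default
0.3°, giving an intra-family DTW spread well below eps/2) and Cartesian
coordinate noise (default 0.005 Å per coordinate — small enough that
the C–N bond-length slack of ~0.04 Å to the continuity cutoff is a
> 5σ event, so noisy fixtures never trip the chain-break filter).
Both calibration conditions are asserted at generation time. Family
sequences mimic canonical-class motifs: single point mutations of a
per-family consensus over a family-private residue alphabet, which
makes families separable in sequence space as well as structure space.
Torso fixtures use two frozen torsion profiles whose α116 lands near
−100° (extended) and +105° (kinked) with ±3° torsion noise, leaving a
wide margin to the sign boundary. RMSD fixtures displace all CDR atoms
along one unit direction with anchors untouched, so anchor-frame
backbone RMSDs equal the planted offsets exactly.

What the generator does **not** emulate: side chains, realistic loop
closure (the two anchor stretches are not packed against a framework),
crystallographic noise models, or the length distributions of real
repertoires. Passing tests therefore demonstrate the correctness of
the algorithms and their documented conventions, not predictive
performance on experimental structures.

## Problem sizes and numerical choices

The tests and the acceptance script run planted datasets of 3 families
× 7 loops (the smallest size that exercises the ≥ 5-structure rule
with headroom), 20 random repetitions for cluster recovery, 200 random
pairs for the DTW oracle, 100 seeds per torso class and 100 random
inputs per geometry oracle — sizes chosen so each property is sampled
broadly while the whole suite stays fast. Angle oracles are checked to
1e-9°, rigid-motion invariance to 1e-6 (Euler extraction near gimbal
lock limits tighter bounds), exact combinatorial results (DTW vs
enumeration, planted partitions, closed-form scores) to 1e-12 or
exactly. Degenerate inputs (collinear point sets, coincident points,
< 3 points) raise rather than return ill-conditioned results.

## Known limitations

- Joint-mode clustering reports no pseudo-classes (see designation
  rules above); datasets where that distinction matters should be run
  per receptor in TCR-only mode as well.
- `torso_class` uses the α116 sign only; it does not reproduce any
  published region polygons in the (τ, α) plane.
- PSSM probabilities are unsmoothed; classes with very few unique
  sequences give brittle scores away from their consensus (mitigated by
  the exact-match route and the unseen-residue floor).
- The PDB writer rounds coordinates to 3 decimals; write→read round
  trips are exact only to that precision.
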