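# canonloop

Canonical-class analysis of the complementarity-determining region (CDR)
loops of T-cell receptors (TCRs) and antibodies.

The six CDR loops form most of an antigen receptor's binding site. Five
of them adopt a limited repertoire of backbone conformations — the
*canonical classes* — which makes it possible to predict a loop's
structure from its sequence alone. `canonloop` implements that analysis
stack for structural immunologists and antibody/TCR engineers:

- **Extraction** of IMGT-defined CDR loops (CDR1 27–38, CDR2 56–65,
  CDR3 105–117) with five anchor residues per side from PDB structures,
  behind strict quality filters (resolution ≤ 2.8 Å, complete backbone,
  B-factors ≤ 80, peptide bonds < 1.37 Å).
- **Length-independent structural clustering**: loops are superposed on
  the backbone atoms of their ten anchor residues, compared by dynamic
  time warping (DTW) over per-residue backbone atom sets — an RMSD-like
  score in Å that tolerates length differences — and clustered with
  DBSCAN on the precomputed distance matrix (1.0 Å threshold for
  TCR-only clustering; per-CDR thresholds for joint TCR/antibody
  clustering). Clusters with ≥ 5 structures and ≥ 2 unique sequences
  become canonical classes; single-sequence clusters become
  pseudo-classes (named with a trailing `*`).
- **Sequence-based prediction**: per-class position-specific scoring
  matrices with `s(a,i) = log2(p_a,i / b_a)`, flat background
  `b_a = 0.05`, an unseen-residue score of −1, and class assignment by
  the summed score `P_c = Σ s(a,i)` with threshold `P_c > 1`
  (`P_c ≥ l` for CDRα3); leave-one-out cross-validation and blind-test
  scoring (correct if any class member is within 1.0 Å backbone RMSD of
  the native loop).
- **CDR3 torso geometry**: pseudo bond angle τ116 and pseudo dihedral
  angle α116 at IMGT position 116, the 6-DOF loop anchor transform
  between local frames at positions 105 and 117, torso φ/ψ (T1–T7), and
  kinked/extended classification (kinked ⇔ α116 > 0).
- **Variability statistics**: for sequences with multiple solved
  structures, multi-cluster occupancy and maximum pairwise backbone
  RMSD.
- **Synthetic fixtures**: an internal-coordinate loop builder generates
  idealised CDR structures with planted cluster structure, torso
  classes, exact pairwise RMSDs and separable sequence classes, so the
  entire pipeline is testable without downloading any structure.

## Worked example

```python
from canonloop.clustering import cluster_loops
from canonloop.synthetic import make_cluster_set

dataset = make_cluster_set(k=3, per_family=7, seed=0, eps=1.0)
catalog, matrix = cluster_loops(dataset.loops, mode="tcr_only", eps=1.0)
for cls in catalog.classes:
    print(cls.name, len(cls.members), len(cls.unique_sequences), cls.kind)
```

prints

```
α1-6-A 7 3 canonical
α1-6-B 7 3 canonical
α1-6-C 7 3 canonical
```

Three planted conformational families of seven CDRα1 structures each
are recovered as three canonical classes. The names follow the field's
convention: CDR type, loop length, then a letter ranking classes of the
same type and length by unique-sequence count (so `α1-6-A` is the
length-6 CDRα1 class with the most unique sequences). Building PSSMs
from this catalog and running leave-one-out cross-validation
(`examples/03_predict_from_sequence.py`) prints

```
LOOCV: TP=20 FP=0 TN=5 FN=0 accuracy=100.0%
```

every held-out member sequence is assigned back to its own class and
every decoy stays unassigned.

The `examples/` directory holds one short script per capability
(extraction, clustering, prediction, torso geometry, variability,
sequence-space analysis); each builds its own input and prints what the
numbers mean. The same stages are available from the shell via the
`canonloop` command (`extract`, `cluster`, `build-pssms`, `predict`,
`loocv`, `torso`, `variability`, `simulate`).

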