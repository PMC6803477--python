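"""Length-independent structural clustering of CDR loops.

Pairwise DTW score matrices are clustered with DBSCAN on the precomputed
distances.  Clusters are then designated as canonical classes (TCR-only
mode: at least five structures and two unique sequences), pseudo-classes
(five or more structures, a single unique sequence; names carry a
trailing asterisk) or dissolved into the unclustered pool.  In joint
TCR/antibody mode a valid class must contain at least six unique
sequences.  Class names follow the ``α1-6-B`` convention: CDR label(s),
observed loop length(s), then a letter ranking classes of that label and
length set by unique-sequence count.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .geometry import backbone_rmsd, dtw_distance
from .records import CDR_LABELS, EQUIVALENT_CDR, LoopRecord, TCR_CDR_TYPES

#: DBSCAN eps (Å) for joint TCR/antibody clustering, keyed by the TCR CDR
#: label of the pair; TCR-only clustering uses 1.0 Å for every CDR.
JOINT_EPS: dict[str, float] = {
    "a1": 0.82,
    "a2": 1.0,
    "a3": 0.91,
    "b1": 0.80,
    "b2": 0.63,
}
TCR_ONLY_EPS = 1.0
MIN_STRUCTURES = 5
JOINT_MIN_UNIQUE_SEQUENCES = 6


@dataclass
class DistanceMatrix:
    """Symmetric pairwise DTW score matrix over an ordered loop set."""

    loop_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.loop_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match loop_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def index_of(self, loop_id: str) -> int:
        return self.loop_ids.index(loop_id)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.loop_ids, columns=self.loop_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def _compatible(types: set[str]) -> bool:
    if len(types) == 1:
        return True
    if len(types) == 2:
        a, b = sorted(types)
        return EQUIVALENT_CDR.get(a) == b
    return False


def pairwise_matrix(loops: list[LoopRecord]) -> DistanceMatrix:
    """All-pairs DTW distance matrix, rows in input order."""
    if len(loops) < 2:
        raise ValueError("need at least two loops")
    if not _compatible({lp.cdr_type for lp in loops}):
        raise ValueError("loops mix incompatible CDR types")
    n = len(loops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(loops[i], loops[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix([lp.loop_id for lp in loops], values)


def dbscan(matrix: DistanceMatrix, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN on a precomputed distance matrix; returns labels (-1 = noise).

    Core points have at least ``min_pts`` neighbours within ``eps``
    (inclusive, self counted).  Clusters are the connected components of
    core points; labels are numbered by first core appearance in input
    order.  A border point joins the cluster of the first core point (in
    input order) within ``eps``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    d = matrix.values
    n = d.shape[0]
    within = d <= eps
    is_core = within.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for i in range(n):
        if not is_core[i] or labels[i] != -1:
            continue
        labels[i] = next_label
        stack = [i]
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(within[p]):
                if is_core[q] and labels[q] == -1:
                    labels[q] = next_label
                    stack.append(q)
        next_label += 1
    for i in range(n):
        if is_core[i] or labels[i] != -1:
            continue
        for j in range(n):
            if is_core[j] and within[i, j]:
                labels[i] = labels[j]
                break
    return labels


@dataclass
class CanonicalClass:
    name: str
    members: list[str]
    unique_sequences: list[str]
    representative: str
    kind: str  # canonical | pseudo


@dataclass
class ClassCatalog:
    """Result of designation: classes, pseudo-classes and unclustered loops."""

    classes: list[CanonicalClass]
    unclustered: list[str]
    mode: str  # tcr_only | joint
    eps: float

    def class_of(self, loop_id: str) -> str:
        """Cluster label of a loop: class name or 'unclustered'."""
        for cls in self.classes:
            if loop_id in cls.members:
                return cls.name
        return "unclustered"

    def find_class(self, name: str) -> CanonicalClass:
        for cls in self.classes:
            if cls.name == name:
                return cls
        raise KeyError(name)

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "eps": self.eps,
            "classes": [vars(c) for c in self.classes],
            "unclustered": self.unclustered,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "ClassCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [CanonicalClass(**c) for c in payload["classes"]],
            payload["unclustered"],
            payload["mode"],
            payload["eps"],
        )

    def membership_rows(self) -> list[tuple[str, str, str]]:
        rows = [(m, c.name, c.kind) for c in self.classes for m in c.members]
        rows += [(m, "unclustered", "unclustered") for m in self.unclustered]
        return rows


def representative(members: list[str], matrix: DistanceMatrix) -> str:
    """Medoid: member minimising summed distance to the others; ties by id."""
    if not members:
        raise ValueError("empty class")
    sub = matrix.submatrix(sorted(members))
    sums = sub.values.sum(axis=1)
    best = int(np.lexsort((np.arange(len(sums)), sums))[0])
    return sub.loop_ids[best]


def _unique_sequences(loops: list[LoopRecord]) -> list[str]:
    return sorted({lp.sequence.upper() for lp in loops})


def designate(labels: np.ndarray,
              loops: list[LoopRecord],
              mode: str,
              matrix: Optional[DistanceMatrix] = None,
              eps: float = TCR_ONLY_EPS,
              min_structures: int = MIN_STRUCTURES,
              joint_min_unique: int = JOINT_MIN_UNIQUE_SEQUENCES) -> ClassCatalog:
    """Apply the mode-specific class validity rules and name the survivors.

    tcr_only: a canonical class needs >= ``min_structures`` members and
    >= 2 unique sequences; a cluster of that size with a single unique
    sequence becomes a pseudo-class.  joint: a class needs
    >= ``joint_min_unique`` unique sequences; everything else is
    unclustered.
    """
    if mode not in ("tcr_only", "joint"):
        raise ValueError("mode must be 'tcr_only' or 'joint'")
    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(i)

    classes: list[CanonicalClass] = []
    unclustered: list[str] = list()
    for lab, idxs in sorted(by_label.items()):
        member_loops = [loops[i] for i in idxs]
        member_ids = [lp.loop_id for lp in member_loops]
        if lab == -1:
            unclustered.extend(member_ids)
            continue
        uniq = _unique_sequences(member_loops)
        if mode == "tcr_only":
            if len(member_ids) >= min_structures and len(uniq) >= 2:
                kind = "canonical"
            elif len(member_ids) >= min_structures and len(uniq) == 1:
                kind = "pseudo"
            else:
                unclustered.extend(member_ids)
                continue
        else:
            if len(uniq) < joint_min_unique:
                unclustered.extend(member_ids)
                continue
            kind = "canonical"
        rep = representative(member_ids, matrix) if matrix is not None else sorted(member_ids)[0]
        classes.append(CanonicalClass("", member_ids, uniq, rep, kind))

    catalog = ClassCatalog(classes, sorted(unclustered), mode, eps)
    return name_classes(catalog, loops)


def _class_label(cls: CanonicalClass, loops_by_id: dict[str, LoopRecord], mode: str) -> str:
    types = sorted({loops_by_id[m].cdr_type for m in cls.members})
    if mode == "joint":
        # joint names always carry the TCR label then the antibody label,
        # even when only one receptor type is present in the cluster
        tcr_type = next((t for t in types if t in TCR_CDR_TYPES), None)
        if tcr_type is None:
            tcr_type = EQUIVALENT_CDR[types[0]]
        ab_type = EQUIVALENT_CDR[tcr_type]
        return f"{CDR_LABELS[tcr_type]},{CDR_LABELS[ab_type]}"
    return CDR_LABELS[types[0]]


def name_classes(catalog: ClassCatalog, loops: Iterable[LoopRecord]) -> ClassCatalog:
    """Assign nomenclature-compliant names in place and return the catalog.

    Classes sharing a (CDR label, observed length set) are lettered A, B,
    C... by unique-sequence count descending; ties broken by member count,
    then by the lexicographically smallest member id.  Pseudo-classes get
    a trailing asterisk.
    """
    loops_by_id = {lp.loop_id: lp for lp in loops}
    groups: dict[tuple[str, tuple[int, ...]], list[CanonicalClass]] = {}
    for cls in catalog.classes:
        label = _class_label(cls, loops_by_id, catalog.mode)
        lengths = tuple(sorted({loops_by_id[m].length for m in cls.members}))
        groups.setdefault((label, lengths), []).append(cls)
    for (label, lengths), members in groups.items():
        members.sort(key=lambda c: (
            -len(c.unique_sequences), -len(c.members), sorted(c.members)[0]))
        lengths_str = ",".join(str(x) for x in lengths)
        for rank, cls in enumerate(members):
            letter = chr(ord("A") + rank)
            suffix = "*" if cls.kind == "pseudo" else ""
            cls.name = f"{label}-{lengths_str}-{letter}{suffix}"
    catalog.classes.sort(key=lambda c: c.name)
    return catalog


def cluster_loops(loops: list[LoopRecord],
                  mode: str = "tcr_only",
                  eps: Optional[float] = None,
                  min_pts: int = MIN_STRUCTURES,
                  matrix: Optional[DistanceMatrix] = None) -> tuple[ClassCatalog, DistanceMatrix]:
    """End-to-end: distance matrix, DBSCAN, designation, naming."""
    ordered = sorted(loops, key=lambda lp: lp.loop_id)
    if eps is None:
        if mode == "tcr_only":
            eps = TCR_ONLY_EPS
        else:
            tcr_type = next((lp.cdr_type for lp in ordered if lp.cdr_type in TCR_CDR_TYPES),
                            None)
            key = tcr_type or EQUIVALENT_CDR[ordered[0].cdr_type]
            eps = JOINT_EPS.get(key, TCR_ONLY_EPS)
    if matrix is None:
        matrix = pairwise_matrix(ordered)
    labels = dbscan(matrix, eps=eps, min_pts=min_pts)
    catalog = designate(labels, ordered, mode, matrix=matrix, eps=eps)
    return catalog, matrix


@dataclass
class CatalogMatch:
    class_a: str
    class_b: str
    evidence: str  # shared_member | sequence_proxy


def match_catalogs(catalog_a: ClassCatalog,
                   catalog_b: ClassCatalog,
                   loops_a: list[LoopRecord],
                   loops_b: list[LoopRecord],
                   rmsd_cutoff: float = 1.0) -> list[CatalogMatch]:
    """Match classes across two catalogs.

    Two classes match if they share a member structure:chain; failing
    that, if one catalog holds a loop whose CDR sequence equals the other
    class's representative and whose backbone RMSD to that representative
    is within ``rmsd_cutoff`` (the sequence-identical proxy rule).
    """
    by_id_a = {lp.loop_id: lp for lp in loops_a}
    by_id_b = {lp.loop_id: lp for lp in loops_b}
    matches: list[CatalogMatch] = []
    for ca in catalog_a.classes:
        sources_a = {by_id_a[m].source for m in ca.members if m in by_id_a}
        for cb in catalog_b.classes:
            sources_b = {by_id_b[m].source for m in cb.members if m in by_id_b}
            if sources_a & sources_b:
                matches.append(CatalogMatch(ca.name, cb.name, "shared_member"))
                continue
            if _proxy_match(ca, cb, by_id_a, by_id_b, rmsd_cutoff) or \
                    _proxy_match(cb, ca, by_id_b, by_id_a, rmsd_cutoff):
                matches.append(CatalogMatch(ca.name, cb.name, "sequence_proxy"))
    return matches


def _proxy_match(cls_with_proxy, cls_foreign, by_id_proxy, by_id_foreign,
                 rmsd_cutoff: float) -> bool:
    rep = by_id_foreign.get(cls_foreign.representative)
    if rep is None:
        return False
    for member_id in sorted(cls_with_proxy.members):
        lp = by_id_proxy.get(member_id)
        if lp is None or lp.sequence.upper() != rep.sequence.upper():
            continue
        if lp.length == rep.length and backbone_rmsd(lp, rep, fit_on="loop") <= rmsd_cutoff:
            return True
    return False
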