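"""Sequence-based canonical-form prediction.

Each canonical class gets a position-specific scoring matrix over the
IMGT positions observed in its (unique) training sequences:

    s(a, i) = log2( p_{a,i} / b_a ),   b_a = 0.05 for every residue,

and a query of length l scores P_c = Σ_i s(a, i), where a residue never
observed at a position contributes −1.  A query is assigned to the class
with the highest P_c among the classes covering its length, provided
P_c > 1 — except CDRα3, where P_c must be at least the loop length.
Pseudo-classes are assigned by exact sequence identity only.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .clustering import ClassCatalog
from .geometry import backbone_rmsd
from .imgt import number_sequence
from .records import LoopRecord

BACKGROUND_PROBABILITY = 0.05
UNSEEN_SCORE = -1.0
PC_THRESHOLD = 1.0  # assignment requires P_c strictly above this
ALPHA3_CDR_TYPE = "a3"  # CDRα3 instead requires P_c >= loop length


@dataclass
class PSSM:
    """Per-class position-specific scoring matrix (log2 odds, bits)."""

    class_name: str
    cdr_type: str
    positions: list[str]
    scores: dict[str, dict[str, float]]  # position -> residue -> s(a, i)
    lengths: set[int]
    n_training: int

    def score(self, position: str, residue: str) -> float:
        return self.scores.get(position, {}).get(residue.upper(), UNSEEN_SCORE)

    def to_dict(self) -> dict:
        return {
            "class_name": self.class_name,
            "cdr_type": self.cdr_type,
            "positions": self.positions,
            "scores": self.scores,
            "lengths": sorted(self.lengths),
            "n_training": self.n_training,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PSSM":
        return cls(d["class_name"], d["cdr_type"], list(d["positions"]),
                   {p: dict(v) for p, v in d["scores"].items()},
                   set(d["lengths"]), int(d["n_training"]))


def build_pssm(class_sequences: Iterable[str], class_name: str, cdr_type: str) -> PSSM:
    """Build a PSSM from the unique sequences of one class.

    Frequencies are computed per IMGT position over unique sequences (a
    redundant copy changes nothing); probabilities at a position sum to 1
    over the residues observed there.  No smoothing beyond the fixed
    unseen-residue score at lookup time.
    """
    unique = sorted({s.upper() for s in class_sequences})
    if not unique:
        raise ValueError("a class needs at least one training sequence")
    counts: dict[str, dict[str, int]] = {}
    coverage: dict[str, int] = {}
    positions: list[str] = []
    lengths: set[int] = set()
    for seq in unique:
        lengths.add(len(seq))
        for pos, aa in number_sequence(cdr_type, seq):
            if pos not in counts:
                counts[pos] = {}
                positions.append(pos)
            counts[pos][aa] = counts[pos].get(aa, 0) + 1
            coverage[pos] = coverage.get(pos, 0) + 1
    scores = {
        pos: {
            aa: math.log2((n / coverage[pos]) / BACKGROUND_PROBABILITY)
            for aa, n in counts[pos].items()
        }
        for pos in positions
    }
    return PSSM(class_name, cdr_type, positions, scores, lengths, len(unique))


def build_pssms(catalog: ClassCatalog,
                loops: Iterable[LoopRecord]) -> list[PSSM]:
    """One PSSM per canonical class of a catalog (pseudo-classes excluded:
    they are matched by exact sequence identity, not scored)."""
    by_id = {lp.loop_id: lp for lp in loops}
    pssms = []
    for cls in catalog.classes:
        if cls.kind != "canonical":
            continue
        cdr_types = {by_id[m].cdr_type for m in cls.members if m in by_id}
        cdr_type = sorted(cdr_types)[0]
        pssms.append(build_pssm(cls.unique_sequences, cls.name, cdr_type))
    return pssms


def write_pssms(pssms: list[PSSM], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in pssms], fh, indent=1, ensure_ascii=False)


def read_pssms(path) -> list[PSSM]:
    with open(path) as fh:
        return [PSSM.from_dict(d) for d in json.load(fh)]


def score_sequence(pssm: PSSM, seq: str) -> Optional[float]:
    """P_c for a query, or None if the PSSM does not cover its length."""
    seq = seq.upper()
    if len(seq) not in pssm.lengths:
        return None
    return sum(pssm.score(pos, aa) for pos, aa in number_sequence(pssm.cdr_type, seq))


@dataclass
class Prediction:
    sequence: str
    cdr_type: str
    assigned: Optional[str]
    score: Optional[float]
    rationale: str  # pssm | exact_sequence | below_threshold | no_length_match


def _threshold_met(cdr_type: str, pc: float, length: int) -> bool:
    if cdr_type == ALPHA3_CDR_TYPE:
        return pc >= length
    return pc > PC_THRESHOLD


def predict(seq: str,
            cdr_type: str,
            catalog: Optional[ClassCatalog],
            pssms: list[PSSM],
            exact_match_canonical: bool = True) -> Prediction:
    """Assign a CDR sequence to a canonical class or pseudo-class.

    Exact sequence identity to any class takes precedence (and is the
    only route into a pseudo-class); otherwise the highest-P_c same-length
    PSSM wins if it clears the threshold.  P_c ties are broken by larger
    training-set size, then by class name.
    """
    seq = seq.upper()
    length = len(seq)
    if catalog is not None:
        exact_hits = [
            cls for cls in catalog.classes
            if seq in cls.unique_sequences
            and (exact_match_canonical or cls.kind == "pseudo")
        ]
        if exact_hits:
            exact_hits.sort(key=lambda c: (-len(c.unique_sequences), c.name))
            return Prediction(seq, cdr_type, exact_hits[0].name, None, "exact_sequence")

    candidates = [p for p in pssms if p.cdr_type == cdr_type and length in p.lengths]
    if not candidates:
        return Prediction(seq, cdr_type, None, None, "no_length_match")
    scored = [(score_sequence(p, seq), p) for p in candidates]
    scored.sort(key=lambda sp: (-sp[0], -sp[1].n_training, sp[1].class_name))
    best_pc, best = scored[0]
    if _threshold_met(cdr_type, best_pc, length):
        return Prediction(seq, cdr_type, best.class_name, best_pc, "pssm")
    return Prediction(seq, cdr_type, None, best_pc, "below_threshold")


@dataclass
class LOOCVResult:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    predictions: list[Prediction] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def loocv(dataset: list[tuple[str, str, Optional[str]]]) -> LOOCVResult:
    """Leave-one-out cross-validation over unique labelled sequences.

    ``dataset`` holds (sequence, cdr_type, true_class_or_None) — None
    marks unclustered sequences.  For each held-out sequence the PSSMs are
    rebuilt without it; counting follows: assigned to its own class = TP,
    assigned to a different class = FP, unclustered and unassigned = TN,
    from a class but unassigned = FN.
    """
    seen: set[tuple[str, str]] = set()
    unique: list[tuple[str, str, Optional[str]]] = []
    for seq, cdr_type, label in dataset:
        key = (seq.upper(), cdr_type)
        if key not in seen:
            seen.add(key)
            unique.append((seq.upper(), cdr_type, label))

    result = LOOCVResult()
    for held_seq, held_type, held_label in unique:
        train: dict[str, list[str]] = {}
        types: dict[str, str] = {}
        for seq, cdr_type, label in unique:
            if label is None or (seq == held_seq and cdr_type == held_type):
                continue
            train.setdefault(label, []).append(seq)
            types[label] = cdr_type
        pssms = [build_pssm(seqs, name, types[name]) for name, seqs in train.items()]
        pred = predict(held_seq, held_type, None, pssms)
        result.predictions.append(pred)
        if held_label is not None:
            if pred.assigned == held_label:
                result.tp += 1
            elif pred.assigned is not None:
                result.fp += 1
            else:
                result.fn += 1
        else:
            if pred.assigned is None:
                result.tn += 1
            else:
                result.fp += 1
    return result


def blind_correct(prediction: Prediction,
                  native: LoopRecord,
                  class_members: list[LoopRecord],
                  rmsd_cutoff: float = 1.0,
                  fit_on: str = "loop") -> Optional[bool]:
    """Blind-test correctness: is any member of the assigned class within
    the backbone-RMSD cutoff (inclusive) of the native loop?  None if the
    prediction made no assignment (not evaluable, distinct from False)."""
    if prediction.assigned is None:
        return None
    best = math.inf
    for member in class_members:
        if member.length != native.length:
            continue
        best = min(best, backbone_rmsd(native, member, fit_on=fit_on))
    return best <= rmsd_cutoff


@dataclass
class NGSRecord:
    """One annotated chain sequence from a repertoire-sequencing run."""

    record_id: str
    cdr1: Optional[str]
    cdr2: Optional[str]
    cdr3: Optional[str]
    productive: bool


def ngs_filter(records: Iterable[NGSRecord],
               min_cdr12: int = 5,
               min_cdr3: int = 8) -> tuple[list[NGSRecord], dict[str, int]]:
    """Keep productive records with CDR1/2 length >= 5 and CDR3 >= 8."""
    kept: list[NGSRecord] = []
    tally: dict[str, int] = {
        "kept": 0, "unproductive": 0, "missing_cdr": 0,
        "short_cdr1": 0, "short_cdr2": 0, "short_cdr3": 0,
    }
    for rec in records:
        if rec.cdr1 is None or rec.cdr2 is None or rec.cdr3 is None:
            tally["missing_cdr"] += 1
        elif not rec.productive:
            tally["unproductive"] += 1
        elif len(rec.cdr1) < min_cdr12:
            tally["short_cdr1"] += 1
        elif len(rec.cdr2) < min_cdr12:
            tally["short_cdr2"] += 1
        elif len(rec.cdr3) < min_cdr3:
            tally["short_cdr3"] += 1
        else:
            kept.append(rec)
            tally["kept"] += 1
    return kept, tally
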