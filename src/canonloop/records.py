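"""Core data records: residues, chains, CDR loops and rejection reasons.

Loops are stored with their five N-terminal and five C-terminal anchor
residues, each residue carrying the four backbone atoms (N, CA, C, O),
IMGT position and per-atom B-factors.  The CDR ``sequence`` excludes the
anchors.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

#: Backbone atom roles, in the fixed order used for superposition and DTW.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

#: IMGT CDR windows (inclusive): CDR1 27-38, CDR2 56-65, CDR3 105-117.
CDR_WINDOWS: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

#: Number of anchor residues flanking each side of a CDR.
N_ANCHORS = 5

#: CDR type codes by (chain_type, CDR number).
CDR_TYPE_BY_CHAIN = {
    ("alpha", 1): "a1", ("alpha", 2): "a2", ("alpha", 3): "a3",
    ("beta", 1): "b1", ("beta", 2): "b2", ("beta", 3): "b3",
    ("light", 1): "L1", ("light", 2): "L2", ("light", 3): "L3",
    ("heavy", 1): "H1", ("heavy", 2): "H2", ("heavy", 3): "H3",
}

#: alpha/light and beta/heavy chains are treated as equivalent pairs.
EQUIVALENT_CDR: dict[str, str] = {
    "a1": "L1", "a2": "L2", "a3": "L3",
    "b1": "H1", "b2": "H2", "b3": "H3",
}
EQUIVALENT_CDR.update({v: k for k, v in list(EQUIVALENT_CDR.items())})

#: Human-readable CDR labels used in class names.
CDR_LABELS = {
    "a1": "α1", "a2": "α2", "a3": "α3",
    "b1": "β1", "b2": "β2", "b3": "β3",
    "L1": "L1", "L2": "L2", "L3": "L3",
    "H1": "H1", "H2": "H2", "H3": "H3",
}

TCR_CDR_TYPES = frozenset({"a1", "a2", "a3", "b1", "b2", "b3"})


@dataclass
class ResidueRecord:
    """One residue with IMGT position and backbone atoms."""

    imgt_position: int
    insertion_code: str
    amino_acid: str
    backbone_atoms: dict[str, np.ndarray]
    bfactors: dict[str, float] = field(default_factory=dict)

    @property
    def position_label(self) -> str:
        return f"{self.imgt_position}{self.insertion_code}"

    def has_complete_backbone(self) -> bool:
        for role in BACKBONE_ATOMS:
            xyz = self.backbone_atoms.get(role)
            if xyz is None or not np.all(np.isfinite(xyz)):
                return False
        return True

    def backbone_coords(self) -> np.ndarray:
        """(4, 3) array in N, CA, C, O order."""
        return np.array([self.backbone_atoms[r] for r in BACKBONE_ATOMS], dtype=float)

    def atom(self, role: str) -> np.ndarray:
        return np.asarray(self.backbone_atoms[role], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ResidueRecord":
        atoms = {
            role: rotation @ np.asarray(xyz, dtype=float) + translation
            for role, xyz in self.backbone_atoms.items()
        }
        return ResidueRecord(
            self.imgt_position, self.insertion_code, self.amino_acid,
            atoms, dict(self.bfactors),
        )

    def to_dict(self) -> dict:
        return {
            "imgt_position": self.imgt_position,
            "insertion_code": self.insertion_code,
            "amino_acid": self.amino_acid,
            "backbone_atoms": {r: [float(v) for v in xyz] for r, xyz in self.backbone_atoms.items()},
            "bfactors": {r: float(b) for r, b in self.bfactors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueRecord":
        return cls(
            int(d["imgt_position"]),
            d.get("insertion_code", ""),
            d["amino_acid"],
            {r: np.array(xyz, dtype=float) for r, xyz in d["backbone_atoms"].items()},
            {r: float(b) for r, b in d.get("bfactors", {}).items()},
        )


@dataclass
class ChainRecord:
    """A receptor chain with IMGT-numbered residues."""

    structure_id: str
    chain_id: str
    receptor_class: str  # TCR | antibody | nanobody
    chain_type: str      # alpha | beta | heavy | light
    residues: list[ResidueRecord]
    resolution: Optional[float]

    @property
    def source(self) -> str:
        return f"{self.structure_id}:{self.chain_id}"


@dataclass
class LoopRecord:
    """One extracted CDR loop: CDR residues plus 5+5 anchor residues."""

    cdr_type: str
    sequence: str
    cdr_residues: list[ResidueRecord]
    anchors_n: list[ResidueRecord]
    anchors_c: list[ResidueRecord]
    source: str
    resolution: Optional[float] = None
    bound_state: Optional[bool] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.cdr_residues):
            raise ValueError("sequence length must match CDR residue count")

    @property
    def loop_id(self) -> str:
        return f"{self.source}/{self.cdr_type}"

    @property
    def length(self) -> int:
        return len(self.cdr_residues)

    @property
    def residues(self) -> list[ResidueRecord]:
        """All residues in chain order: N-anchors, CDR, C-anchors."""
        return [*self.anchors_n, *self.cdr_residues, *self.anchors_c]

    def anchor_backbone(self) -> np.ndarray:
        """(40, 3) backbone coordinates of the ten anchors."""
        anchors = [*self.anchors_n, *self.anchors_c]
        return np.concatenate([r.backbone_coords() for r in anchors], axis=0)

    def cdr_backbone(self) -> np.ndarray:
        """(L*4, 3) backbone coordinates of the CDR residues."""
        return np.concatenate([r.backbone_coords() for r in self.cdr_residues], axis=0)

    def cdr_backbone_by_residue(self) -> np.ndarray:
        """(L, 4, 3) per-residue backbone coordinates."""
        return np.stack([r.backbone_coords() for r in self.cdr_residues], axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LoopRecord":
        return LoopRecord(
            self.cdr_type,
            self.sequence,
            [r.transformed(rotation, translation) for r in self.cdr_residues],
            [r.transformed(rotation, translation) for r in self.anchors_n],
            [r.transformed(rotation, translation) for r in self.anchors_c],
            self.source,
            self.resolution,
            self.bound_state,
        )

    def find_residue(self, imgt_position: int, insertion_code: str = "") -> Optional[ResidueRecord]:
        for res in self.residues:
            if res.imgt_position == imgt_position and res.insertion_code == insertion_code:
                return res
        return None

    def to_dict(self) -> dict:
        return {
            "cdr_type": self.cdr_type,
            "sequence": self.sequence,
            "cdr_residues": [r.to_dict() for r in self.cdr_residues],
            "anchors_n": [r.to_dict() for r in self.anchors_n],
            "anchors_c": [r.to_dict() for r in self.anchors_c],
            "source": self.source,
            "resolution": self.resolution,
            "bound_state": self.bound_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoopRecord":
        return cls(
            d["cdr_type"],
            d["sequence"],
            [ResidueRecord.from_dict(r) for r in d["cdr_residues"]],
            [ResidueRecord.from_dict(r) for r in d["anchors_n"]],
            [ResidueRecord.from_dict(r) for r in d["anchors_c"]],
            d["source"],
            d.get("resolution"),
            d.get("bound_state"),
        )


@dataclass(frozen=True)
class RejectionReason:
    """Why a loop failed extraction; ``code`` identifies the filter."""

    code: str  # RESOLUTION | MISSING_BACKBONE | HIGH_BFACTOR | CHAIN_BREAK | MISSING_ANCHORS
    detail: str = ""


def write_loops_jsonl(loops: Iterable[LoopRecord], path) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            fh.write(json.dumps(loop.to_dict(), sort_keys=True) + "\n")


def read_loops_jsonl(path) -> list[LoopRecord]:
    loops = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                loops.append(LoopRecord.from_dict(json.loads(line)))
    return loops


def iter_loops_jsonl(path) -> Iterator[LoopRecord]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield LoopRecord.from_dict(json.loads(line))
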