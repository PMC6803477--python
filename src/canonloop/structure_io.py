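"""Structure parsing, CDR loop extraction and quality filtering.

Input structures are PDB files whose receptor chains are already
IMGT-renumbered (the STCRDab/SAbDab convention), or plain PDB files
accompanied by a sidecar TSV mapping author residue numbering to IMGT
positions.  Receptor class and chain type are metadata, not inferred
from sequence.

A loop is accepted only if the parent structure's resolution is at most
2.8 Å, every residue of the CDR-plus-anchors span has all four backbone
atoms with B-factors at most 80, and all consecutive C–N peptide bonds
across the span are shorter than 1.37 Å.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

from .records import (
    BACKBONE_ATOMS,
    CDR_TYPE_BY_CHAIN,
    CDR_WINDOWS,
    ChainRecord,
    LoopRecord,
    N_ANCHORS,
    RejectionReason,
    ResidueRecord,
)

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class FilterConfig:
    """Structural quality thresholds."""

    resolution_cutoff: float = 2.8   # Å, inclusive
    bfactor_cutoff: float = 80.0     # reject if any backbone B-factor exceeds this
    bond_cutoff: float = 1.37        # Å, C–N distances at/above break the chain


DEFAULT_FILTERS = FilterConfig()

_CDR_NUMBER = {"CDR1": 1, "CDR2": 2, "CDR3": 3}


def read_sidecar(path) -> dict[tuple[str, int, str], tuple[int, str]]:
    """Read a sidecar numbering TSV.

    Columns: chain, author_resid, author_icode, imgt_position.  The IMGT
    position may carry a trailing insertion letter (e.g. ``111A``).
    Returns {(chain, author_resid, author_icode): (imgt_position, icode)}.
    """
    mapping: dict[tuple[str, int, str], tuple[int, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            raw = row["imgt_position"].strip()
            if raw and raw[-1].isalpha():
                pos, icode = int(raw[:-1]), raw[-1].upper()
            else:
                pos, icode = int(raw), ""
            mapping[(row["chain"].strip(),
                     int(row["author_resid"]),
                     row.get("author_icode", "").strip())] = (pos, icode)
    return mapping


def _pick_altloc(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """Highest-occupancy conformer for an atom name; ties keep the first seen."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_structure(path,
                   numbering_source: str = "embedded",
                   sidecar: Optional[dict] = None,
                   chain_metadata: Optional[dict[str, dict]] = None,
                   default_receptor_class: str = "TCR",
                   default_chain_type: str = "beta") -> list[ChainRecord]:
    """Parse a PDB file into IMGT-numbered receptor chains.

    ``chain_metadata`` maps chain id to ``{"receptor_class": ..,
    "chain_type": ..}``; when given, chains absent from it are skipped.
    Without it, every protein chain is kept with the default annotation.
    Non-protein chains (nucleic acids, waters, ligands) are always ignored.
    """
    if numbering_source not in ("embedded", "sidecar"):
        raise ValueError("numbering_source must be 'embedded' or 'sidecar'")
    if numbering_source == "sidecar":
        if sidecar is None:
            raise ValueError("sidecar numbering requested but no table given")
        if isinstance(sidecar, (str, Path)):
            sidecar = read_sidecar(sidecar)

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    structure_id = (st.name or Path(path).stem)[:4].lower()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    chains: list[ChainRecord] = []
    if len(st) == 0:
        return chains
    model = st[0]
    for chain in model:
        if chain_metadata is not None and chain.name not in chain_metadata:
            continue
        residues: list[ResidueRecord] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            if numbering_source == "sidecar":
                key = (chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
                if key not in sidecar:
                    continue
                pos, icode = sidecar[key]
            else:
                pos = res.seqid.num
                icode = (res.seqid.icode or " ").strip()
            atoms: dict[str, np.ndarray] = {}
            bfactors: dict[str, float] = {}
            for role in BACKBONE_ATOMS:
                atom = _pick_altloc(res, role)
                if atom is not None:
                    atoms[role] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    bfactors[role] = float(atom.b_iso)
            residues.append(ResidueRecord(
                pos, icode, THREE_TO_ONE.get(res.name, "X"), atoms, bfactors))
        if not residues:
            if chain_metadata is not None:
                logger.warning("chain %s: no IMGT-mapped residues, skipped", chain.name)
            continue
        # stable sort on the integer position keeps file order of insertion
        # codes, which is the IMGT chain order (descending letters on the
        # C-terminal side of the loop apex)
        residues.sort(key=lambda r: r.imgt_position)
        meta = (chain_metadata or {}).get(chain.name, {})
        chains.append(ChainRecord(
            structure_id=structure_id,
            chain_id=chain.name,
            receptor_class=meta.get("receptor_class", default_receptor_class),
            chain_type=meta.get("chain_type", default_chain_type),
            residues=residues,
            resolution=resolution,
        ))
    return chains


def extract_loop(chain: ChainRecord, cdr: str,
                 config: FilterConfig = DEFAULT_FILTERS,
                 bound_state: Optional[bool] = None):
    """Extract one CDR loop (with 5+5 anchors) or return a RejectionReason."""
    if cdr not in CDR_WINDOWS:
        raise ValueError(f"cdr must be one of {sorted(CDR_WINDOWS)}")
    start, end = CDR_WINDOWS[cdr]

    if chain.resolution is None:
        return RejectionReason("RESOLUTION", "no crystallographic resolution recorded")
    if chain.resolution > config.resolution_cutoff:
        return RejectionReason(
            "RESOLUTION",
            f"{chain.resolution:.2f} Å > {config.resolution_cutoff:.2f} Å")

    idx = [i for i, r in enumerate(chain.residues) if start <= r.imgt_position <= end]
    if not idx:
        return RejectionReason("MISSING_ANCHORS", f"no residues in {cdr} window {start}-{end}")
    first, last = idx[0], idx[-1]
    if first < N_ANCHORS or last + N_ANCHORS >= len(chain.residues):
        return RejectionReason(
            "MISSING_ANCHORS",
            f"fewer than {N_ANCHORS} residues flanking the {cdr} window")

    span = chain.residues[first - N_ANCHORS:last + N_ANCHORS + 1]
    for res in span:
        if not res.has_complete_backbone():
            return RejectionReason(
                "MISSING_BACKBONE", f"incomplete backbone at IMGT {res.position_label}")
    for res in span:
        for role in BACKBONE_ATOMS:
            if res.bfactors.get(role, 0.0) > config.bfactor_cutoff:
                return RejectionReason(
                    "HIGH_BFACTOR",
                    f"{role} B-factor {res.bfactors[role]:.1f} > "
                    f"{config.bfactor_cutoff:.0f} at IMGT {res.position_label}")
    for prev, curr in zip(span, span[1:]):
        bond = float(np.linalg.norm(curr.atom("N") - prev.atom("C")))
        if bond >= config.bond_cutoff:
            return RejectionReason(
                "CHAIN_BREAK",
                f"C–N bond {bond:.3f} Å >= {config.bond_cutoff:.2f} Å after "
                f"IMGT {prev.position_label}")

    cdr_residues = chain.residues[first:last + 1]
    cdr_type = CDR_TYPE_BY_CHAIN.get((chain.chain_type, _CDR_NUMBER[cdr]))
    if cdr_type is None:
        raise ValueError(f"unknown chain type {chain.chain_type!r}")
    return LoopRecord(
        cdr_type=cdr_type,
        sequence="".join(r.amino_acid for r in cdr_residues),
        cdr_residues=cdr_residues,
        anchors_n=chain.residues[first - N_ANCHORS:first],
        anchors_c=chain.residues[last + 1:last + N_ANCHORS + 1],
        source=chain.source,
        resolution=chain.resolution,
        bound_state=bound_state,
    )


def extract_loops(chains: Iterable[ChainRecord],
                  cdrs: Iterable[str] = ("CDR1", "CDR2", "CDR3"),
                  config: FilterConfig = DEFAULT_FILTERS,
                  bound_states: Optional[dict[str, bool]] = None):
    """Extract all requested CDRs from all chains.

    Returns (loops, rejections) where rejections are
    (source, cdr, RejectionReason) triples.
    """
    loops: list[LoopRecord] = []
    rejections: list[tuple[str, str, RejectionReason]] = []
    for chain in chains:
        for cdr in cdrs:
            result = extract_loop(
                chain, cdr, config,
                bound_state=(bound_states or {}).get(chain.source))
            if isinstance(result, LoopRecord):
                loops.append(result)
            else:
                rejections.append((chain.source, cdr, result))
    return loops, rejections


def write_rejections_csv(rejections, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure", "chain", "cdr", "code", "detail"])
        for source, cdr, reason in rejections:
            structure, _, chain = source.partition(":")
            writer.writerow([structure, chain, cdr, reason.code, reason.detail])


# ---------------------------------------------------------------------------
# PDB writing (synthetic fixtures and round-trip tests)

def loops_to_pdb(loops: list[LoopRecord], path, resolution: float = 2.0) -> None:
    """Write loops as a PDB file, one chain per loop, IMGT numbering embedded."""
    st = gemmi.Structure()
    st.name = Path(path).stem[:4]
    st.resolution = resolution
    model = gemmi.Model("1")
    for loop in loops:
        _, _, chain_id = loop.source.partition(":")
        chain = gemmi.Chain(chain_id or "A")
        for res in loop.residues:
            g_res = gemmi.Residue()
            g_res.name = ONE_TO_THREE.get(res.amino_acid, "ALA")
            g_res.seqid = gemmi.SeqId(res.imgt_position, res.insertion_code or " ")
            for role in BACKBONE_ATOMS:
                if role not in res.backbone_atoms:
                    continue
                atom = gemmi.Atom()
                atom.name = role
                x, y, z = (float(v) for v in res.backbone_atoms[role])
                atom.pos = gemmi.Position(x, y, z)
                atom.element = gemmi.Element(role[0])
                atom.occ = 1.0
                atom.b_iso = float(res.bfactors.get(role, 0.0))
                g_res.add_atom(atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)
    _ensure_resolution_remark(doc_path, resolution)


def _ensure_resolution_remark(path: str, resolution: float) -> None:
    """Guarantee a REMARK 2 resolution record readable by gemmi."""
    with open(path) as fh:
        lines = fh.readlines()
    if any(line.startswith("REMARK   2 RESOLUTION") for line in lines):
        return
    remark = f"REMARK   2 RESOLUTION.    {resolution:5.2f} ANGSTROMS.\n"
    insert_at = 1 if lines and lines[0].startswith(("HEADER", "TITLE")) else 0
    lines.insert(insert_at, remark)
    with open(path, "w") as fh:
        fh.writelines(lines)
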