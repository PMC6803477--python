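"""Conformational variability of sequence-identical CDR loops.

Groups loops by (CDR type, sequence), keeps groups with at least two
structures, and reports how many distinct structural clusters each group
occupies and the maximum pairwise backbone RMSD within it.  A group
spanning more than one cluster label (the unclustered pool counts as a
label) marks a sequence observed in multiple conformations.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .clustering import ClassCatalog
from .geometry import backbone_rmsd
from .records import LoopRecord

#: Default reporting threshold below which a group counts as "similar".
SIMILAR_RMSD = 1.0


@dataclass
class SequenceGroup:
    cdr_type: str
    sequence: str
    member_ids: list[str]
    clusters: list[str] = field(default_factory=list)
    max_rmsd: Optional[float] = None

    @property
    def n_structures(self) -> int:
        return len(self.member_ids)

    @property
    def multi_cluster(self) -> bool:
        return len(self.clusters) > 1


def group_by_sequence(loops: Iterable[LoopRecord]) -> list[SequenceGroup]:
    """Sequence-identical groups with >= 2 member structures.

    Sequence comparison is case-insensitive; singleton sequences are
    dropped.
    """
    buckets: dict[tuple[str, str], list[str]] = {}
    for lp in loops:
        buckets.setdefault((lp.cdr_type, lp.sequence.upper()), []).append(lp.loop_id)
    return [
        SequenceGroup(cdr_type, seq, sorted(ids))
        for (cdr_type, seq), ids in sorted(buckets.items())
        if len(ids) >= 2
    ]


def multi_cluster_fraction(groups: list[SequenceGroup],
                           catalog: ClassCatalog) -> tuple[float, list[SequenceGroup]]:
    """Fraction of groups whose members occupy more than one cluster label.

    Fills each group's ``clusters`` field in place and returns
    (fraction, groups).
    """
    for group in groups:
        group.clusters = sorted({catalog.class_of(m) for m in group.member_ids})
    if not groups:
        return 0.0, groups
    n_multi = sum(1 for g in groups if g.multi_cluster)
    return n_multi / len(groups), groups


def max_pairwise_rmsd(group: SequenceGroup,
                      loops: Iterable[LoopRecord],
                      fit_on: str = "loop") -> float:
    """Maximum backbone RMSD over all member pairs of a group."""
    by_id = {lp.loop_id: lp for lp in loops}
    members = [by_id[m] for m in group.member_ids]
    if len(members) < 2:
        raise ValueError("group needs at least two members")
    rmsd = max(backbone_rmsd(a, b, fit_on=fit_on) for a, b in combinations(members, 2))
    group.max_rmsd = rmsd
    return rmsd


def variability_report(loops: list[LoopRecord],
                       catalog: ClassCatalog,
                       fit_on: str = "loop",
                       similar_rmsd: float = SIMILAR_RMSD) -> dict:
    """Full variability analysis.

    Returns a dict with the groups, the multi-cluster fraction, and the
    fraction of groups with max RMSD below the similarity threshold.
    """
    groups = group_by_sequence(loops)
    fraction, groups = multi_cluster_fraction(groups, catalog)
    for group in groups:
        max_pairwise_rmsd(group, loops, fit_on=fit_on)
    n_similar = sum(1 for g in groups if g.max_rmsd is not None and g.max_rmsd < similar_rmsd)
    return {
        "groups": groups,
        "n_groups": len(groups),
        "multi_cluster_fraction": fraction,
        "similar_fraction": n_similar / len(groups) if groups else 0.0,
    }


def write_variability_csv(groups: list[SequenceGroup], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cdr_type", "sequence", "n_structures", "n_clusters",
                         "cluster_names", "max_rmsd"])
        for g in groups:
            writer.writerow([
                g.cdr_type, g.sequence, g.n_structures, len(g.clusters),
                ";".join(g.clusters),
                f"{g.max_rmsd:.4f}" if g.max_rmsd is not None else "",
            ])
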