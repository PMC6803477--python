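"""Sequence-space analysis of shared structural clusters.

One-hot encodes unique CDR sequences by (IMGT position, residue) and
projects them with PCA to examine whether TCR and antibody members of a
cluster occupy distinct sequence space.  Also builds per-position
frequency matrices (logo input) with the hydrophobicity colour classes:
hydrophilic R K D E N Q, neutral S G H T A P, hydrophobic Y V M C L F I W.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .imgt import number_sequence

HYDROPHOBICITY_CLASSES: dict[str, str] = {}
for _aa in "RKDENQ":
    HYDROPHOBICITY_CLASSES[_aa] = "hydrophilic"
for _aa in "SGHTAP":
    HYDROPHOBICITY_CLASSES[_aa] = "neutral"
for _aa in "YVMCLFIW":
    HYDROPHOBICITY_CLASSES[_aa] = "hydrophobic"


@dataclass
class OneHotMatrix:
    """0/1 indicator matrix: rows are unique sequences, columns (position, residue)."""

    sequences: list[str]
    columns: list[tuple[str, str]]
    values: np.ndarray

    @property
    def zero_variance_columns(self) -> np.ndarray:
        return np.flatnonzero(self.values.std(axis=0) == 0.0)


def one_hot_encode(seqs: Sequence[str], cdr_type: str) -> OneHotMatrix:
    """One-hot encode unique sequences on the shared IMGT position frame.

    Variable lengths are aligned by IMGT position; a sequence simply has
    no feature at positions it does not cover (gaps carry no feature).
    """
    unique = list(dict.fromkeys(s.upper() for s in seqs))
    features: list[tuple[str, str]] = []
    index: dict[tuple[str, str], int] = {}
    rows = []
    for seq in unique:
        rows.append([(pos, aa) for pos, aa in number_sequence(cdr_type, seq)])
        for key in rows[-1]:
            if key not in index:
                index[key] = len(features)
                features.append(key)
    values = np.zeros((len(unique), len(features)))
    for i, row in enumerate(rows):
        for key in row:
            values[i, index[key]] = 1.0
    return OneHotMatrix(unique, features, values)


@dataclass
class PCAResult:
    sequences: list[str]
    groups: list[str]
    coordinates: np.ndarray  # (n_sequences, n_components)
    explained_variance: np.ndarray
    components: np.ndarray   # (n_components, n_features)
    columns: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])])
        df.insert(0, "group", self.groups)
        df.insert(0, "sequence", self.sequences)
        return df


def one_hot_pca(records: Sequence[tuple[str, str]],
                cdr_type: str,
                n_components: int = 2) -> PCAResult:
    """PCA of one-hot encoded unique sequences.

    ``records`` are (sequence, group) pairs, e.g. group "TCR"/"antibody";
    uniqueness is per (sequence, group).  Components are ordered by
    explained variance and sign-fixed so the largest-magnitude loading of
    each component is positive, making coordinates reproducible.
    """
    uniq: list[tuple[str, str]] = list(dict.fromkeys(
        (seq.upper(), group) for seq, group in records))
    if len(uniq) < 3:
        raise ValueError("need at least 3 unique sequences")
    seqs = [s for s, _ in uniq]
    groups = [g for _, g in uniq]
    onehot = one_hot_encode_rows(seqs, cdr_type)
    if np.allclose(onehot.values.std(axis=0), 0.0):
        raise ValueError("all sequences identical: components undefined")
    n_components = min(n_components, *onehot.values.shape)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(onehot.values)
    components = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            coords[:, k] *= -1.0
    return PCAResult(seqs, groups, coords, pca.explained_variance_.copy(),
                     components, onehot.columns)


def one_hot_encode_rows(seqs: Sequence[str], cdr_type: str) -> OneHotMatrix:
    """Like one_hot_encode but keeps duplicate rows (row i = seqs[i])."""
    unique_cols: dict[tuple[str, str], int] = {}
    features: list[tuple[str, str]] = []
    rows = []
    for seq in seqs:
        row = [(pos, aa) for pos, aa in number_sequence(cdr_type, seq.upper())]
        rows.append(row)
        for key in row:
            if key not in unique_cols:
                unique_cols[key] = len(features)
                features.append(key)
    values = np.zeros((len(seqs), len(features)))
    for i, row in enumerate(rows):
        for key in row:
            values[i, unique_cols[key]] = 1.0
    return OneHotMatrix(list(seqs), features, values)


@dataclass
class FrequencyMatrix:
    """Per-IMGT-position residue frequencies over unique sequences."""

    frequencies: pd.DataFrame  # index: position labels, columns: residues
    residue_classes: dict[str, str]

    def to_csv(self, path) -> None:
        self.frequencies.to_csv(path)


def frequency_matrix(seqs: Sequence[str], cdr_type: str) -> FrequencyMatrix:
    """Position frequency matrix (logo input) from unique sequences.

    Frequencies at each position sum to 1 over the residues observed
    there, matching the probabilities behind the class PSSMs.
    """
    unique = list(dict.fromkeys(s.upper() for s in seqs))
    if not unique:
        raise ValueError("need at least one sequence")
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for seq in unique:
        for pos, aa in number_sequence(cdr_type, seq):
            if pos not in counts:
                counts[pos] = {}
                order.append(pos)
            counts[pos][aa] = counts[pos].get(aa, 0) + 1
    residues = sorted({aa for c in counts.values() for aa in c})
    data = np.zeros((len(order), len(residues)))
    for i, pos in enumerate(order):
        total = sum(counts[pos].values())
        for j, aa in enumerate(residues):
            data[i, j] = counts[pos].get(aa, 0) / total
    df = pd.DataFrame(data, index=order, columns=residues)
    classes = {aa: HYDROPHOBICITY_CLASSES.get(aa, "neutral") for aa in residues}
    return FrequencyMatrix(df, classes)
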