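"""IMGT position assignment for CDR sequences.

CDR windows are CDR1 27-38, CDR2 56-65 and CDR3 105-117.  For a loop
shorter than its window, positions are filled from both ends and the gap
sits in the middle (the extra position of an odd split goes to the
N-terminal side).  Loops longer than the window receive insertion codes
on the two central positions, ascending letters on the N-side centre and
descending letters into the C-side centre, matching chain order.
"""
from __future__ import annotations

import math

from .records import CDR_WINDOWS

_CDR_OF_TYPE = {
    "a1": "CDR1", "b1": "CDR1", "L1": "CDR1", "H1": "CDR1",
    "a2": "CDR2", "b2": "CDR2", "L2": "CDR2", "H2": "CDR2",
    "a3": "CDR3", "b3": "CDR3", "L3": "CDR3", "H3": "CDR3",
}


def cdr_of_type(cdr_type: str) -> str:
    """Map a CDR type code (e.g. ``a3``) to its window name (``CDR3``)."""
    try:
        return _CDR_OF_TYPE[cdr_type]
    except KeyError:
        raise ValueError(f"unknown CDR type: {cdr_type!r}") from None


def imgt_positions(cdr_type: str, length: int) -> list[tuple[int, str]]:
    """IMGT (position, insertion code) labels for a CDR of given length.

    Returned in chain (N-to-C) order; insertion codes are letters.
    """
    if length < 1:
        raise ValueError("CDR length must be >= 1")
    start, end = CDR_WINDOWS[cdr_of_type(cdr_type)]
    width = end - start + 1
    if length <= width:
        n_left = math.ceil(length / 2)
        n_right = length - n_left
        left = [(p, "") for p in range(start, start + n_left)]
        right = [(p, "") for p in range(end - n_right + 1, end + 1)]
        return left + right
    extra = length - width
    centre_left = start + math.ceil(width / 2) - 1
    centre_right = centre_left + 1
    left = [(p, "") for p in range(start, centre_left + 1)]
    right = [(p, "") for p in range(centre_right, end + 1)]
    n_ins_left = math.ceil(extra / 2)
    n_ins_right = extra - n_ins_left
    ins_left = [(centre_left, chr(ord("A") + k)) for k in range(n_ins_left)]
    ins_right = [(centre_right, chr(ord("A") + k)) for k in reversed(range(n_ins_right))]
    return left + ins_left + ins_right + right


def position_label(position: int, insertion_code: str = "") -> str:
    return f"{position}{insertion_code}"


def number_sequence(cdr_type: str, sequence: str) -> list[tuple[str, str]]:
    """Pair each residue of a CDR sequence with its IMGT position label."""
    labels = imgt_positions(cdr_type, len(sequence))
    return [(position_label(p, ic), aa) for (p, ic), aa in zip(labels, sequence.upper())]
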