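"""M/E-box motif scanning.

MiT/TFE-family bHLH-LZ factors (TFE3, TFEB, MITF and their fusion proteins)
bind a palindromic E-box with a CACGTG core, often called the M/E-box; the
CLEAR element GTCACGTGAC is the extended lysosomal variant.  The scanner
takes an IUPAC consensus, matches it exactly (no mismatches) on both strands
and reports 0-based offsets.  An ``N`` in the *sequence* never matches — an
ambiguous base is not evidence for a motif.
"""

from __future__ import annotations

import re
from typing import NamedTuple

# IUPAC codes expanded to concrete-base character classes.  Sequence-side N
# is deliberately absent from every class.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MEBOX = "CACGTG"
CLEAR = "GTCACGTGAC"


class MotifHit(NamedTuple):
    offset: int
    strand: str


def reverse_complement(pattern: str) -> str:
    """Reverse-complement a sequence or IUPAC pattern."""
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern:
    pattern = pattern.upper()
    try:
        body = "".join(
            IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} in pattern") from exc
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


def scan_motif(sequence: str, pattern: str = MEBOX) -> list[MotifHit]:
    """Find all exact matches of an IUPAC pattern on both strands.

    Returns hits sorted by offset.  Offsets always refer to the forward
    strand: a minus-strand hit at offset *i* means the reverse complement of
    the pattern starts at *i* of the given sequence.  For palindromic
    patterns such as CACGTG both strands yield the same positions and each
    is reported once (as ``+``).
    """
    seq = sequence.upper()
    fwd = _pattern_regex(pattern)
    rev = _pattern_regex(reverse_complement(pattern))
    hits: dict[int, str] = {}
    for m in fwd.finditer(seq):
        hits[m.start()] = "+"
    for m in rev.finditer(seq):
        hits.setdefault(m.start(), "-")
    return [MotifHit(pos, hits[pos]) for pos in sorted(hits)]


def has_motif(sequence: str, pattern: str = MEBOX) -> bool:
    return bool(scan_motif(sequence, pattern))
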