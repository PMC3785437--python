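"""IUPAC nucleotide codes as bitmasks, plus fast degenerate matching helpers.

Each base maps to a 4-bit mask over (A, C, G, T). Two symbols are compatible
when their masks intersect. The gap character maps to 0 and is therefore
compatible with nothing.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

IUPAC_MASK: dict[str, int] = {
    sym: sum(_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}
IUPAC_MASK["-"] = 0

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN-", "TGCAAYRSWMKVHDBN-")

# lookup table from uint8 char code -> mask (255 marks an invalid symbol)
_MASK_TABLE = np.full(256, 255, dtype=np.uint8)
for _sym, _mask in IUPAC_MASK.items():
    _MASK_TABLE[ord(_sym)] = _mask
    _MASK_TABLE[ord(_sym.lower())] = _mask

VALID_SYMBOLS = frozenset(IUPAC_MASK)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of IUPAC bitmasks.

    Raises ValueError naming the first invalid character.
    """
    arr = _MASK_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(arr == 255)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"invalid nucleotide symbol {seq[i]!r} at position {i + 1}")
    return arr


def match_iupac(pattern: str, text: str, max_mismatch: int = 0) -> list[int]:
    """All 1-based start positions where ``pattern`` matches ``text``.

    A position pair mismatches when the IUPAC sets of the two symbols do not
    intersect; a match site tolerates at most ``max_mismatch`` such pairs.
    Only the given strand of ``text`` is searched.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    k, n = len(pattern), len(text)
    if k > n:
        return []
    pat = encode(pattern)
    txt = encode(text)
    windows = np.lib.stride_tricks.sliding_window_view(txt, k)
    mismatches = ((windows & pat) == 0).sum(axis=1)
    return [int(i) + 1 for i in np.nonzero(mismatches <= max_mismatch)[0]]


def symbols_compatible(a: str, b: str) -> bool:
    """True when the IUPAC sets of two symbols intersect (gap matches nothing)."""
    return bool(IUPAC_MASK.get(a.upper(), 0) & IUPAC_MASK.get(b.upper(), 0))
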