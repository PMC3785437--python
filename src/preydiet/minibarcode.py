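"""Mini-barcode selection by sliding-window species discrimination.

Degraded DNA in faecal samples only supports short amplicons, so the full
reference fragment must be narrowed to the shortest window that still
identifies every species. A sequence is "correctly identified" in a window
when all of its nearest neighbours by p-distance (self excluded) belong to
the same species; a window's identification success I is the fraction of
evaluable sequences identified correctly. Selection returns the shortest
window, then the leftmost, reaching a required success level.

Singleton species have no conspecific neighbour; a singleton counts as
correct when its closest heterospecific distance in the window is > 0
(i.e. it is diagnosable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._iupac import encode, match_iupac, reverse_complement
from .refdb import ReferenceLibrary

__all__ = [
    "WindowScore",
    "window_identification_success",
    "sliding_window",
    "select_minibarcode",
    "locate_amplicon",
]

_N_MASK = 15


@dataclass(frozen=True)
class WindowScore:
    """Discrimination diagnostics for one alignment window.

    ``start`` is a 1-based inclusive alignment column;
    ``identification_success`` is None when no sequence could be evaluated
    (e.g. a window of gap-only columns).
    """

    start: int
    length: int
    identification_success: float | None
    n_evaluated: int


class _WindowEngine:
    """Precomputed per-pair mismatch/comparable cumsums for fast window scans."""

    def __init__(self, lib: ReferenceLibrary):
        if not lib.is_aligned:
            raise ValueError("mini-barcode scan requires an aligned library")
        if not lib.species_clusters:
            raise ValueError("species_clusters must be populated before scanning")
        self.n = len(lib.sequences)
        self.L = lib.alignment_length
        order = sorted(lib.sequences, key=lambda s: s.seq_id)
        enc = np.stack([encode(s.sequence) for s in order])
        species_ids = {sp: k for k, sp in enumerate(sorted(lib.species_clusters))}
        self.species = np.array(
            [species_ids[lib.species_of(s.seq_id)] for s in order]
        )
        iu, ju = np.triu_indices(self.n, 1)
        self.iu, self.ju = iu, ju
        a, b = enc[iu], enc[ju]
        comparable = (a != 0) & (a != _N_MASK) & (b != 0) & (b != _N_MASK)
        diff = ((a & b) == 0) & comparable
        zeros = np.zeros((len(iu), 1), dtype=np.int64)
        self.cs_diff = np.concatenate([zeros, np.cumsum(diff, axis=1)], axis=1)
        self.cs_comp = np.concatenate([zeros, np.cumsum(comparable, axis=1)], axis=1)

    def scan(self, w: int, start0: int = 0, n_windows: int | None = None):
        """Score all w-wide windows; returns (I, n_evaluated) arrays."""
        if w < 1:
            raise ValueError("window width must be >= 1")
        if w > self.L:
            raise ValueError(f"window width {w} exceeds alignment length {self.L}")
        S_all = self.L - w + 1
        if n_windows is None:
            n_windows = S_all - start0
        if start0 < 0 or start0 + n_windows > S_all:
            raise ValueError("window outside alignment")
        sl = slice(start0, start0 + n_windows)
        mism = (self.cs_diff[:, w:] - self.cs_diff[:, :-w])[:, sl]
        comp = (self.cs_comp[:, w:] - self.cs_comp[:, :-w])[:, sl]
        with np.errstate(invalid="ignore"):
            dist = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
        n, S = self.n, n_windows
        d = np.full((S, n, n), np.nan)
        d[:, self.iu, self.ju] = dist.T
        d[:, self.ju, self.iu] = dist.T
        con = self.species[:, None] == self.species[None, :]
        np.fill_diagonal(con, False)
        het = self.species[:, None] != self.species[None, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            min_con = np.nanmin(np.where(con, d, np.nan), axis=2)
            min_het = np.nanmin(np.where(het, d, np.nan), axis=2)
        has_con_member = con.any(axis=1)  # species with >1 member
        con_def = ~np.isnan(min_con)
        het_def = ~np.isnan(min_het)
        multi = has_con_member[None, :]
        evaluated = np.where(multi, con_def | het_def, het_def)
        correct_multi = con_def & (~het_def | (min_con < np.where(het_def, min_het, np.inf)))
        correct_single = het_def & (min_het > 0)
        correct = np.where(multi, correct_multi, correct_single) & evaluated
        n_eval = evaluated.sum(axis=1)
        with np.errstate(invalid="ignore"):
            I = np.where(n_eval > 0, correct.sum(axis=1) / np.maximum(n_eval, 1), np.nan)
        return I, n_eval


def window_identification_success(
    lib: ReferenceLibrary, start: int, w: int
) -> WindowScore:
    """Score one window (1-based inclusive start column, width w)."""
    eng = _WindowEngine(lib)
    if start < 1 or start + w - 1 > eng.L:
        raise ValueError(
            f"window [{start}, {start + w - 1}] outside alignment of length {eng.L}"
        )
    I, n_eval = eng.scan(w, start0=start - 1, n_windows=1)
    success = None if np.isnan(I[0]) else float(I[0])
    return WindowScore(start, w, success, int(n_eval[0]))


def sliding_window(lib: ReferenceLibrary, w: int) -> list[WindowScore]:
    """Score every w-wide window (step 1), ordered by start column."""
    eng = _WindowEngine(lib)
    I, n_eval = eng.scan(w)
    return [
        WindowScore(s + 1, w, None if np.isnan(I[s]) else float(I[s]), int(n_eval[s]))
        for s in range(len(I))
    ]


def select_minibarcode(
    lib: ReferenceLibrary,
    w_min: int,
    w_max: int,
    required_I: float = 1.0,
) -> WindowScore | None:
    """Shortest (then leftmost) window whose identification success meets
    ``required_I``; None when no window in [w_min, w_max] qualifies."""
    if w_min > w_max:
        raise ValueError("w_min must be <= w_max")
    eng = _WindowEngine(lib)
    w_max = min(w_max, eng.L)
    for w in range(w_min, w_max + 1):
        I, n_eval = eng.scan(w)
        ok = np.where(np.isnan(I), 0.0, I) >= required_I
        hits = np.nonzero(ok)[0]
        if hits.size:
            s = int(hits[0])
            success = None if np.isnan(I[s]) else float(I[s])
            return WindowScore(s + 1, w, success, int(n_eval[s]))
    return None


def locate_amplicon(
    genome: str,
    forward: str,
    reverse: str,
    max_mismatch: int = 0,
    max_length: int | None = 1000,
) -> tuple[int, int, str]:
    """Map a degenerate primer pair onto a genome sequence.

    Finds a forward-primer site followed downstream by the reverse complement
    of the reverse primer and returns the primer-inclusive amplicon as
    (1-based start on the given strand, length, sequence). The shortest
    amplicon is returned; both strands are searched, with plus-strand hits
    preferred. Raises ValueError when no primer pair delimits an amplicon.
    """
    genome = genome.upper().replace("\n", "")
    candidates: list[tuple[int, int, str]] = []
    for strand_seq in (genome, reverse_complement(genome)):
        f_sites = match_iupac(forward, strand_seq, max_mismatch)
        r_sites = match_iupac(reverse_complement(reverse), strand_seq, max_mismatch)
        for f in f_sites:
            for r in r_sites:
                end = r + len(reverse) - 1
                length = end - f + 1
                if length >= len(forward) + len(reverse) and (
                    max_length is None or length <= max_length
                ):
                    candidates.append((f, length, strand_seq[f - 1 : end]))
        if candidates:
            break
    if not candidates:
        raise ValueError("primer pair does not delimit an amplicon in this genome")
    candidates.sort(key=lambda c: (c[1], c[0]))
    return candidates[0]
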