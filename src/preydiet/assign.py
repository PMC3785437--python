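"""Species assignment of amplicons by local alignment and E-value rules.

Each dereplicated amplicon is aligned (Smith-Waterman, affine gaps, both
strands) against every reference sequence; raw scores are converted to
E-values with ungapped Karlin-Altschul statistics, E = K*m*n*exp(-lambda*S),
where m is the query length and n the summed length of the library. A
species' hit is the best E over its cluster members. An amplicon is assigned
only under the conservative rules: a single species hit with E below the
significance threshold, or several significant hits whose top/second E-value
ratio falls below the ratio threshold. Unassigned amplicons diverging from
every library sequence by more than the novel-taxon threshold are clustered
among themselves into additional ("novel") species.

Applying the ungapped (lambda, K) to gapped local scores is an approximation;
at mini-barcode lengths and the extreme thresholds used here the resulting
decisions are insensitive to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner
from scipy.optimize import brentq

from ._iupac import reverse_complement
from .refdb import ReferenceLibrary, cluster_species, min_distance_to_library
from .readprep import AmpliconRecord

__all__ = [
    "ScoringScheme",
    "Hit",
    "AssignmentResult",
    "local_align",
    "karlin_altschul_params",
    "evalue",
    "apply_assignment_rule",
    "assign_amplicon",
    "assign_amplicons",
    "detect_novel_taxa",
]

UNIFORM_FREQS = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class ScoringScheme:
    """Integer alignment scores plus the Karlin-Altschul constants they imply.

    A gap of length k scores ``gap_open + (k-1) * gap_extend``. ``lam`` and
    ``K`` default to the values computed for the ungapped (match/mismatch)
    scheme under uniform base frequencies.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float | None = None
    K: float | None = None

    def with_params(self, freqs: dict[str, float] | None = None) -> "ScoringScheme":
        lam, K = karlin_altschul_params(self, freqs)
        return ScoringScheme(
            self.match, self.mismatch, self.gap_open, self.gap_extend, lam, K
        )

    def params(self) -> tuple[float, float]:
        if self.lam is None or self.K is None:
            return karlin_altschul_params(self)
        return self.lam, self.K


@dataclass(frozen=True)
class Hit:
    subject_id: str
    species: str
    score: float
    evalue: float


@dataclass
class AssignmentResult:
    amplicon_id: str
    sequence: str
    total_count: int
    per_sample_counts: dict[str, int]
    status: str  # assigned | unassigned | novel
    species: str | None
    best_e: float | None
    second_e: float | None
    min_library_distance: float | None = None


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal Smith-Waterman score (>= 0) of query vs subject.

    Symbols are compared literally: an ambiguity code matches only its own
    symbol. The empty local alignment scores 0.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = _aligner(scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return max(0.0, float(aligner.score(query.upper(), subject.upper())))


def _score_distribution(
    scheme: ScoringScheme, freqs: dict[str, float]
) -> dict[int, float]:
    p_match = sum(p * p for p in freqs.values())
    return {scheme.match: p_match, scheme.mismatch: 1.0 - p_match}


def karlin_altschul_params(
    scheme: ScoringScheme, freqs: dict[str, float] | None = None
) -> tuple[float, float]:
    """(lambda, K) for the ungapped match/mismatch scheme.

    lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1; K is computed from
    the classical series over the score random walk S_k:

        sigma = sum_k (1/k) [ P(S_k >= 0) + E(exp(lambda S_k); S_k < 0) ]
        K = exp(-2 sigma) * delta * lambda / (H * (1 - exp(-lambda delta)))

    with delta the lattice span of the scores and H the relative entropy.
    The simple closed form is used when scores are {+1, -1}.
    """
    freqs = freqs or UNIFORM_FREQS
    dist = _score_distribution(scheme, freqs)
    expected = sum(s * p for s, p in dist.items())
    if expected >= 0:
        raise ValueError("invalid scoring scheme: expected score must be negative")
    if max(dist) <= 0:
        raise ValueError("invalid scoring scheme: a positive score must be achievable")

    def f(lam: float) -> float:
        return sum(p * math.exp(lam * s) for s, p in dist.items()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-15)

    lo, hi_s = min(dist), max(dist)
    if lo == -1 and hi_s == 1:
        K = (dist[lo] - dist[hi_s]) ** 2 / dist[lo]
        return lam, K

    delta = math.gcd(*[abs(s) for s in dist])
    H = lam * sum(p * math.exp(lam * s) * s for s, p in dist.items())
    # random walk on the integer lattice of step `delta`
    steps = sorted(dist)
    offset = -min(steps) // delta  # index of score 0 in a single-step pmf
    step_pmf = np.zeros((max(steps) - min(steps)) // delta + 1)
    for s, p in dist.items():
        step_pmf[(s - min(steps)) // delta] = p
    pmf = np.array([1.0])
    zero_idx = 0
    sigma = 0.0
    for k in range(1, 200):
        pmf = np.convolve(pmf, step_pmf)
        zero_idx += offset
        scores = (np.arange(len(pmf)) - zero_idx) * delta
        neg = scores < 0
        term = pmf[~neg].sum() + (pmf[neg] * np.exp(lam * scores[neg])).sum()
        sigma += term / k
        if term / k < 1e-12:
            break
    C = math.exp(-2.0 * sigma)
    K = C * delta * lam / (H * (1.0 - math.exp(-lam * delta)))
    return lam, K


def evalue(score: float, m: int, n: int, lam: float, K: float) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return K * m * n * math.exp(-lam * score)


def apply_assignment_rule(
    species_evalues: dict[str, float], e_sig: float = 1e-5, r_sig: float = 1e-5
) -> tuple[str, str | None, float | None, float | None]:
    """Conservative assignment from per-species best E-values.

    Returns (status, species, best_e, second_e) where second_e is the
    E-value of the second-best *significant* species (absent otherwise).
    Significant species have E < e_sig; with one such species the amplicon
    is assigned to it; with several it is assigned to the best only when
    best/second < r_sig (a tie therefore stays unassigned).
    """
    if not species_evalues:
        return "unassigned", None, None, None
    ranked = sorted(species_evalues.items(), key=lambda kv: (kv[1], kv[0]))
    best_sp, best_e = ranked[0]
    significant = [(sp, e) for sp, e in ranked if e < e_sig]
    if len(significant) == 1:
        return "assigned", significant[0][0], significant[0][1], None
    if len(significant) >= 2:
        second_e = significant[1][1]
        if best_e / second_e < r_sig:
            return "assigned", best_sp, best_e, second_e
        return "unassigned", None, best_e, second_e
    return "unassigned", None, best_e, None


def _species_evalues(
    sequence: str,
    lib: ReferenceLibrary,
    scheme: ScoringScheme,
    lam: float,
    K: float,
    n_total: int,
) -> dict[str, float]:
    rc = reverse_complement(sequence)
    m = len(sequence)
    evals: dict[str, float] = {}
    for species, members in lib.species_clusters.items():
        best = 0.0
        for seq_id in members:
            subject = lib.get(seq_id).sequence.replace("-", "")
            s = local_align(sequence, subject, scheme)
            s_rc = local_align(rc, subject, scheme)
            best = max(best, s, s_rc)
        evals[species] = evalue(best, m, n_total, lam, K)
    return evals


def assign_amplicon(
    amplicon: AmpliconRecord | str,
    lib: ReferenceLibrary,
    scheme: ScoringScheme | None = None,
    e_sig: float = 1e-5,
    r_sig: float = 1e-5,
    amplicon_id: str = "amplicon1",
) -> AssignmentResult:
    """Assign one amplicon; both strands are scored and the best is used."""
    if not lib.sequences:
        raise ValueError("empty library")
    if not lib.species_clusters:
        raise ValueError("library has no species clusters")
    if isinstance(amplicon, str):
        amplicon = AmpliconRecord(amplicon, 1, {"unknown": 1})
    scheme = (scheme or ScoringScheme()).with_params()
    lam, K = scheme.lam, scheme.K
    n_total = sum(len(s.sequence.replace("-", "")) for s in lib.sequences)
    evals = _species_evalues(amplicon.sequence, lib, scheme, lam, K, n_total)
    status, species, best_e, second_e = apply_assignment_rule(evals, e_sig, r_sig)
    return AssignmentResult(
        amplicon_id,
        amplicon.sequence,
        amplicon.total_count,
        amplicon.per_sample_counts,
        status,
        species,
        best_e,
        second_e,
    )


def assign_amplicons(
    records: list[AmpliconRecord],
    lib: ReferenceLibrary,
    scheme: ScoringScheme | None = None,
    e_sig: float = 1e-5,
    r_sig: float = 1e-5,
) -> list[AssignmentResult]:
    """Assign a batch of amplicons (ids follow their input order)."""
    if not lib.sequences:
        raise ValueError("empty library")
    if not lib.species_clusters:
        raise ValueError("library has no species clusters")
    scheme = (scheme or ScoringScheme()).with_params()
    lam, K = scheme.lam, scheme.K
    n_total = sum(len(s.sequence.replace("-", "")) for s in lib.sequences)
    results = []
    for i, rec in enumerate(records, 1):
        evals = _species_evalues(rec.sequence, lib, scheme, lam, K, n_total)
        status, species, best_e, second_e = apply_assignment_rule(evals, e_sig, r_sig)
        results.append(
            AssignmentResult(
                f"amplicon{i}",
                rec.sequence,
                rec.total_count,
                rec.per_sample_counts,
                status,
                species,
                best_e,
                second_e,
            )
        )
    return results


def detect_novel_taxa(
    results: list[AssignmentResult], lib: ReferenceLibrary
) -> list[AssignmentResult]:
    """Promote divergent unassigned amplicons to novel species.

    An unassigned amplicon whose minimum p-distance to the library (either
    strand, computed on a global alignment) exceeds ``lib.d_novel`` becomes
    a novel-taxon candidate; candidates are clustered among themselves at
    ``lib.d_species`` and each cluster is labelled ``novel<k>``. Amplicons
    within ``d_novel`` of the library stay unassigned. Results are updated
    in place and returned.
    """
    from .refdb import ReferenceSequence

    candidates = []
    for res in results:
        if res.status != "unassigned":
            continue
        seq = res.sequence.replace("-", "")
        _, d_fwd = min_distance_to_library(seq, lib, aligned=False)
        _, d_rc = min_distance_to_library(reverse_complement(seq), lib, aligned=False)
        res.min_library_distance = min(d_fwd, d_rc)
        if res.min_library_distance > lib.d_novel:
            candidates.append(res)
    if not candidates:
        return results
    cand_lib = ReferenceLibrary(
        [ReferenceSequence(r.amplicon_id, r.sequence.replace("-", "")) for r in candidates],
        d_species=lib.d_species,
        d_novel=lib.d_novel,
    )
    clusters = cluster_species(cand_lib, lib.d_species)
    by_id = {r.amplicon_id: r for r in candidates}
    # deterministic novel ids: clusters ordered by total count (desc), then id
    def cluster_count(members: list[str]) -> int:
        return sum(by_id[m].total_count for m in members)

    ordered = sorted(clusters.values(), key=lambda mm: (-cluster_count(mm), min(mm)))
    for k, members in enumerate(ordered, 1):
        for member in members:
            res = by_id[member]
            res.status = "novel"
            res.species = f"novel{k}"
    return results
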