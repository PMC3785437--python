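"""Prey reference library: loading, p-distances and threshold species clustering.

The library holds 16S rDNA sequences from identified prey specimens. Species
are delimited as single-linkage clusters at a fixed distance threshold
(default 10% uncorrected p-distance), so that any two sequences placed in
different species differ by more than the threshold. A lower threshold
(default 7.5%) marks the divergence beyond which a query is considered to
belong to a taxon absent from the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from scipy.cluster.hierarchy import fcluster, linkage

from ._iupac import VALID_SYMBOLS, encode

__all__ = [
    "ReferenceSequence",
    "ReferenceLibrary",
    "read_library",
    "p_distance",
    "cluster_species",
    "min_distance_to_library",
]

# Global-alignment scoring used only to pre-align sequence pairs that are not
# rows of a common alignment before taking the p-distance.
UNALIGNED_MATCH = 1
UNALIGNED_MISMATCH = -1
UNALIGNED_GAP = -2

_N_MASK = 15  # IUPAC mask of N: excluded from comparable sites, like gaps


@dataclass
class ReferenceSequence:
    """One library entry: a labelled prey sequence."""

    seq_id: str
    sequence: str
    species_label: str | None = None
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.seq_id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_SYMBOLS
        if bad:
            raise ValueError(
                f"record {self.seq_id!r}: invalid symbol(s) {sorted(bad)}"
            )


@dataclass
class ReferenceLibrary:
    """Labelled prey sequences plus a species partition over them.

    ``species_clusters`` maps a species/cluster id to the sorted list of
    member ``seq_id``s; it is empty until :func:`cluster_species` is run or
    :meth:`clusters_from_labels` is called.
    """

    sequences: list[ReferenceSequence]
    species_clusters: dict[str, list[str]] = field(default_factory=dict)
    d_species: float = 0.10
    d_novel: float = 0.075

    def __post_init__(self) -> None:
        if not 0 < self.d_novel < self.d_species < 1:
            raise ValueError(
                "thresholds must satisfy 0 < d_novel < d_species < 1 "
                f"(got d_novel={self.d_novel}, d_species={self.d_species})"
            )
        ids = [s.seq_id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_id(s): {dup}")
        if self.species_clusters:
            members = [m for mm in self.species_clusters.values() for m in mm]
            if sorted(members) != sorted(ids):
                raise ValueError("species_clusters is not a partition of seq_ids")

    def __len__(self) -> int:
        return len(self.sequences)

    def get(self, seq_id: str) -> ReferenceSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    @property
    def is_aligned(self) -> bool:
        """True when all rows have equal length (a common alignment)."""
        lengths = {len(s.sequence) for s in self.sequences}
        return len(lengths) == 1

    @property
    def alignment_length(self) -> int:
        if not self.is_aligned:
            raise ValueError("library is not aligned (unequal row lengths)")
        return len(self.sequences[0].sequence)

    def clusters_from_labels(self) -> dict[str, list[str]]:
        """Populate species_clusters from the per-record species labels."""
        clusters: dict[str, list[str]] = {}
        for s in self.sequences:
            if s.species_label is None:
                raise ValueError(f"record {s.seq_id!r} has no species label")
            clusters.setdefault(s.species_label, []).append(s.seq_id)
        self.species_clusters = {k: sorted(v) for k, v in sorted(clusters.items())}
        return self.species_clusters

    def species_of(self, seq_id: str) -> str:
        for sp, members in self.species_clusters.items():
            if seq_id in members:
                return sp
        raise KeyError(f"{seq_id!r} not in any cluster")


def read_library(
    path: str | Path,
    label_rule: str = "pipe",
    species_map: dict[str, str] | None = None,
    d_species: float = 0.10,
    d_novel: float = 0.075,
) -> ReferenceLibrary:
    """Read a (possibly aligned) multi-FASTA into a ReferenceLibrary.

    ``label_rule="pipe"`` parses headers of the form ``species|specimen``;
    ``label_rule="none"`` leaves labels unset unless ``species_map`` (a
    seq_id -> species mapping, e.g. loaded from a two-column TSV) provides
    them. Clusters are left empty.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no records")
    seqs = []
    for rec in records:
        seq_id = rec.id
        label = None
        if label_rule == "pipe" and "|" in seq_id:
            label = seq_id.split("|")[0]
        if species_map is not None:
            label = species_map.get(seq_id, label)
        try:
            seqs.append(ReferenceSequence(seq_id, str(rec.seq), label))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    lib = ReferenceLibrary(seqs, d_species=d_species, d_novel=d_novel)
    if lib.is_aligned:
        for s in lib.sequences:
            s.aligned = True
    return lib


def _global_align(a: str, b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = UNALIGNED_MATCH
    aligner.mismatch_score = UNALIGNED_MISMATCH
    aligner.open_gap_score = UNALIGNED_GAP
    aligner.extend_gap_score = UNALIGNED_GAP
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _p_distance_encoded(ea: np.ndarray, eb: np.ndarray) -> float | None:
    comparable = (ea != 0) & (ea != _N_MASK) & (eb != 0) & (eb != _N_MASK)
    n = int(comparable.sum())
    if n == 0:
        return None
    diff = int((((ea & eb) == 0) & comparable).sum())
    return diff / n


def p_distance(a: str, b: str, aligned: bool = True) -> float | None:
    """Uncorrected p-distance with pairwise deletion.

    Sites where either symbol is a gap or ``N`` are excluded; at remaining
    sites two symbols match when their IUPAC sets intersect. Returns ``None``
    when no comparable sites exist. In unaligned mode the pair is first
    globally aligned (match +1, mismatch -1, gap -2).
    """
    a, b = a.upper(), b.upper()
    if not aligned:
        a, b = _global_align(a.replace("-", ""), b.replace("-", ""))
    elif len(a) != len(b):
        raise ValueError(
            f"aligned mode requires equal lengths (got {len(a)} and {len(b)})"
        )
    return _p_distance_encoded(encode(a), encode(b))


def pairwise_distance_matrix(
    lib: ReferenceLibrary, aligned: bool | None = None
) -> tuple[list[str], np.ndarray]:
    """Symmetric p-distance matrix over the library, NaN where undefined."""
    if aligned is None:
        aligned = lib.is_aligned
    order = sorted(lib.sequences, key=lambda s: s.seq_id)
    ids = [s.seq_id for s in order]
    n = len(order)
    dmat = np.zeros((n, n))
    if aligned:
        enc = [encode(s.sequence) for s in order]
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                d = _p_distance_encoded(enc[i], enc[j])
            else:
                d = p_distance(order[i].sequence, order[j].sequence, aligned=False)
            dmat[i, j] = dmat[j, i] = np.nan if d is None else d
    return ids, dmat


def cluster_species(
    lib: ReferenceLibrary, threshold: float | None = None
) -> dict[str, list[str]]:
    """Single-linkage species partition at a p-distance threshold.

    Sequences end up in different clusters exactly when every linkage path
    between them crosses a distance greater than ``threshold`` (default: the
    library's ``d_species``). Cluster ids are assigned deterministically in
    order of each cluster's lexicographically smallest member.
    """
    if threshold is None:
        threshold = lib.d_species
    ids, dmat = pairwise_distance_matrix(lib)
    bad = np.argwhere(np.isnan(np.triu(dmat, 1)))
    if bad.size:
        pairs = [(ids[i], ids[j]) for i, j in bad if np.isnan(dmat[i, j])]
        raise ValueError(f"undefined distance for pair(s): {pairs}")
    if len(ids) == 1:
        labels = np.array([1])
    else:
        condensed = dmat[np.triu_indices(len(ids), 1)]
        labels = fcluster(linkage(condensed, "single"), threshold, "distance")
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    ordered = sorted(groups.values(), key=lambda mm: min(mm))
    clusters = {f"cluster{i + 1}": sorted(mm) for i, mm in enumerate(ordered)}
    lib.species_clusters = clusters
    return clusters


def min_distance_to_library(
    query: str, lib: ReferenceLibrary, aligned: bool = False
) -> tuple[str, float]:
    """Nearest library sequence by p-distance; ties broken by smallest seq_id."""
    if not lib.sequences:
        raise ValueError("empty library")
    best: tuple[float, str] | None = None
    for s in sorted(lib.sequences, key=lambda s: s.seq_id):
        d = p_distance(query, s.sequence, aligned=aligned)
        if d is None:
            continue
        if best is None or d < best[0]:
            best = (d, s.seq_id)
    if best is None:
        raise ValueError("no comparable sites between query and any library sequence")
    return best[1], best[0]
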