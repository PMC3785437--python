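"""Demultiplexing, primer trimming, quality control and dereplication.

Pooled amplicon reads carry, at each end: a sequencing adapter, a 10 nt
sample tag (MID), and a degenerate group-specific primer around the insert.
A read is traced to its sample by an exact MID match immediately 5' of a
group-primer site; primer sites are then used to trim the read to the
primer-inclusive amplicon. Quality control keeps a read when it contains at
least one complete primer, its trimmed length falls within the expected
amplicon range, and its mean Phred quality over the trimmed region exceeds
the threshold (strict, per Q>30 = 99.9% base-call accuracy). Kept reads are
dereplicated dataset-wide into exact-sequence amplicons, and amplicons seen
fewer than ``c_min`` times in total are discarded as likely chimeras or PCR
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._iupac import match_iupac, reverse_complement

__all__ = [
    "PrimerSet",
    "TaggedRead",
    "AmpliconRecord",
    "QCConfig",
    "match_iupac",
    "read_fastq",
    "demultiplex",
    "qc_filter",
    "dereplicate",
]

# Group-specific primers for the endemic-earthworm 16S mini-barcode.
DEFAULT_FORWARD = "AATTMGGTTGGGGCGACSHW"
DEFAULT_REVERSE = "AACATCGAGGTGCCAAWCCC"
MID_LENGTH = 10


@dataclass
class PrimerSet:
    forward: str = DEFAULT_FORWARD
    reverse: str = DEFAULT_REVERSE
    mids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        tags = [t for _, t in self.mids]
        if len(tags) != len(set(tags)):
            raise ValueError("MIDs must be unique")
        for sample, tag in self.mids:
            if len(tag) != MID_LENGTH:
                raise ValueError(
                    f"MID for sample {sample!r} has length {len(tag)}, expected {MID_LENGTH}"
                )


@dataclass
class TaggedRead:
    read_id: str
    sequence: str
    qualities: np.ndarray
    sample_id: str | None = None
    ambiguous: bool = False
    primer_found: str = "none"  # forward | reverse | both | none
    insert: str | None = None
    insert_qualities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id!r}: quality/sequence length mismatch")
        if (self.qualities < 0).any():
            raise ValueError(f"read {self.read_id!r}: negative Phred score")


@dataclass
class AmpliconRecord:
    sequence: str
    total_count: int
    per_sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.total_count != sum(self.per_sample_counts.values()):
            raise ValueError("total_count must equal the sum of per-sample counts")
        if self.total_count < 1:
            raise ValueError("amplicon must have count >= 1")


@dataclass
class QCConfig:
    l_min: int = 120
    l_max: int = 160
    q_min: float = 30.0
    c_min: int = 5
    max_primer_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.l_min > self.l_max:
            raise ValueError("l_min must be <= l_max")
        if self.q_min < 0:
            raise ValueError("q_min must be >= 0")
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")


def read_fastq(path: str | Path) -> list[TaggedRead]:
    """Load Sanger Phred+33 FASTQ into TaggedRead records."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            TaggedRead(
                rec.id,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=int),
            )
        )
    return reads


def load_mid_map(path: str | Path) -> list[tuple[str, str]]:
    """Load a two-column (sample_id, tag) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "tag"], dtype=str)
    return list(df.itertuples(index=False, name=None))


def _mid_candidates(
    oriented: str, primers: PrimerSet, tag_to_sample: dict[str, str], max_mm: int
) -> set[str]:
    found = set()
    for primer in (primers.forward, primers.reverse):
        for pos in match_iupac(primer, oriented, max_mm):
            if pos > MID_LENGTH:
                tag = oriented[pos - 1 - MID_LENGTH : pos - 1]
                if tag in tag_to_sample:
                    found.add(tag_to_sample[tag])
    return found


def demultiplex(
    reads: list[TaggedRead], primers: PrimerSet, max_primer_mismatch: int = 0
) -> list[TaggedRead]:
    """Assign each read to a sample via its MID, or leave it unassigned.

    The 10 nt tag immediately 5' of a group-primer site (searched on both
    strands) must match a configured MID exactly. Reads whose tags point at
    two different samples are flagged ambiguous and left unassigned.
    """
    if not primers.mids:
        raise ValueError("no MIDs configured")
    tag_to_sample = {tag: sample for sample, tag in primers.mids}
    out = []
    for read in reads:
        samples = _mid_candidates(
            read.sequence, primers, tag_to_sample, max_primer_mismatch
        ) | _mid_candidates(
            reverse_complement(read.sequence), primers, tag_to_sample, max_primer_mismatch
        )
        if len(samples) == 1:
            out.append(replace(read, sample_id=samples.pop()))
        else:
            out.append(replace(read, sample_id=None, ambiguous=len(samples) > 1))
    return out


def _trim(read: TaggedRead, primers: PrimerSet, max_mm: int) -> TaggedRead | None:
    """Orientation-normalise and trim a read to its primer-inclusive amplicon.

    Returns None when the read contains no complete primer. In the
    normalised orientation the forward primer reads 5'->3' and the reverse
    primer appears reverse-complemented at the 3' side.
    """
    rc_rev = reverse_complement(primers.reverse)
    seq, qual = read.sequence, read.qualities
    plus = bool(match_iupac(primers.forward, seq, max_mm)) or bool(
        match_iupac(rc_rev, seq, max_mm)
    )
    if not plus:
        rc = reverse_complement(seq)
        if match_iupac(primers.forward, rc, max_mm) or match_iupac(rc_rev, rc, max_mm):
            seq, qual = rc, qual[::-1]
        else:
            return None
    f_sites = match_iupac(primers.forward, seq, max_mm)
    r_sites = match_iupac(rc_rev, seq, max_mm)
    start = f_sites[0] if f_sites else 1
    r_after = [p for p in r_sites if p + len(primers.reverse) - 1 >= start]
    end = (r_after[-1] + len(primers.reverse) - 1) if r_after else len(seq)
    if f_sites and r_after:
        flag = "both"
    elif f_sites:
        flag = "forward"
    else:
        flag = "reverse"
    return replace(
        read,
        sequence=seq,
        qualities=qual,
        primer_found=flag,
        insert=seq[start - 1 : end],
        insert_qualities=qual[start - 1 : end],
    )


def qc_filter(
    reads: list[TaggedRead], cfg: QCConfig, primers: PrimerSet | None = None
) -> tuple[list[TaggedRead], dict[str, int]]:
    """Apply the primer -> length -> quality filters.

    A read is kept iff it contains at least one complete primer, its trimmed
    amplicon length lies in [l_min, l_max] (inclusive), and the mean Phred
    score over the trimmed region is strictly greater than q_min. Rejection
    counts partition the rejected reads by the first failing rule.
    """
    primers = primers or PrimerSet()
    kept = []
    rejections = {"primer": 0, "length": 0, "quality": 0}
    for read in reads:
        trimmed = _trim(read, primers, cfg.max_primer_mismatch)
        if trimmed is None:
            rejections["primer"] += 1
            continue
        if not cfg.l_min <= len(trimmed.insert) <= cfg.l_max:
            rejections["length"] += 1
            continue
        if float(np.mean(trimmed.insert_qualities)) <= cfg.q_min:
            rejections["quality"] += 1
            continue
        kept.append(trimmed)
    return kept, rejections


def dereplicate(kept: list[TaggedRead], cfg: QCConfig) -> list[AmpliconRecord]:
    """Collapse kept reads into exact-sequence amplicons; drop count < c_min.

    Dereplication is dataset-wide: the abundance filter applies to the total
    count across all samples, the copy-number proxy for chimera and artefact
    removal. Records are sorted by descending count, then sequence.
    """
    groups: dict[str, dict[str, int]] = {}
    for read in kept:
        if read.insert is None:
            raise ValueError(f"read {read.read_id!r} has not been trimmed")
        sample = read.sample_id if read.sample_id is not None else "unassigned"
        per = groups.setdefault(read.insert, {})
        per[sample] = per.get(sample, 0) + 1
    records = [
        AmpliconRecord(seq, sum(per.values()), dict(sorted(per.items())))
        for seq, per in groups.items()
    ]
    records = [r for r in records if r.total_count >= cfg.c_min]
    records.sort(key=lambda r: (-r.total_count, r.sequence))
    return records


def write_amplicons_fasta(records: list[AmpliconRecord], path: str | Path) -> None:
    """Write amplicons as FASTA with ``;size=`` count annotations."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records, 1):
            fh.write(f">amplicon{i};size={rec.total_count}\n{rec.sequence}\n")


def per_sample_count_table(records: list[AmpliconRecord]) -> pd.DataFrame:
    """Amplicons x samples count table (amplicon index matches FASTA order)."""
    rows = [rec.per_sample_counts for rec in records]
    df = pd.DataFrame(rows).fillna(0).astype(int)
    df.index = [f"amplicon{i}" for i in range(1, len(records) + 1)]
    return df.sort_index(axis=1)
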