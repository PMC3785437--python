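from __future__ import annotations

import numpy as np
import pytest

from preydiet.readprep import PrimerSet, TaggedRead
from preydiet.refdb import ReferenceLibrary, ReferenceSequence
from preydiet._iupac import reverse_complement


@pytest.fixture
def small_library() -> ReferenceLibrary:
    """Three well-separated 20 nt species, two members each."""
    seqs = {
        "spA_m1": "ACGTACGTACGTACGTACGT",
        "spA_m2": "ACGTACGTACGTACGTACGA",
        "spB_m1": "TGCATGCATGCATGCATGCA",
        "spB_m2": "TGCATGCATGCATGCATGCC",
        "spC_m1": "AATTAATTAATTAATTAATT",
        "spC_m2": "AATTAATTAATTAATTAATG",
    }
    lib = ReferenceLibrary(
        [ReferenceSequence(k, v, species_label=k.split("_")[0]) for k, v in seqs.items()]
    )
    lib.clusters_from_labels()
    return lib


def make_read(
    read_id: str,
    insert: str,
    mid: str = "ACGTACGTAC",
    mean_q: float = 38.0,
    primers: PrimerSet | None = None,
    key: str = "TCAG",
) -> TaggedRead:
    """Construct a full tagged read: key + MID + insert + rc(MID) + nothing.

    ``insert`` should already be the primer-inclusive amplicon.
    """
    seq = key + mid + insert + reverse_complement(mid)
    quals = np.full(len(seq), int(mean_q))
    return TaggedRead(read_id, seq, quals)


@pytest.fixture
def qc_ten_reads() -> list[TaggedRead]:
    """The constructed QC audit set: 2 no-primer, 3 short, 1 low-quality, 4 clean."""
    from preydiet.readprep import PrimerSet

    primers = PrimerSet()
    rng = np.random.default_rng(42)
    core = "".join("ACGT"[i] for i in rng.integers(0, 4, size=94))
    fwd_site = "AATTAGGTTGGGGCGACCAT"  # matches the degenerate forward primer
    rev_site = reverse_complement("AACATCGAGGTGCCAATCCC")  # matches reverse primer
    amplicon = fwd_site + core + rev_site
    assert len(amplicon) == 134
    short = fwd_site + core[:60]  # 80 bp < 120 after trimming
    no_primer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=140))
    reads = [
        make_read("clean1", amplicon),
        make_read("clean2", amplicon),
        make_read("clean3", amplicon),
        make_read("clean4", amplicon),
        make_read("lowq1", amplicon, mean_q=25.0),
        make_read("short1", short),
        make_read("short2", short),
        make_read("short3", short),
        TaggedRead("noprimer1", no_primer, np.full(140, 38)),
        TaggedRead("noprimer2", no_primer[::-1], np.full(140, 38)),
    ]
    return reads
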