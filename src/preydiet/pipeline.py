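"""One-shot pipeline driver: demux -> QC -> dereplicate -> assign -> diet.

Everything is determined by (inputs, config, seed); every stage writes a
plain-text artefact and the manifest records each output with its row count
together with the fully resolved configuration, so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assign import ScoringScheme, assign_amplicons, detect_novel_taxa
from .dietstats import anova_richness, build_diet_matrix, occurrence, permanova
from .readprep import (
    PrimerSet,
    QCConfig,
    demultiplex,
    dereplicate,
    load_mid_map,
    per_sample_count_table,
    qc_filter,
    read_fastq,
    write_amplicons_fasta,
)
from .refdb import cluster_species, read_library

log = logging.getLogger("preydiet")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    library_fasta: str
    reads_fastq: str
    mid_map: str
    output_dir: str
    sample_metadata: str | None = None  # TSV: sample_id <tab> age_class
    forward_primer: str = PrimerSet.forward
    reverse_primer: str = PrimerSet.reverse
    e_sig: float = 1e-5
    r_sig: float = 1e-5
    l_min: int = 120
    l_max: int = 160
    q_min: float = 30.0
    c_min: int = 5
    max_primer_mismatch: int = 0
    d_species: float = 0.10
    d_novel: float = 0.075
    permanova_distance: str = "jaccard"
    permutations: int = 999
    seed: int = 0

    def qc_config(self) -> QCConfig:
        return QCConfig(self.l_min, self.l_max, self.q_min, self.c_min,
                        self.max_primer_mismatch)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t")
    return len(df)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "outputs": {}}

    lib = read_library(cfg.library_fasta, d_species=cfg.d_species, d_novel=cfg.d_novel)
    if all(s.species_label for s in lib.sequences):
        lib.clusters_from_labels()
    else:
        cluster_species(lib)
    log.info("library: %d sequences, %d species", len(lib), len(lib.species_clusters))

    reads = read_fastq(cfg.reads_fastq)
    primers = PrimerSet(cfg.forward_primer, cfg.reverse_primer, load_mid_map(cfg.mid_map))
    demuxed = demultiplex(reads, primers, cfg.max_primer_mismatch)
    assigned_reads = [r for r in demuxed if r.sample_id is not None]
    demux_counts = pd.Series(
        [r.sample_id for r in assigned_reads], dtype=str
    ).value_counts().rename("reads").to_frame()
    demux_counts.loc["unassigned"] = len(reads) - len(assigned_reads)
    manifest["outputs"]["demux_summary.tsv"] = _write_tsv(
        demux_counts, out / "demux_summary.tsv"
    )
    log.info("demultiplexed %d/%d reads", len(assigned_reads), len(reads))

    qc = cfg.qc_config()
    kept, rejections = qc_filter(assigned_reads, qc, primers)
    log.info("QC kept %d reads; rejections %s (l_min=%d l_max=%d q_min=%s)",
             len(kept), rejections, qc.l_min, qc.l_max, qc.q_min)
    rej = pd.DataFrame(
        {"rule": list(rejections), "rejected": list(rejections.values())}
    ).set_index("rule")
    manifest["outputs"]["rejections.tsv"] = _write_tsv(rej, out / "rejections.tsv")

    records = dereplicate(kept, qc)
    write_amplicons_fasta(records, out / "amplicons.fasta")
    manifest["outputs"]["amplicons.fasta"] = len(records)
    manifest["outputs"]["amplicon_counts.tsv"] = _write_tsv(
        per_sample_count_table(records), out / "amplicon_counts.tsv"
    )
    log.info("dereplicated to %d amplicons at c_min=%d", len(records), qc.c_min)

    results = assign_amplicons(records, lib, ScoringScheme(), cfg.e_sig, cfg.r_sig)
    results = detect_novel_taxa(results, lib)
    assign_df = pd.DataFrame(
        [
            {
                "amplicon_id": r.amplicon_id,
                "status": r.status,
                "species": r.species or "",
                "best_e": r.best_e,
                "second_e": r.second_e,
                "min_library_distance": r.min_library_distance,
                "total_count": r.total_count,
            }
            for r in results
        ]
    ).set_index("amplicon_id")
    manifest["outputs"]["assignments.tsv"] = _write_tsv(
        assign_df, out / "assignments.tsv"
    )

    if cfg.sample_metadata:
        meta_df = pd.read_csv(
            cfg.sample_metadata, sep="\t", header=None,
            names=["sample_id", "age_class"], dtype=str,
        )
        meta = dict(zip(meta_df.sample_id, meta_df.age_class))
    else:
        meta = {s: "na" for s, _ in primers.mids}
    matrix = build_diet_matrix(results, meta, species=sorted(lib.species_clusters))
    diet_df = matrix.counts.copy()
    diet_df.insert(0, "age_class", matrix.age_class)
    manifest["outputs"]["diet_matrix.tsv"] = _write_tsv(diet_df, out / "diet_matrix.tsv")

    stats: dict = {}
    if len(matrix.positive_samples) > 0:
        occ = occurrence(matrix)
        stats["occurrence"] = occ.occurrence.round(6).to_dict()
        stats["mean_richness"] = occ.mean_richness
        stats["richness_se"] = occ.richness_se
        stats["n_positive_samples"] = occ.n_positive
        groups = matrix.age_class.loc[matrix.positive_samples]
        if groups.nunique() >= 2 and len(groups) - groups.nunique() >= 1:
            an = anova_richness(matrix)
            stats["anova_richness"] = {
                "f": an.f, "df1": an.df1, "df2": an.df2, "p": an.p,
            }
            pm = permanova(
                matrix, cfg.permanova_distance, cfg.permutations, cfg.seed
            )
            stats["permanova"] = {
                "pseudo_f": pm.pseudo_f, "p": pm.p,
                "n_permutations": pm.n_permutations, "seed": pm.seed,
                "distance": pm.distance,
            }
    (out / "diet_stats.json").write_text(json.dumps(stats, indent=2))
    manifest["outputs"]["diet_stats.json"] = len(stats)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
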