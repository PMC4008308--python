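"""End-to-end orchestration: reads -> tags -> candidates -> records.

Ties the stages together exactly as a command-line run would: clean and
collapse reads, annotate ncRNA contaminants, map the remaining tags to
the genome, excise and evaluate hairpin candidates, apply the
pseudo-hairpin filter, assemble mature records with status calls, and
annotate clusters, families and copy numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import annotate, discover, genome_map, preprocess
from .config import PipelineConfig
from .io import SequenceRecord

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    accounts: list[preprocess.StageAccount]
    tags: list[preprocess.SmallRNATag]
    alignments: list[genome_map.TagAlignment]
    candidates: list[discover.HairpinCandidate]
    kept: list[discover.HairpinCandidate]
    records: list[discover.MiRNARecord]
    clusters: list[annotate.Cluster]
    families: list[annotate.Family]
    copy_histogram: dict[int, int] = field(default_factory=dict)
    total_loci: int = 0

    @property
    def tag_classes(self) -> dict[str, str]:
        """Tag sequence -> assigned precursor read class, over all kept
        candidates (arm/loop/moRNA calls agree across exact copies)."""
        out: dict[str, str] = {}
        for rec in self.records:
            if rec.profile is not None:
                out.update(rec.profile.tag_classes)
        return out

    def summary(self) -> pd.DataFrame:
        return preprocess.summarize_counts(self.accounts)


def run_pipeline(
    genome: Sequence[SequenceRecord],
    reads: Sequence[SequenceRecord],
    ncrna_library: Sequence[SequenceRecord],
    same_species_ref: Sequence[SequenceRecord] = (),
    foreign_ref: Sequence[SequenceRecord] = (),
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    if not same_species_ref and not foreign_ref:
        same_species_ref, foreign_ref = discover.load_toy_references()
    accounts = [preprocess.StageAccount("input", len(reads),
                                        len({r.seq for r in reads}))]
    cleaned, clean_account = preprocess.clean_reads(
        reads, config.read_len_min, config.read_len_max
    )
    accounts.append(clean_account)
    tags = preprocess.collapse_tags(cleaned)
    tags = preprocess.annotate_ncrna(tags, ncrna_library)
    tags_by_id = {t.tag_id: t for t in tags}

    index = genome_map.build_index(genome, config.index_k)
    alignments = genome_map.map_tags(tags, index, config.max_hits)
    mapped_tags = {a.tag_id for a in alignments}
    mapped_reads = sum(tags_by_id[t].count for t in mapped_tags)
    accounts.append(
        preprocess.StageAccount("mapped", mapped_reads, len(mapped_tags),
                                parent="clean")
    )

    unannotated = [
        a for a in alignments
        if tags_by_id[a.tag_id].annotation == preprocess.UNANNOTATED
    ]
    chroms = {rec.id: rec.seq for rec in genome}
    candidates = discover.excise_candidates(unannotated, tags_by_id, chroms, config)
    kept = []
    for cand in candidates:
        discover.evaluate_candidate(cand, config)
        if not cand.passed:
            continue
        keep, reason, pvalue = discover.mipred_filter(
            cand, config.n_shuffles, config.rng_seed, config
        )
        if keep:
            kept.append(cand)
        else:
            log.debug("candidate %s discarded by pseudo filter (%s)",
                      cand.candidate_id, reason)
    records = discover.build_records(kept, same_species_ref, foreign_ref, config)

    loci = [(rec.name, locus) for rec in records for locus in rec.loci]
    clusters = annotate.build_clusters(loci, config.cluster_gap)
    families = annotate.assign_families(
        [(rec.name, rec.mature) for rec in records],
        config.seed_start, config.seed_end,
    )
    hist, total = annotate.copy_number_summary(
        {rec.name: rec.loci for rec in records}
    )
    return PipelineResult(
        accounts=accounts,
        tags=tags,
        alignments=alignments,
        candidates=candidates,
        kept=kept,
        records=records,
        clusters=clusters,
        families=families,
        copy_histogram=hist,
        total_loci=total,
    )
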