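"""End-to-end orchestration of the small-RNA + degradome analysis.

Chains every stage on one dataset -- read cleaning, known-miRNA
quantification, novel-locus prediction, differential expression, target
scanning, degradome confirmation, and the three-way inverse-expression
integration -- and, when run on a synthetic dataset, scores each stage
against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import degradome as deg
from . import diffexpr, integrate, synthetic_data
from .io_formats import SequenceRecord, TagCountTable, to_rna
from .mirna_quant import MiRNARef, match_precursor, quantify_known
from .novel_mirna import HairpinCandidate, HairpinCriteria, predict_novel
from .preprocess import CleaningSummary, clean_libraries, map_to_genome
from .target_score import TargetAlignment, scan_transcriptome

__all__ = ["PipelineResult", "run_synthetic_pipeline", "score_against_truth"]


@dataclass
class PipelineResult:
    table: TagCountTable
    summaries: dict[str, CleaningSummary]
    known_counts: pd.DataFrame
    novel_candidates: list[HairpinCandidate]
    novel_counts: pd.DataFrame
    de: dict[str, list[diffexpr.DERecord]]
    targets: list[TargetAlignment]
    cleavage_events: list[deg.CleavageEvent]
    pairs: list[integrate.PairRecord]
    qpcr_concordance: float = float("nan")
    truth: synthetic_data.GroundTruth | None = None
    extras: dict = field(default_factory=dict)


def _refs_from_truth(truth: synthetic_data.GroundTruth) -> list[MiRNARef]:
    return [
        MiRNARef(name=k.name, precursor_seq=k.precursor,
                 mature_seq=k.mature, mature_start=k.mature_start)
        for k in truth.known
    ]


def run_synthetic_pipeline(cfg: synthetic_data.SimulationConfig,
                           criteria: HairpinCriteria | None = None,
                           target_cutoff: float = 5.0,
                           run_novel: bool = True) -> PipelineResult:
    """Generate a dataset in memory and run every stage on it."""
    criteria = criteria or HairpinCriteria()
    genome, truth = synthetic_data.generate_genome(cfg)
    libraries = synthetic_data.generate_srna_libraries(cfg, truth)

    table, summaries = clean_libraries(libraries, cfg.adapter)
    _, map_stats = map_to_genome(table, genome)
    for label, st in map_stats.items():
        summaries[label].mapped_total = st["mapped_total"]
        summaries[label].mapped_unique = st["mapped_unique"]

    refs = _refs_from_truth(truth)
    known_counts = quantify_known(table, refs)

    novel_candidates: list[HairpinCandidate] = []
    novel_counts = pd.DataFrame(columns=table.labels, dtype=int)
    if run_novel:
        known_tags = {
            t for t in table.tags
            if any(match_precursor(to_rna(t), r) is not None for r in refs)
        }
        novel_candidates, novel_counts = predict_novel(
            table, genome, criteria, exclude_tags=known_tags)
        # drop candidates sitting on a known precursor locus
        known_spans = [(k.genome_start, k.genome_end) for k in truth.known]
        kept = [
            c for c in novel_candidates
            if not any(c.start <= e and s <= c.end for s, e in known_spans)
        ]
        if len(kept) != len(novel_candidates):
            novel_candidates = kept
            novel_counts = novel_counts.loc[[c.name for c in kept]]

    all_counts = pd.concat([known_counts, novel_counts]) \
        if len(novel_counts) else known_counts
    totals = {lab: s.clean_reads for lab, s in summaries.items()}
    de = diffexpr.run_all_comparisons(all_counts, cfg.control, totals)

    mirna_records = [SequenceRecord(id=k.name, seq=k.mature) for k in truth.known]
    mirna_records += [SequenceRecord(id=c.name, seq=c.mature_tag)
                      for c in novel_candidates]
    transcripts = [SequenceRecord(id=tid, seq=seq)
                   for tid, seq in truth.transcripts.items()]
    targets = scan_transcriptome(mirna_records, transcripts, cutoff=target_cutoff)

    deg_reads = synthetic_data.generate_degradome(cfg, truth)
    tags = deg.clean_degradome(deg_reads)
    profiles = deg.build_profiles(tags, transcripts)
    events = deg.match_cleavage(targets, profiles)

    mirna_triples = integrate.direction_from_de(de)
    dge = synthetic_data.generate_dge_calls(cfg, truth)
    target_triples = {
        tid: integrate.DirectionTriple(
            conditions=tuple(cfg.conditions),
            calls=tuple(dge.loc[tid, c] for c in cfg.conditions))
        for tid in dge.index
    }
    pairs = integrate.find_inverse_pairs(mirna_triples, target_triples, events)

    qpcr = synthetic_data.generate_qpcr(cfg, truth)
    conc = integrate.concordance(qpcr, de, control=cfg.control)

    return PipelineResult(
        table=table, summaries=summaries, known_counts=known_counts,
        novel_candidates=novel_candidates, novel_counts=novel_counts,
        de=de, targets=targets, cleavage_events=events, pairs=pairs,
        qpcr_concordance=conc.attrs["agreement"], truth=truth,
        extras={"cfg": cfg},
    )


def score_against_truth(result: PipelineResult) -> dict[str, float]:
    """Recovery metrics of a synthetic run against its planted truth."""
    truth = result.truth
    if truth is None:
        raise ValueError("result carries no ground truth")

    identified = set(result.known_counts.index[
        (result.known_counts > 0).any(axis=1)])
    planted_known = {k.name for k in truth.known}
    known_recovery = len(identified & planted_known) / max(len(planted_known), 1)

    recovered_novel = 0
    for locus in truth.novel:
        for c in result.novel_candidates:
            if c.start <= locus.genome_end and locus.genome_start <= c.end \
                    and c.mature_tag == locus.mature:
                recovered_novel += 1
                break
    novel_recall = recovered_novel / max(len(truth.novel), 1)

    cat0 = {(e.mirna, e.transcript, e.cleavage_pos)
            for e in result.cleavage_events if e.category == 0}
    planted_sites = {(m, t, p) for m, t, p, _ in truth.cleavage}
    cat0_recovery = len(cat0 & planted_sites) / max(len(planted_sites), 1)

    inverse_count = sum(p.inverse for p in result.pairs)

    return {
        "known_recovery": known_recovery,
        "novel_recall": novel_recall,
        "category0_recovery": cat0_recovery,
        "inverse_pairs": float(inverse_count),
        "planted_pairs": float(len(truth.pairs)),
        "qpcr_concordance": result.qpcr_concordance,
    }
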