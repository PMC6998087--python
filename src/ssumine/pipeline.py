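"""End-to-end orchestration: evaluate -> cluster -> screen -> design -> coverage.

The library-level counterpart of the ``pipeline`` CLI subcommand. Takes
5'-anchored reads plus a taxonomy map and returns every intermediate
product: per-read evaluations, the contingency summary, the OTU partition,
the screened novel OTUs, per-group primer candidates, and the coverage of
each group's best candidate against its own reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .design import PrimerCandidate, coverage, enumerate_candidates
from .evaluate import AnchoredRead, SiteEvaluation, evaluate_reads, summarize
from .io import domain_call_from_lineage
from .iupac import union_consensus
from .otus import Otu, annotate_otus, greedy_cluster, mismatch_table, screen_novel

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    evaluations: list[SiteEvaluation]
    summary: pd.DataFrame
    otus: list[Otu]
    screened: list[Otu]
    screened_table: pd.DataFrame
    candidates: dict[str, list[PrimerCandidate]]
    coverage: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(reads: list[AnchoredRead],
                 taxonomy: dict[str, str] | None = None,
                 config: PipelineConfig | None = None,
                 reference_ids: frozenset[str] = frozenset(),
                 design_primers: bool = True) -> PipelineResult:
    if not reads:
        raise ValueError("no reads")
    config = config or PipelineConfig()
    taxonomy = taxonomy or {r.id: r.taxonomy for r in reads if r.taxonomy}
    for r in reads:
        lineage = taxonomy.get(r.id, r.taxonomy)
        if lineage is not None:
            r.taxonomy = lineage
            r.domain_call = domain_call_from_lineage(lineage)

    evals = evaluate_reads(reads, max_offset=config.max_offset,
                           max_ambiguous_frac=config.max_ambiguous_frac)
    summary = summarize(evals, reads)
    evals_by_id = {e.read_id: e for e in evals}

    otus = greedy_cluster([(r.id, r.sequence) for r in reads],
                          cutoff=config.read_cluster_cutoff,
                          mode=config.identity_mode,
                          reference_ids=reference_ids)
    annotate_otus(otus, evals_by_id, taxonomy)
    screened = screen_novel(otus, evals_by_id, config.screening)
    table = mismatch_table(screened)

    seq_by_id = {r.id: r.sequence for r in reads}
    candidates: dict[str, list[PrimerCandidate]] = {}
    cov: dict[str, pd.DataFrame] = {}
    if design_primers:
        d = config.design
        for otu in screened:
            windows = [seq_by_id[m][: d.window] for m in otu.member_ids
                       if len(seq_by_id[m]) >= d.window]
            if not windows:
                continue
            consensus = union_consensus(windows, name=otu.otu_id)
            refs = [
                (other.otu_id, seq_by_id[other.representative_id],
                 other.otu_id == otu.otu_id)
                for other in otus
                if other.representative_id in seq_by_id
            ]
            cands = enumerate_candidates(
                consensus, target_group=otu.otu_id, window=d.window,
                lengths=(d.min_length, d.max_length),
                tm_range=(d.tm_min, d.tm_max), tm_method=d.tm_method,
                degeneracy_cap=d.degeneracy_cap, references=refs,
                max_mismatches=d.specificity_max_mismatches)
            candidates[otu.otu_id] = cands
            if cands:
                best = cands[0]
                cov[otu.otu_id] = coverage(
                    best.sequence,
                    [(m, seq_by_id[m]) for m in otu.member_ids],
                    max_offset=None)
    return PipelineResult(evaluations=evals, summary=summary, otus=otus,
                          screened=screened, screened_table=table,
                          candidates=candidates, coverage=cov)
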