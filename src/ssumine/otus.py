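"""Greedy centroid OTU clustering and novelty screening.

Sequences (reads, optionally mixed with reference sequences) are sorted by
length and clustered greedily: each sequence joins the first existing
centroid whose alignment identity reaches the cutoff, otherwise it founds a
new centroid. Identity is computed with edlib; by default it is "one-way"
(edit distance of the shorter sequence aligned end-gap-free inside the
longer, divided by the shorter length), which is the natural convention for
5'-anchored fragments of very different lengths. A "two-way" global
convention is available as a switch.

Screening then flags OTUs that look like genuinely novel, primer-evading
lineages: big enough to be real (>= 10 reads), taxonomically unclassified
at the domain and/or phylum level, and with every member carrying a
complete binding site that mismatches its universal primer at >= 3 bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .evaluate import SiteEvaluation
from .io import RANKS, UNCLASSIFIED_RE, is_unclassified_at, rank_value

__all__ = [
    "Otu",
    "ScreeningCriteria",
    "identity",
    "greedy_cluster",
    "annotate_otus",
    "screen_novel",
    "mismatch_table",
]


def identity(a: str, b: str, mode: str = "one_way") -> float:
    """Pairwise identity in [0, 1] between two unaligned sequences.

    ``one_way``: the shorter sequence is aligned inside the longer with free
    end gaps on the longer (edlib HW); identity = 1 - dist / len(shorter).
    ``two_way``: global alignment (edlib NW); identity = 1 - dist / len(longer).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if mode == "one_way":
        d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
        return max(0.0, 1.0 - d / len(short))
    if mode == "two_way":
        d = edlib.align(short, long_, mode="NW", task="distance")["editDistance"]
        return max(0.0, 1.0 - d / len(long_))
    raise ValueError(f"unknown identity mode {mode!r}")


@dataclass
class Otu:
    """A cluster of sequences at a fixed identity cutoff.

    ``member_ids`` lists read members only; co-clustered reference sequences
    are tracked separately and never count toward the OTU size used by the
    screening size criterion (size refers to read support).
    """

    otu_id: str
    member_ids: list[str]
    representative_id: str
    reference_ids: list[str] = field(default_factory=list)
    consensus_taxonomy: str | None = None
    dominant_pattern: str | None = None
    dominant_mismatch_count: int | None = None
    primer_name: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(records: list[tuple[str, str]], cutoff: float,
                   mode: str = "one_way",
                   reference_ids: set[str] | frozenset[str] = frozenset()
                   ) -> list[Otu]:
    """Length-sorted greedy centroid clustering.

    Deterministic: sorting by decreasing length is stable, so equal-length
    sequences keep input order; each sequence joins the FIRST centroid (in
    founding order) reaching the identity cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if not records:
        raise ValueError("no sequences to cluster")
    ordered = sorted(records, key=lambda r: -len(r[1]))
    centroids: list[tuple[str, str]] = []  # (id, seq)
    members: list[list[str]] = []
    refs: list[list[str]] = []
    for seq_id, seq in ordered:
        placed = False
        for k, (_, cseq) in enumerate(centroids):
            if identity(seq, cseq, mode=mode) >= cutoff:
                (refs[k] if seq_id in reference_ids else members[k]).append(seq_id)
                placed = True
                break
        if not placed:
            centroids.append((seq_id, seq))
            members.append([])
            refs.append([])
            (refs[-1] if seq_id in reference_ids else members[-1]).append(seq_id)
    return [
        Otu(otu_id=f"OTU{k + 1}", member_ids=members[k],
            representative_id=centroids[k][0], reference_ids=refs[k])
        for k in range(len(centroids))
    ]


def _modal(values: list[str]) -> str:
    """Most frequent value; ties broken lexicographically."""
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def annotate_otus(otus: list[Otu],
                  evals: dict[str, SiteEvaluation],
                  taxonomy: dict[str, str] | None = None) -> list[Otu]:
    """Attach dominant mismatch pattern, primer, and consensus taxonomy.

    The dominant pattern is the modal pattern over members with complete
    sites; consensus taxonomy takes the modal value per rank (members with
    no value at a rank contribute "unclassified").
    """
    taxonomy = taxonomy or {}
    for otu in otus:
        pats = []
        primers = []
        counts = []
        for mid in otu.member_ids:
            ev = evals.get(mid)
            if ev is None:
                continue
            primers.append(ev.primer_name)
            if ev.pattern is not None:
                pats.append(ev.pattern)
                counts.append((ev.pattern, ev.mismatch_count))
        if primers:
            otu.primer_name = _modal(primers)
        if pats:
            otu.dominant_pattern = _modal(pats)
            otu.dominant_mismatch_count = dict(counts)[otu.dominant_pattern]
        lineages = [taxonomy.get(mid) for mid in otu.member_ids]
        depth = 0
        for lin in lineages:
            if lin:
                depth = max(depth, len([p for p in lin.split(";") if p.strip()]))
        depth = min(depth, len(RANKS))
        if depth:
            parts = []
            for rank in RANKS[:depth]:
                vals = [rank_value(lin, rank) or "unclassified" for lin in lineages]
                parts.append(_modal(vals))
            otu.consensus_taxonomy = ";".join(parts)
    return otus


@dataclass
class ScreeningCriteria:
    """Thresholds defining a candidate novel primer-evading OTU."""

    min_mismatches: int = 3
    min_otu_size: int = 10
    require_complete_sites: bool = True
    novelty_ranks: tuple[str, ...] = ("domain", "phylum")

    def __post_init__(self) -> None:
        if self.min_mismatches < 0:
            raise ValueError("min_mismatches must be >= 0")
        if self.min_otu_size < 1:
            raise ValueError("min_otu_size must be >= 1")


def screen_novel(otus: list[Otu], evals: dict[str, SiteEvaluation],
                 criteria: ScreeningCriteria | None = None) -> list[Otu]:
    """OTUs passing ALL screening criteria (see module docstring).

    Novelty requires the consensus lineage to be unclassified at at least
    one of the configured ranks; completeness and the mismatch floor apply
    to every read member.
    """
    criteria = criteria or ScreeningCriteria()
    passing = []
    for otu in otus:
        if otu.size < criteria.min_otu_size:
            continue
        ok = True
        for mid in otu.member_ids:
            ev = evals.get(mid)
            if ev is None:
                raise ValueError(f"member {mid!r} of {otu.otu_id} has no evaluation")
            if ev.status in ("incomplete", "unevaluable"):
                if criteria.require_complete_sites:
                    ok = False
                    break
                continue
            if ev.mismatch_count < criteria.min_mismatches:
                ok = False
                break
        if not ok:
            continue
        if not any(is_unclassified_at(otu.consensus_taxonomy, rank,
                                      UNCLASSIFIED_RE)
                   for rank in criteria.novelty_ranks):
            continue
        passing.append(otu)
    return passing


def mismatch_table(otus: list[Otu]) -> pd.DataFrame:
    """Screened OTUs as a table: primer, OTU, pattern, size, taxonomy calls."""
    rows = [
        {
            "primer": otu.primer_name,
            "otu_id": otu.otu_id,
            "pattern": otu.dominant_pattern,
            "mismatch_count": otu.dominant_mismatch_count,
            "size": otu.size,
            "taxonomy": otu.consensus_taxonomy,
        }
        for otu in otus
    ]
    df = pd.DataFrame(rows, columns=["primer", "otu_id", "pattern",
                                     "mismatch_count", "size", "taxonomy"])
    if len(df):
        df = df.sort_values(["primer", "size"], ascending=[True, False],
                            ignore_index=True)
    return df
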