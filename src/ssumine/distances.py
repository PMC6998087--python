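"""Uncorrected pairwise distances and novelty assessment for near-full-length 16S.

Distances are computed on a multiple alignment with the conventions usual
for 16S taxonomy work: columns gapped in both sequences are skipped, a run
of consecutive gap columns in one sequence counts as a single difference
(one indel event), and terminal gap overhangs are ignored. The distance is
differences / compared columns and is the complement of sequence identity,
so the proposed 75% identity boundary for phyla corresponds to a distance
of 0.25: a group whose *minimum* distance to every named phylum exceeds
0.25 is called a candidate phylum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .otus import Otu, greedy_cluster

__all__ = [
    "GAP_CHARS",
    "GroupDistanceSummary",
    "pairwise_distance",
    "filter_columns",
    "group_summaries",
    "candidate_phylum_call",
    "cluster_full_length",
    "distance_matrix",
    "write_phylip_lower",
]

GAP_CHARS = frozenset("-.")

#: Minimum ungapped length (bp) for a sequence to enter distance analysis
#: or full-length clustering.
MIN_FULL_LENGTH = 1200


def pairwise_distance(a: str, b: str, gap_runs_as_one: bool = True,
                      ignore_terminal_gaps: bool = True) -> float:
    """Uncorrected distance between two rows of the same alignment."""
    if len(a) != len(b):
        raise ValueError("sequences must come from one alignment "
                         "(equal aligned lengths)")
    a, b = a.upper(), b.upper()
    start, end = 0, len(a)
    if ignore_terminal_gaps:
        def span(s: str) -> tuple[int, int]:
            i, j = 0, len(s)
            while i < j and s[i] in GAP_CHARS:
                i += 1
            while j > i and s[j - 1] in GAP_CHARS:
                j -= 1
            return i, j
        ia, ja = span(a)
        ib, jb = span(b)
        start, end = max(ia, ib), min(ja, jb)

    diffs = 0
    compared = 0
    open_gap_in: str | None = None  # which sequence the current gap run is in
    for i in range(start, end):
        xg, yg = a[i] in GAP_CHARS, b[i] in GAP_CHARS
        if xg and yg:
            continue  # shared gap column: not compared, run stays open
        if xg or yg:
            gapped = "a" if xg else "b"
            if not gap_runs_as_one:
                diffs += 1
                compared += 1
            elif open_gap_in != gapped:
                diffs += 1
                compared += 1
            open_gap_in = gapped
            continue
        open_gap_in = None
        compared += 1
        if a[i] != b[i]:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable columns between the two sequences")
    return diffs / compared


def filter_columns(seqs: dict[str, str], max_gap_frac: float = 0.5
                   ) -> dict[str, str]:
    """Drop alignment columns gapped in more than ``max_gap_frac`` of rows."""
    if not seqs:
        return {}
    rows = list(seqs.values())
    n = len(rows)
    keep = [
        i for i in range(len(rows[0]))
        if sum(1 for r in rows if r[i] in GAP_CHARS) <= max_gap_frac * n
    ]
    return {k: "".join(v[i] for i in keep) for k, v in seqs.items()}


@dataclass
class GroupDistanceSummary:
    """Distance extrema between (or within) labelled sequence groups."""

    group_a: str
    group_b: str
    min_dist: float | None
    max_dist: float | None
    mean_dist: float | None
    n_pairs: int

    @property
    def is_intra(self) -> bool:
        return self.group_a == self.group_b


def group_summaries(seqs: dict[str, str], labels: dict[str, str]
                    ) -> tuple[list[GroupDistanceSummary], pd.DataFrame]:
    """Intra- and inter-group distance summaries plus the raw pair table.

    The raw table (columns a, b, group_a, group_b, distance) is the
    violin-plot-ready export. Singleton groups yield an intra summary with
    ``n_pairs == 0`` and undefined extrema rather than a fake zero.
    """
    groups: dict[str, list[str]] = {}
    for sid in seqs:
        groups.setdefault(labels[sid], []).append(sid)
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    rows = []
    for a, b in combinations(sorted(seqs), 2):
        rows.append({
            "a": a, "b": b,
            "group_a": labels[a], "group_b": labels[b],
            "distance": pairwise_distance(seqs[a], seqs[b]),
        })
    raw = pd.DataFrame(rows, columns=["a", "b", "group_a", "group_b",
                                      "distance"])

    summaries = []
    names = sorted(groups)
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                mask = (raw["group_a"] == ga) & (raw["group_b"] == ga)
                expected = len(groups[ga]) * (len(groups[ga]) - 1) // 2
            else:
                mask = (((raw["group_a"] == ga) & (raw["group_b"] == gb))
                        | ((raw["group_a"] == gb) & (raw["group_b"] == ga)))
                expected = len(groups[ga]) * len(groups[gb])
            d = raw.loc[mask, "distance"]
            assert len(d) == expected
            if len(d) == 0:
                summaries.append(GroupDistanceSummary(ga, gb, None, None,
                                                      None, 0))
            else:
                summaries.append(GroupDistanceSummary(
                    ga, gb, float(d.min()), float(d.max()), float(d.mean()),
                    int(len(d))))
    return summaries, raw


def candidate_phylum_call(summary: GroupDistanceSummary,
                          identity_threshold: float = 0.75) -> bool:
    """True when two groups are further apart than the phylum boundary.

    Strict inequality: the minimum inter-group distance must exceed
    ``1 - identity_threshold`` (0.25 at the proposed 75% phylum-level
    identity threshold).
    """
    if summary.is_intra:
        raise ValueError("candidate-phylum call needs an inter-group summary")
    if summary.min_dist is None:
        raise ValueError("summary has no distances")
    return summary.min_dist > 1.0 - identity_threshold


def _degap(seq: str) -> str:
    return "".join(ch for ch in seq if ch not in GAP_CHARS)


def cluster_full_length(records: list[tuple[str, str]], cutoff: float = 0.97,
                        min_length: int = MIN_FULL_LENGTH,
                        mode: str = "one_way") -> list[Otu]:
    """Greedy OTU clustering of near-full-length sequences.

    Sequences are degapped, those with ungapped length <= ``min_length`` are
    excluded (strict: a 1200 bp sequence fails the ">1200 bp" filter), and
    the survivors are clustered at ``cutoff`` (0.97 by default).
    """
    kept = [(sid, _degap(seq)) for sid, seq in records
            if len(_degap(seq)) > min_length]
    if not kept:
        raise ValueError(f"no sequences longer than {min_length} bp")
    return greedy_cluster(kept, cutoff=cutoff, mode=mode)


def distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Square symmetric matrix of pairwise distances (zero diagonal)."""
    ids = list(seqs)
    df = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        d = pairwise_distance(seqs[a], seqs[b])
        df.loc[a, b] = d
        df.loc[b, a] = d
    return df


def write_phylip_lower(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a distance matrix in PHYLIP lower-triangle format."""
    ids = list(matrix.index)
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, sid in enumerate(ids):
            vals = "\t".join(f"{matrix.iloc[i, j]:.6f}" for j in range(i))
            fh.write(f"{sid}\t{vals}".rstrip() + "\n")
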