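"""Targeted and degenerate forward-primer design.

Candidates are exhaustively enumerated from a target group's consensus over
the first 100 nt of the molecule (the region covered by 5'-anchored reads),
gated on length (16-20 nt), melting temperature (45-52 degC by default) and
degeneracy, then scored for specificity against a reference set. Primers
for several groups can be merged into one degenerate primer by per-position
union after a mismatch-minimizing registration of the group windows.

Tm models
---------
``wallace`` — the Wallace rule 2(A+T) + 4(G+C): transparent and
hand-checkable, adequate for short oligos screened against a coarse window.
``nn`` — nearest-neighbor thermodynamics (Biopython's unified parameter
implementation) at 50 mM monovalent salt and 25 nM oligo; use this when the
absolute scale matters. Degenerate candidates are gated strictly: every
concrete expansion must fall inside the Tm window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils import MeltingTemp as mt

from .evaluate import classify_mismatches
from .iupac import (
    IUPAC_SETS,
    DegenerateSequence,
    read_base_matches,
    to_paren_dialect,
    union_consensus,
)

__all__ = [
    "PrimerCandidate",
    "melting_temperature",
    "tm_range_of",
    "enumerate_candidates",
    "specificity_check",
    "merge_degenerate",
    "coverage",
    "candidate_table",
]

DESIGN_WINDOW = 100
MIN_LENGTH, MAX_LENGTH = 16, 20
TM_RANGE = (45.0, 52.0)
DEGENERACY_CAP = 32


@dataclass
class PrimerCandidate:
    """A designed forward primer with its design-window coordinates."""

    sequence: DegenerateSequence
    target_group: str
    start: int  # 0-based offset in the group consensus, half-open interval
    length: int
    tm_min: float
    tm_max: float
    degeneracy: int
    on_target_hits: int | None = None
    off_target_hits: int | None = None


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Tm (degC) of a concrete oligo under the selected model."""
    seq = seq.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in seq):
        raise ValueError("degenerate input: expand before computing Tm")
    if not 10 <= len(seq) <= 40:
        raise ValueError("Tm model calibrated for 10-40 nt oligos")
    if method == "wallace":
        return float(mt.Tm_Wallace(seq))
    if method == "nn":
        return float(mt.Tm_NN(seq, Na=50, dnac1=25, dnac2=25))
    raise ValueError(f"unknown Tm method {method!r}")


def tm_range_of(seq: DegenerateSequence, method: str = "wallace"
                ) -> tuple[float, float]:
    """Min and max Tm over all concrete expansions of a degenerate oligo."""
    tms = [melting_temperature(x, method) for x in seq.expansions()]
    return min(tms), max(tms)


def enumerate_candidates(consensus: DegenerateSequence,
                         target_group: str = "",
                         window: int = DESIGN_WINDOW,
                         lengths: tuple[int, int] = (MIN_LENGTH, MAX_LENGTH),
                         tm_range: tuple[float, float] = TM_RANGE,
                         degeneracy_cap: int = DEGENERACY_CAP,
                         tm_method: str = "wallace",
                         references: list[tuple[str, str, bool]] | None = None,
                         max_mismatches: int = 0) -> list[PrimerCandidate]:
    """All design-window substrings passing length, Tm, and degeneracy gates.

    Every concrete expansion of a degenerate substring must fall inside the
    Tm window (strict gate: every covered variant stays amplifiable). When
    ``references`` is given, each candidate is scored with
    :func:`specificity_check` and the list is sorted by off-target hits then
    by max Tm; otherwise candidates are in scan order.
    """
    lo, hi = lengths
    if window < lo:
        raise ValueError(f"design window {window} shorter than minimum primer "
                         f"length {lo}")
    region = consensus.bases[:window]
    out: list[PrimerCandidate] = []
    for length in range(lo, hi + 1):
        for start in range(0, len(region) - length + 1):
            sub = DegenerateSequence(region[start : start + length],
                                     name=f"{target_group}_{start}_{length}")
            if sub.degeneracy > degeneracy_cap:
                continue
            tmin, tmax = tm_range_of(sub, tm_method)
            if tmin < tm_range[0] or tmax > tm_range[1]:
                continue
            cand = PrimerCandidate(sequence=sub, target_group=target_group,
                                   start=start, length=length, tm_min=tmin,
                                   tm_max=tmax, degeneracy=sub.degeneracy)
            out.append(cand)
    if references is not None:
        for cand in out:
            on, off = specificity_check(cand.sequence, references,
                                        max_mismatches=max_mismatches)
            cand.on_target_hits, cand.off_target_hits = on, off
        out.sort(key=lambda c: (c.off_target_hits, c.tm_max))
    return out


def _iupac_regex(seq: DegenerateSequence) -> re.Pattern:
    return re.compile("".join(
        ch if len(IUPAC_SETS[ch]) == 1 else "[" + "".join(sorted(IUPAC_SETS[ch])) + "]"
        for ch in seq.bases
    ))


def _has_site(primer: DegenerateSequence, seq: str, max_mismatches: int,
              rx: re.Pattern) -> bool:
    if max_mismatches == 0:
        return rx.search(seq) is not None
    L = len(primer)
    three_prime = range(L - 4, L)
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        n = 0
        good = True
        for i in range(L):
            if not read_base_matches(primer.bases[i], window[i]):
                if i in three_prime:  # 3' anchor must match exactly
                    good = False
                    break
                n += 1
                if n > max_mismatches:
                    good = False
                    break
        if good:
            return True
    return False


def specificity_check(candidate: DegenerateSequence,
                      references: list[tuple[str, str, bool]],
                      max_mismatches: int = 0) -> tuple[int, int]:
    """Count reference sequences carrying a binding site for the candidate.

    ``references`` is a list of ``(id, sequence, is_target)``; the forward
    strand is searched (candidates are forward primers against SSU rRNA
    references written 5'->3'). With ``max_mismatches > 0`` the four
    3'-terminal primer positions must still match exactly, mirroring the
    3'-weighted view of amplification.
    """
    if not references:
        raise ValueError("empty reference set")
    rx = _iupac_regex(candidate)
    on = off = 0
    for _, seq, is_target in references:
        if _has_site(candidate, seq.upper().replace("U", "T"),
                     max_mismatches, rx):
            if is_target:
                on += 1
            else:
                off += 1
    return on, off


def _degenerate_mismatches(a: str, b: str) -> int:
    """Positions where two IUPAC strings have disjoint expansion sets."""
    return sum(1 for x, y in zip(a, b)
               if not (IUPAC_SETS[x] & IUPAC_SETS[y]))


def _register(anchor: str, other: str) -> int:
    """Offset of ``other`` within/against ``anchor`` minimizing mismatches.

    The shorter string slides along the longer; only full-overlap placements
    are considered. Returns the offset of ``other`` relative to ``anchor``
    (negative when ``other`` extends 5' of the anchor).
    """
    if len(other) <= len(anchor):
        offsets = range(0, len(anchor) - len(other) + 1)
        best = min(offsets, key=lambda o: _degenerate_mismatches(
            anchor[o : o + len(other)], other))
        return best
    offsets = range(0, len(other) - len(anchor) + 1)
    best = min(offsets, key=lambda o: _degenerate_mismatches(
        other[o : o + len(anchor)], anchor))
    return -best


def merge_degenerate(group_sites: dict[str, list[str]],
                     degeneracy_cap: int = DEGENERACY_CAP,
                     name: str = "merged") -> DegenerateSequence:
    """Single degenerate primer covering every site of every group.

    Group windows are first registered against the first group's consensus
    at the mismatch-minimizing offset (site lengths need not agree across
    groups), then cropped to the common window and unioned per position.
    Raises when the merged degeneracy exceeds the cap, reporting the
    offending positions.
    """
    if not group_sites:
        raise ValueError("no groups to merge")
    names = list(group_sites)
    consensi = {g: union_consensus(group_sites[g]).bases for g in names}
    anchor = consensi[names[0]]
    offsets = {names[0]: 0}
    for g in names[1:]:
        offsets[g] = _register(anchor, consensi[g])
    # common window in anchor coordinates
    lo = max(offsets[g] for g in names)
    hi = min(offsets[g] + len(consensi[g]) for g in names)
    if hi - lo < 1:
        raise ValueError("group windows do not overlap after registration")
    cropped = []
    for g in names:
        for site in group_sites[g]:
            cropped.append(site[lo - offsets[g] : hi - offsets[g]])
    merged = union_consensus(cropped, name=name)
    if merged.degeneracy > degeneracy_cap:
        bad = [i + 1 for i, ch in enumerate(merged.bases)
               if len(IUPAC_SETS[ch]) > 1]
        raise ValueError(
            f"merged degeneracy {merged.degeneracy} exceeds cap "
            f"{degeneracy_cap}; degenerate positions: {bad}"
        )
    return merged


def coverage(primer: DegenerateSequence, seqs: list[tuple[str, str]],
             max_offset: int | None = None) -> pd.DataFrame:
    """Best-placement mismatch report of a primer against each sequence.

    Scans every placement of the primer on the forward strand (restricted
    to the first ``max_offset`` starts when given), keeps the one with the
    fewest mismatches, and classifies it with the 3'-weighted matching rule.
    Sequences shorter than the primer are reported as ``incomplete``.
    """
    L = len(primer)
    rows = []
    for seq_id, seq in seqs:
        seq = seq.upper().replace("U", "T")
        if len(seq) < L:
            rows.append({"id": seq_id, "best_start": None,
                         "mismatch_count": None, "call": "incomplete"})
            continue
        last = len(seq) - L if max_offset is None else min(max_offset,
                                                           len(seq) - L)
        best_n, best_off, best_pos = None, None, None
        for off in range(last + 1):
            positions = [
                i + 1 for i in range(L)
                if not read_base_matches(primer.bases[i], seq[off + i])
            ]
            if best_n is None or len(positions) < best_n:
                best_n, best_off, best_pos = len(positions), off, positions
                if best_n == 0:
                    break
        rows.append({
            "id": seq_id,
            "best_start": best_off,
            "mismatch_count": best_n,
            "call": classify_mismatches(best_pos, L),
        })
    return pd.DataFrame(rows, columns=["id", "best_start", "mismatch_count",
                                       "call"])


def candidate_table(candidates: list[PrimerCandidate]) -> pd.DataFrame:
    """Candidates as a TSV-ready table (IUPAC and parenthetical spellings)."""
    rows = [
        {
            "name": c.sequence.name,
            "target_group": c.target_group,
            "iupac": c.sequence.bases,
            "spelled": to_paren_dialect(c.sequence),
            "start": c.start,
            "length": c.length,
            "tm_min": c.tm_min,
            "tm_max": c.tm_max,
            "degeneracy": c.degeneracy,
            "on_target_hits": c.on_target_hits,
            "off_target_hits": c.off_target_hits,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["name", "target_group", "iupac",
                                       "spelled", "start", "length", "tm_min",
                                       "tm_max", "degeneracy",
                                       "on_target_hits", "off_target_hits"])
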