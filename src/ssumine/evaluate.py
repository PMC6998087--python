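"""Universal-primer evaluation of 5'-anchored SSU rRNA reads.

Reads produced by 5'-adaptor-ligated meta-transcriptome libraries start at
the biological 5' terminus of the SSU rRNA, so a forward primer's binding
site sits at (or within a few bases of) the read start. Each read is
classified against the universal primer assigned to its domain call:

* ``incomplete``   — the read is too short to contain the full binding site;
* ``matching``     — 0 mismatches, or exactly 1 mismatch outside the last
  four primer positions;
* ``mismatching``  — >=2 mismatches, or 1 mismatch within the last four
  3'-end positions (a 3'-terminal mismatch abolishes extension in practice);
* ``unevaluable``  — the site window is too ambiguous to judge.

Mismatch patterns use the conventional dialect: ``=`` where the read agrees
with the primer, the observed read base where it does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import DEFAULT_DOMAIN_PRIMERS, PRIMERS
from .iupac import DegenerateSequence, read_base_matches

__all__ = [
    "AnchoredRead",
    "SiteEvaluation",
    "classify_mismatches",
    "locate_site",
    "evaluate_site",
    "evaluate_read",
    "evaluate_reads",
    "summarize",
    "unclassified_pct_of_mismatched",
]

#: Number of 3'-terminal primer positions where a single mismatch is fatal.
THREE_PRIME_WINDOW = 4

#: Maximum tolerated fraction of ambiguous bases in a site window.
DEFAULT_MAX_AMBIGUOUS_FRAC = 0.10


@dataclass
class AnchoredRead:
    """A 5'-complete (or deliberately truncated) SSU rRNA read."""

    id: str
    sequence: str
    taxonomy: str | None = None
    domain_call: str = "Unclassified"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")


@dataclass
class SiteEvaluation:
    """Outcome of comparing one read's binding site to one primer."""

    read_id: str
    primer_name: str
    status: str  # incomplete | matching | mismatching | unevaluable
    pattern: str | None = None
    mismatch_count: int | None = None
    site_start: int | None = None

    def __post_init__(self) -> None:
        if self.status in ("matching", "mismatching"):
            if self.pattern is None or self.mismatch_count is None:
                raise ValueError(f"{self.status} evaluation requires a pattern")
            n = sum(1 for ch in self.pattern if ch != "=")
            if n != self.mismatch_count:
                raise ValueError(
                    f"mismatch_count {self.mismatch_count} disagrees with "
                    f"pattern {self.pattern!r} ({n} non-'=' characters)"
                )


def classify_mismatches(positions: list[int], primer_length: int) -> str:
    """Apply the 3'-weighted matching rule to 1-based mismatch positions."""
    if len(positions) == 0:
        return "matching"
    if len(positions) == 1:
        # last four positions: L-3 .. L inclusive
        return ("mismatching"
                if positions[0] > primer_length - THREE_PRIME_WINDOW
                else "matching")
    return "mismatching"


def _site_mismatches(primer: DegenerateSequence, site: str) -> list[int]:
    return [
        i + 1
        for i, (code, base) in enumerate(zip(primer.bases, site))
        if not read_base_matches(code, base)
    ]


def locate_site(read: AnchoredRead, primer: DegenerateSequence,
                max_offset: int = 0) -> tuple[int, bool]:
    """Best placement of the primer's binding site near the read 5' end.

    Scans offsets ``0..max_offset`` (offsets > 0 accommodate residual
    adaptor bases) and returns the offset with the fewest mismatches among
    placements fully contained in the read; ties go to the smallest offset.
    Returns ``(0, False)`` when no complete placement fits.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    L = len(primer)
    best: tuple[int, int] | None = None  # (count, offset)
    for off in range(max_offset + 1):
        if off + L > len(read.sequence):
            break
        n = len(_site_mismatches(primer, read.sequence[off : off + L]))
        if best is None or n < best[0]:
            best = (n, off)
        if n == 0:
            break
    if best is None:
        return 0, False
    return best[1], True


def evaluate_site(primer: DegenerateSequence, site: str) -> tuple[str, int, str]:
    """Pattern string, mismatch count, and status for one complete site."""
    positions = _site_mismatches(primer, site)
    posset = set(positions)
    pattern = "".join(
        site[i] if (i + 1) in posset else "=" for i in range(len(primer))
    )
    return pattern, len(positions), classify_mismatches(positions, len(primer))


def evaluate_read(read: AnchoredRead, primer: DegenerateSequence,
                  max_offset: int = 0,
                  max_ambiguous_frac: float = DEFAULT_MAX_AMBIGUOUS_FRAC
                  ) -> SiteEvaluation:
    """Classify one read against one primer (see module docstring)."""
    if len(read.sequence) == 0:
        return SiteEvaluation(read.id, primer.name, "unevaluable")
    start, complete = locate_site(read, primer, max_offset)
    if not complete:
        return SiteEvaluation(read.id, primer.name, "incomplete")
    site = read.sequence[start : start + len(primer)]
    ambiguous = sum(1 for ch in site if ch not in "ACGT")
    if ambiguous > max_ambiguous_frac * len(primer):
        return SiteEvaluation(read.id, primer.name, "unevaluable",
                              site_start=start)
    pattern, n, status = evaluate_site(primer, site)
    return SiteEvaluation(read.id, primer.name, status, pattern=pattern,
                          mismatch_count=n, site_start=start)


def evaluate_reads(reads: list[AnchoredRead],
                   domain_primers: dict[str, str] | None = None,
                   primers: dict[str, DegenerateSequence] | None = None,
                   max_offset: int = 0,
                   max_ambiguous_frac: float = DEFAULT_MAX_AMBIGUOUS_FRAC
                   ) -> list[SiteEvaluation]:
    """Evaluate every read against the primer assigned to its domain call.

    Site windows recur verbatim across reads from the same lineage, so
    results are memoized on the window string — a large speedup on real
    datasets where a handful of site variants dominate.
    """
    domain_primers = dict(DEFAULT_DOMAIN_PRIMERS if domain_primers is None
                          else domain_primers)
    primers = dict(PRIMERS if primers is None else primers)
    cache: dict[tuple[str, str], SiteEvaluation] = {}
    out: list[SiteEvaluation] = []
    for read in reads:
        pname = domain_primers.get(read.domain_call,
                                   domain_primers["Unclassified"])
        primer = primers[pname]
        window = read.sequence[: len(primer) + max_offset]
        key = (pname, window)
        hit = cache.get(key)
        if hit is None:
            hit = evaluate_read(read, primer, max_offset, max_ambiguous_frac)
            cache[key] = hit
        out.append(SiteEvaluation(read.id, hit.primer_name, hit.status,
                                  hit.pattern, hit.mismatch_count,
                                  hit.site_start))
    return out


def summarize(evals: list[SiteEvaluation],
              reads: list[AnchoredRead]) -> pd.DataFrame:
    """Contingency table per (domain call, primer).

    Columns: ``incomplete``, ``matching``, ``mismatching_1_2`` (mismatching
    reads with 1 or 2 mismatches), ``mismatching_ge3``, ``unevaluable``.
    """
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate read ids: {dupes[:5]}")
    by_id = {r.id: r for r in reads}
    if len(evals) != len(reads):
        raise ValueError("need exactly one evaluation per read")

    rows: dict[tuple[str, str], dict[str, int]] = {}
    for ev in evals:
        read = by_id[ev.read_id]
        key = (read.domain_call, ev.primer_name)
        row = rows.setdefault(key, {c: 0 for c in (
            "incomplete", "matching", "mismatching_1_2", "mismatching_ge3",
            "unevaluable")})
        if ev.status == "mismatching":
            col = "mismatching_1_2" if ev.mismatch_count <= 2 else "mismatching_ge3"
        else:
            col = ev.status
        row[col] += 1
    df = pd.DataFrame(
        [{"domain": d, "primer": p, **counts} for (d, p), counts in rows.items()]
    ).sort_values(["domain", "primer"], ignore_index=True)
    return df


def unclassified_pct_of_mismatched(n_unclassified: int, n_mismatched: int,
                                   ndigits: int = 1) -> float:
    """Percentage of mismatching reads unclassified at the phylum level."""
    if n_mismatched <= 0:
        raise ValueError("no mismatched reads")
    if not 0 <= n_unclassified <= n_mismatched:
        raise ValueError("unclassified count outside [0, mismatched]")
    return round(100.0 * n_unclassified / n_mismatched, ndigits)
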