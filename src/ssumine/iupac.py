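"""Degenerate-nucleotide algebra.

Everything downstream — binding-site evaluation, mismatch patterns,
degenerate primer merging — reduces to set operations on IUPAC ambiguity
codes. A degenerate sequence is treated as a per-position family of
concrete A/C/G/T sets; two positions "match" when the observed base is a
member of the code's expansion set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_SETS",
    "DegenerateSequence",
    "code_matches",
    "read_base_matches",
    "degeneracy",
    "mismatch_positions",
    "reverse_complement",
    "union_consensus",
    "parse_primer_text",
    "to_paren_dialect",
    "reference_expansion",
    "apply_pattern",
]

#: Expansion set of each IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: frozenset of concrete bases -> minimal IUPAC code.
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Per-code complement (complement of the expansion set, re-encoded).
COMPLEMENT: dict[str, str] = {
    code: SET_TO_CODE[frozenset(_COMPLEMENT_BASE[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC alphabet."""


def _normalize(bases: str) -> str:
    """Uppercase, RNA->DNA (U->T), and validate against the IUPAC alphabet."""
    out = bases.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_SETS:
            raise InvalidSequenceError(
                f"invalid IUPAC character {ch!r} at position {i + 1}"
            )
    return out


@dataclass(frozen=True)
class DegenerateSequence:
    """An IUPAC-coded nucleotide string, e.g. a primer or a consensus site.

    Parameters
    ----------
    bases
        Sequence over the 15-letter IUPAC nucleotide alphabet. Lowercase and
        RNA `U` are accepted and canonicalized to uppercase DNA.
    name
        Free-form identifier (primer name, group id).
    orientation
        ``"forward"`` or ``"reverse"`` — bookkeeping only; the bases are
        always stored as written 5'->3'.
    """

    bases: str
    name: str = ""
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise InvalidSequenceError("empty sequence")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        object.__setattr__(self, "bases", _normalize(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i):
        return self.bases[i]

    def __iter__(self):
        return iter(self.bases)

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences this degenerate sequence encodes."""
        n = 1
        for ch in self.bases:
            n *= len(IUPAC_SETS[ch])
        return n

    def expansions(self):
        """Yield every concrete A/C/G/T sequence encoded (lexicographic order)."""
        pools = [sorted(IUPAC_SETS[ch]) for ch in self.bases]
        for combo in itertools.product(*pools):
            yield "".join(combo)

    def sub(self, start: int, length: int, name: str = "") -> "DegenerateSequence":
        return DegenerateSequence(self.bases[start : start + length], name=name,
                                  orientation=self.orientation)


def code_matches(code: str, base: str) -> bool:
    """True iff concrete ``base`` is in the expansion set of IUPAC ``code``."""
    try:
        codeset = IUPAC_SETS[code.upper()]
    except KeyError:
        raise InvalidSequenceError(f"invalid IUPAC code {code!r}") from None
    if base.upper() not in "ACGT":
        raise InvalidSequenceError(f"base must be concrete A/C/G/T, got {base!r}")
    return base.upper() in codeset


def read_base_matches(code: str, read_base: str) -> bool:
    """Match rule tolerating ambiguous bases in reads.

    A concrete read base matches when it lies in the code's expansion set.
    An ambiguous read base (N, R, ...) counts as a match only when its own
    expansion set is a subset of the code's set — conservative, so ambiguity
    never manufactures agreement with the primer.
    """
    code_set = IUPAC_SETS[code.upper()]
    try:
        read_set = IUPAC_SETS[read_base.upper()]
    except KeyError:
        raise InvalidSequenceError(f"invalid read base {read_base!r}") from None
    return read_set <= code_set


def degeneracy(seq: DegenerateSequence | str) -> int:
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    return seq.degeneracy


def mismatch_positions(primer: DegenerateSequence | str, site: str) -> list[int]:
    """1-based positions where ``site`` disagrees with ``primer``.

    ``site`` must be exactly primer-length: extract a complete binding site
    before calling. Ambiguous site bases are judged by the subset rule of
    :func:`read_base_matches`.
    """
    if isinstance(primer, str):
        primer = DegenerateSequence(primer)
    site = _normalize(site)
    if len(site) != len(primer):
        raise ValueError(
            f"site length {len(site)} != primer length {len(primer)}; "
            "extract a complete binding site first"
        )
    return [
        i + 1
        for i, (code, base) in enumerate(zip(primer.bases, site))
        if not read_base_matches(code, base)
    ]


def reverse_complement(seq: DegenerateSequence | str) -> DegenerateSequence:
    """Reverse complement over IUPAC codes (R<->Y, K<->M, B<->V, D<->H)."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    rc = "".join(COMPLEMENT[ch] for ch in reversed(seq.bases))
    flipped = "reverse" if seq.orientation == "forward" else "forward"
    return DegenerateSequence(rc, name=seq.name, orientation=flipped)


def union_consensus(sites: list[str], name: str = "") -> DegenerateSequence:
    """Minimal degenerate sequence covering every input site.

    Per position, the IUPAC code whose expansion set equals the union of
    bases observed there. Inputs may themselves be degenerate; their sets
    are unioned. All sites must share one length.
    """
    if not sites:
        raise ValueError("union_consensus requires at least one site")
    norm = [_normalize(s) for s in sites]
    length = len(norm[0])
    if any(len(s) != length for s in norm):
        raise ValueError("all sites must have equal length")
    out = []
    for col in zip(*norm):
        union: frozenset[str] = frozenset()
        for ch in col:
            union |= IUPAC_SETS[ch]
        out.append(SET_TO_CODE[union])
    return DegenerateSequence("".join(out), name=name)


_PAREN_RE = re.compile(r"\(([ACGTUacgtu](?:/[ACGTUacgtu])+)\)")


def parse_primer_text(text: str) -> str:
    """Normalize a primer string to pure IUPAC.

    Accepts either plain IUPAC (``GGRCACTGCTATCGGCTT``) or the parenthetical
    dialect common in primer tables (``GG(A/G)CACTGCTATCGGCTT``); whitespace
    and 5'-/-3' decorations are stripped.
    """
    s = text.strip()
    s = re.sub(r"^5['′]-?|-?3['′]$", "", s)
    s = re.sub(r"\s+", "", s)

    def repl(m: re.Match) -> str:
        alts = frozenset(b.upper().replace("U", "T") for b in m.group(1).split("/"))
        return SET_TO_CODE[alts]

    return _normalize(_PAREN_RE.sub(repl, s))


def to_paren_dialect(seq: DegenerateSequence | str) -> str:
    """Render with degenerate positions spelled out, e.g. ``R`` -> ``(A/G)``."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    out = []
    for ch in seq.bases:
        s = IUPAC_SETS[ch]
        if len(s) == 1:
            out.append(ch)
        else:
            out.append("(" + "/".join(sorted(s)) + ")")
    return "".join(out)


def reference_expansion(seq: DegenerateSequence | str) -> str:
    """Canonical concrete expansion: lexicographically smallest base per position."""
    if isinstance(seq, str):
        seq = DegenerateSequence(seq)
    return "".join(min(IUPAC_SETS[ch]) for ch in seq.bases)


def apply_pattern(primer: DegenerateSequence | str, pattern: str) -> str:
    """Reconstruct a binding site from a primer and a mismatch pattern.

    The pattern dialect writes ``=`` where the site agrees with the primer
    and the observed base where it does not. Agreement positions are filled
    from the primer's canonical expansion, so the reconstruction is exact at
    every non-degenerate primer position.
    """
    if isinstance(primer, str):
        primer = DegenerateSequence(primer)
    if len(pattern) != len(primer):
        raise ValueError(
            f"pattern length {len(pattern)} != primer length {len(primer)}"
        )
    ref = reference_expansion(primer)
    out = []
    for i, ch in enumerate(pattern):
        if ch == "=":
            out.append(ref[i])
        else:
            out.append(_normalize(ch))
    return "".join(out)
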