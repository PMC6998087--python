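"""Built-in primer catalog.

Universal SSU rRNA primers routinely used for prokaryotic community
profiling, plus the targeted/degenerate forward primers published for the
Asgard-superphylum work this package supports. All sequences are stored as
IUPAC strings; the parenthetical table dialect is accepted on ingest.
"""

from __future__ import annotations

from .iupac import DegenerateSequence, parse_primer_text

__all__ = ["PRIMERS", "get_primer", "DEFAULT_DOMAIN_PRIMERS"]

_RAW = {
    # universal forward primers
    "8F": "AGAGTTTGAT(C/T)(A/C)TGGCTCAG",
    "Arch21F": "TTCCGGTTGATCCTGCCGGA",
    # universal reverse primers (supplied for coverage validation only)
    "1492R": "GGTTACCTTGTTA(C/T)GACTT",
    "1492R-22W": "TACGG(A/T)TACCTTGTTACGACTT",
    # legacy archaeal forward primer used for early Asgard-related clones
    "4F": "TCCGGTTGATCCTGCC(A/G)G",
    # targeted forward primers for the two primer-evading groups
    "21AF": "CTCTAGTTGATCCTGCTAGA",
    "26AF": "GG(A/G)CACTGCTATCGGCTT",
    "59AF": "AAGTCGAACGGACACGCAT",
    "12BF": "CGATCCTGACGGAGCCTA",
    "15BF": "ATCCTGACGGAGCCTA",
    "16BF": "TCCTGACGGAGCCTAC",
    "17BF": "CCTGACGGAGCCTACT",
    "26BF": "GCCTACTGCTATCGGATT",
    "27BF": "CCTACTGCTATCGGATT",
    # degenerate forward primer covering both groups
    "26ABF": "G(G/C)(G/A/C)(C/T)ACTGCTATCGG(A/C)TT",
}

_REVERSE = {"1492R", "1492R-22W"}

PRIMERS: dict[str, DegenerateSequence] = {
    name: DegenerateSequence(
        parse_primer_text(seq),
        name=name,
        orientation="reverse" if name in _REVERSE else "forward",
    )
    for name, seq in _RAW.items()
}

#: Which forward primer evaluates reads of each domain call. Bacterial reads
#: are checked against 8F; archaeal and domain-unclassified reads against
#: Arch21F.
DEFAULT_DOMAIN_PRIMERS: dict[str, str] = {
    "Bacteria": "8F",
    "Archaea": "Arch21F",
    "Unclassified": "Arch21F",
}


def get_primer(name: str) -> DegenerateSequence:
    try:
        return PRIMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown primer {name!r}; known: {', '.join(sorted(PRIMERS))}"
        ) from None
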