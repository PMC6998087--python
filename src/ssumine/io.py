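"""Format plumbing: FASTA, taxonomy TSV, primer files, result tables.

FASTA goes through Bio.SeqIO; tabular inputs and outputs are pandas
DataFrames written as TSV. Taxonomy lineages are semicolon-delimited,
SILVA-style, with positional rank inference (domain; phylum; class; ...).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import DegenerateSequence, parse_primer_text

__all__ = [
    "RANKS",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "read_primers",
    "split_lineage",
    "rank_value",
    "is_unclassified_at",
    "domain_call_from_lineage",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Rank values matching this pattern are treated as "no classification".
UNCLASSIFIED_RE = re.compile(r"unclassified|unknown|uncultured", re.IGNORECASE)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``[(id, uppercase sequence), ...]``."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """2-column TSV (sequence id, semicolon-delimited lineage) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "lineage"],
                     dtype=str, comment="#")
    return dict(zip(df["id"], df["lineage"].fillna("")))


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(taxonomy), "lineage": [taxonomy[k] for k in taxonomy]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_primers(path: str | Path) -> list[DegenerateSequence]:
    """Read primers from FASTA or a TSV of (name, sequence[, orientation]).

    Sequences may use IUPAC codes or the parenthetical ``(C/T)`` dialect;
    both are normalized to IUPAC.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [
            DegenerateSequence(parse_primer_text(seq), name=name)
            for name, seq in read_fasta(path)
        ]
    primers = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"primer TSV line needs >=2 columns: {line!r}")
        name, seq = parts[0], parts[1]
        orientation = parts[2] if len(parts) > 2 else "forward"
        primers.append(
            DegenerateSequence(parse_primer_text(seq), name=name,
                               orientation=orientation)
        )
    return primers


def split_lineage(lineage: str | None) -> list[str]:
    if not lineage:
        return []
    return [part.strip() for part in lineage.split(";") if part.strip() != ""]


def rank_value(lineage: str | None, rank: str) -> str | None:
    """Value at a named rank (positional), or None when the lineage is shorter."""
    parts = split_lineage(lineage)
    idx = RANKS.index(rank)
    return parts[idx] if idx < len(parts) else None


def is_unclassified_at(lineage: str | None, rank: str,
                       pattern: re.Pattern = UNCLASSIFIED_RE) -> bool:
    """True when the lineage lacks the rank or its value looks unclassified."""
    value = rank_value(lineage, rank)
    return value is None or bool(pattern.search(value))


def domain_call_from_lineage(lineage: str | None) -> str:
    """Collapse a lineage to the coarse call used to pick the test primer."""
    value = rank_value(lineage, "domain")
    if value is None or UNCLASSIFIED_RE.search(value):
        return "Unclassified"
    if value.lower().startswith("bac"):
        return "Bacteria"
    if value.lower().startswith("arch"):
        return "Archaea"
    return "Unclassified"
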