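"""Degenerate-nucleotide algebra: matching, degeneracy, complement, union."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssumine.catalog import PRIMERS
from ssumine.iupac import (
    IUPAC_SETS,
    DegenerateSequence,
    InvalidSequenceError,
    apply_pattern,
    code_matches,
    degeneracy,
    mismatch_positions,
    parse_primer_text,
    read_base_matches,
    reference_expansion,
    reverse_complement,
    to_paren_dialect,
    union_consensus,
)

iupac_strings = st.text(alphabet=sorted(IUPAC_SETS), min_size=1, max_size=25)
concrete_strings = st.text(alphabet="ACGT", min_size=1, max_size=25)


@pytest.mark.parametrize("code,base,expected", [
    ("Y", "T", True), ("Y", "C", True), ("Y", "A", False),
    ("G", "A", False), ("G", "G", True),
    ("N", "G", True), ("R", "G", True), ("R", "C", False),
])
def test_code_matches(code, base, expected):
    assert code_matches(code, base) is expected


def test_code_matches_rejects_invalid_input():
    with pytest.raises(InvalidSequenceError):
        code_matches("X", "A")
    with pytest.raises(InvalidSequenceError):
        code_matches("A", "N")  # second argument must be concrete


def test_ambiguous_read_base_subset_rule():
    # Y-read vs N-primer: {C,T} <= {A,C,G,T} -> match
    assert read_base_matches("N", "Y")
    # N-read vs Y-primer: {A,C,G,T} !<= {C,T} -> mismatch
    assert not read_base_matches("Y", "N")


@pytest.mark.parametrize("seq,expected", [
    ("TTCCGGTTGATCCTGCCGGA", 1),        # Arch21F: no degenerate codes
    ("AGAGTTTGATYMTGGCTCAG", 4),        # 8F: 2 x 2
    ("GSVYACTGCTATCGGMTT", 24),         # 26ABF: 2 x 3 x 2 x 2
])
def test_degeneracy_equals_enumerated_expansion_count(seq, expected):
    ds = DegenerateSequence(seq)
    expansions = list(ds.expansions())
    assert degeneracy(ds) == expected
    assert len(expansions) == len(set(expansions)) == expected


def test_mismatch_positions_identity_and_published_patterns():
    arch21f = PRIMERS["Arch21F"]
    assert mismatch_positions(arch21f, "TTCCGGTTGATCCTGCCGGA") == []
    # the 5-mismatch site variant of the Type A evader group
    assert mismatch_positions(arch21f, "CTCTAGTTGATCCTGCTAGA") == [1, 4, 5, 17, 18]


def test_type_b_site_carries_three_mismatches_against_legacy_4f():
    site_b = apply_pattern(PRIMERS["Arch21F"], "=====T=C=======A====")
    # 4F is 18 nt, aligned to the inner positions 2..19 of the 20-nt site
    assert len(mismatch_positions(PRIMERS["4F"], site_b[1:19])) == 3


def test_mismatch_positions_requires_complete_site():
    with pytest.raises(ValueError, match="complete binding site"):
        mismatch_positions(PRIMERS["Arch21F"], "TTCC")


def test_reverse_complement_of_degenerate_reverse_primer():
    rc = reverse_complement(PRIMERS["1492R"])
    assert rc.bases == "AAGTCRTAACAAGGTAACC"
    # per-code complement checked by full expansion enumeration
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    def rc_concrete(s):
        return "".join(comp[b] for b in reversed(s))
    assert set(rc.expansions()) == {
        rc_concrete(x) for x in PRIMERS["1492R"].expansions()
    }


def test_reverse_complement_palindrome():
    assert reverse_complement("ACGT").bases == "ACGT"


@settings(max_examples=100, derandomize=True)
@given(iupac_strings)
def test_reverse_complement_is_involution(s):
    assert reverse_complement(reverse_complement(s)).bases == \
        DegenerateSequence(s).bases


@settings(max_examples=100, derandomize=True)
@given(concrete_strings, concrete_strings)
def test_mismatch_count_symmetric_under_joint_reverse_complement(p, s):
    n = min(len(p), len(s))
    p, s = p[:n], s[:n]
    fwd = mismatch_positions(p, s)
    rev = mismatch_positions(reverse_complement(p),
                             reverse_complement(s).bases)
    assert len(fwd) == len(rev)


def test_union_consensus_trivials():
    assert union_consensus(["ACGT", "ACGT"]).bases == "ACGT"
    assert union_consensus(["AAAA", "GAAA"]).bases[0] == "R"
    with pytest.raises(ValueError):
        union_consensus([])
    with pytest.raises(ValueError):
        union_consensus(["AC", "ACG"])


def test_union_of_group_binding_sites_reproduces_published_degenerate_primer():
    """The two evader groups' target windows union into 26ABF exactly."""
    type_a_sites = list(PRIMERS["26AF"].expansions())   # A-group variants
    type_b_sites = ["GCCTACTGCTATCGGATT"]               # B-group window
    merged = union_consensus(type_a_sites + type_b_sites)
    assert merged.bases == PRIMERS["26ABF"].bases == "GSVYACTGCTATCGGMTT"
    # every per-position union verified by brute force
    for i, code in enumerate(merged.bases):
        observed = {s[i] for s in type_a_sites + type_b_sites}
        assert set(IUPAC_SETS[code]) == observed, f"position {i + 1}"


@pytest.mark.parametrize("seq", ["AGAGTTTGATYMTGGCTCAG", "GSVYACTGCTATCGGMTT"])
def test_union_consensus_round_trips_full_expansion_set(seq):
    ds = DegenerateSequence(seq)
    assert union_consensus(list(ds.expansions())).bases == ds.bases


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.text(alphabet="ACGT", min_size=8, max_size=8),
                min_size=1, max_size=6))
def test_every_member_matches_its_union_consensus(sites):
    consensus = union_consensus(sites)
    for s in sites:
        assert mismatch_positions(consensus, s) == []


@pytest.mark.parametrize("name", ["8F", "Arch21F", "26ABF", "1492R"])
def test_primer_expansions_never_mismatch_their_own_primer(name):
    primer = PRIMERS[name]
    assert primer.degeneracy <= 64
    for s in primer.expansions():
        assert mismatch_positions(primer, s) == []


def test_parenthetical_dialect_round_trip():
    assert parse_primer_text("AGAGTTTGAT(C/T)(A/C)TGGCTCAG") == \
        "AGAGTTTGATYMTGGCTCAG"
    assert parse_primer_text("5'-GGTTACCTTGTTA(C/T)GACTT-3'") == \
        "GGTTACCTTGTTAYGACTT"
    spelled = to_paren_dialect("GSVYACTGCTATCGGMTT")
    assert spelled == "G(C/G)(A/C/G)(C/T)ACTGCTATCGG(A/C)TT"
    assert parse_primer_text(spelled) == "GSVYACTGCTATCGGMTT"


def test_rna_and_case_normalization():
    assert DegenerateSequence("uucc ggu".replace(" ", "")).bases == "TTCCGGT"
    assert parse_primer_text("agaguuugau(c/u)(a/c)uggcucag") == \
        "AGAGTTTGATYMTGGCTCAG"


def test_invalid_character_error_names_position():
    with pytest.raises(InvalidSequenceError, match="position 3"):
        DegenerateSequence("ACXGT")


def test_apply_pattern_reconstructs_targeted_primer():
    """The 5-mismatch evader pattern applied to Arch21F is exactly 21AF."""
    site = apply_pattern(PRIMERS["Arch21F"], "C==TA===========TA==")
    assert site == PRIMERS["21AF"].bases == "CTCTAGTTGATCCTGCTAGA"


def test_reference_expansion_is_smallest():
    assert reference_expansion("AGAGTTTGATYMTGGCTCAG") == \
        "AGAGTTTGATCATGGCTCAG"
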