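"""Tm models, candidate enumeration, specificity, merging, coverage."""

import math

import numpy as np
import pytest

from ssumine.catalog import PRIMERS
from ssumine.design import (
    coverage,
    enumerate_candidates,
    melting_temperature,
    merge_degenerate,
    specificity_check,
    tm_range_of,
)
from ssumine.iupac import DegenerateSequence, apply_pattern

SITE_A = apply_pattern(PRIMERS["Arch21F"], "C==TA===========TA==")
SITE_B = apply_pattern(PRIMERS["Arch21F"], "=====T=C=======A====")


def nn_tm_oracle(seq):
    """Independent nearest-neighbor Tm: unified duplex parameters
    (dH kcal/mol, dS cal/mol/K), 0.368*(N-1)*ln[Na+] entropy salt term,
    25 nM per strand (non-self-complementary: CT/4)."""
    nn = {
        "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    def pair(p):
        if p in nn:
            return nn[p]
        return nn[comp[p[1]] + comp[p[0]]]
    dh, ds = 0.2, -5.7  # initiation
    dh += 2.2 if seq[0] in "AT" else 0.0
    ds += 6.9 if seq[0] in "AT" else 0.0
    dh += 2.2 if seq[-1] in "AT" else 0.0
    ds += 6.9 if seq[-1] in "AT" else 0.0
    for i in range(len(seq) - 1):
        h, s = pair(seq[i:i + 2])
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(0.05)
    ct = 25e-9 + 25e-9
    return dh * 1000 / (ds + 1.987 * math.log(ct / 4)) - 273.15


def test_wallace_rule_closed_form():
    assert melting_temperature("ATCGATCGATCGATCG") == 48  # 2*8 + 4*8
    assert melting_temperature("A" * 16) < melting_temperature("G" * 16)


def test_nn_mode_matches_independent_reference_parameters():
    for seq in ("ATCGATCGATCGATCG", "CTCTAGTTGATCCTGCTAGA",
                "GGACACTGCTATCGGCTT"):
        assert melting_temperature(seq, "nn") == pytest.approx(
            nn_tm_oracle(seq), abs=0.5)


def test_tm_rejects_degenerate_and_out_of_range_input():
    with pytest.raises(ValueError, match="expand"):
        melting_temperature("ACGTACGTACGTACGR")
    with pytest.raises(ValueError):
        melting_temperature("ACGT")


def test_targeted_primer_enumerated_from_its_group_consensus():
    """A consensus starting with the 21AF 20-mer yields 21AF as a candidate.

    Under nearest-neighbor Tm the published primer sits inside the
    45-52 degC design window (the Wallace rule overestimates short-oligo Tm
    and would place it above the window).
    """
    rng = np.random.default_rng(2)
    tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=80)])
    consensus = DegenerateSequence(PRIMERS["21AF"].bases + tail)
    cands = enumerate_candidates(consensus, target_group="A", tm_method="nn")
    assert any(c.sequence.bases == PRIMERS["21AF"].bases and c.start == 0
               for c in cands)


def test_low_complexity_consensus_yields_no_candidates():
    # Wallace Tm of any A-only oligo <= 20 nt is <= 40 degC, below the window
    assert enumerate_candidates(DegenerateSequence("A" * 100)) == []


def test_window_shorter_than_min_length_is_an_error():
    with pytest.raises(ValueError, match="window"):
        enumerate_candidates(DegenerateSequence("ACGTACGTACGT"), window=12)


def test_enumeration_is_exhaustive_against_brute_force():
    rng = np.random.default_rng(9)
    consensus = DegenerateSequence(
        "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100)]))
    cands = {(c.start, c.length) for c in enumerate_candidates(consensus)}
    brute = set()
    for length in range(16, 21):
        for start in range(0, 100 - length + 1):
            sub = consensus.bases[start:start + length]
            tm = melting_temperature(sub)
            if 45 <= tm <= 52:
                brute.add((start, length))
    assert cands == brute


def test_all_expansions_must_pass_the_tm_gate():
    # R-position expansions straddle the window edge -> candidate rejected
    seq = DegenerateSequence("GGGGGGGGRAAAAAAA")  # Tm in {48, 50}: both ok
    tmin, tmax = tm_range_of(seq)
    cand_ok = enumerate_candidates(DegenerateSequence(seq.bases + "A" * 84))
    assert 45 <= tmin <= tmax <= 52
    assert any(c.start == 0 and c.length == 16 for c in cand_ok)
    seq_bad = DegenerateSequence("GGGGGGGGGGRAAAAA")  # Tm in {52, 54}: 54 leaks
    cand_bad = enumerate_candidates(DegenerateSequence(seq_bad.bases + "A" * 84))
    assert not any(c.start == 0 and c.length == 16 for c in cand_bad)


def test_specificity_counts_planted_target_sites():
    rng = np.random.default_rng(4)
    cand = DegenerateSequence("GGACACTGCTATCGGCTT", name="26AF-like")
    refs = []
    for i in range(7):
        pad = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=120)])
        refs.append((f"t{i}", pad[:40] + cand.bases + pad[40:], True))
    for i in range(5):
        refs.append((f"n{i}",
                     "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=160)]),
                     False))
    assert specificity_check(cand, refs, max_mismatches=0) == (7, 0)


def test_candidate_hits_its_own_source_consensus():
    cand = DegenerateSequence(SITE_B[:18])
    on, off = specificity_check(cand, [("self", SITE_B + "ACGT" * 30, True)])
    assert on >= 1 and off == 0


def test_cross_reactive_sites_show_up_as_off_target_hits():
    """A candidate from a conserved block hits non-targets; a candidate from
    the group-private region does not (the qualitative published outcome)."""
    rng = np.random.default_rng(8)
    conserved = "GCATTCGACGGTACGATCGA"
    private = "TTGACCGGATTCAACGGTAT"
    target = ("t0", conserved + private + "ACGT" * 20, True)
    nontargets = [
        (f"n{i}",
         conserved + "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100)]),
         False)
        for i in range(6)
    ]
    refs = [target] + nontargets
    conserved_cand = DegenerateSequence(conserved[:18])
    private_cand = DegenerateSequence(private[:18])
    assert specificity_check(conserved_cand, refs) == (1, 6)
    assert specificity_check(private_cand, refs) == (1, 0)


def test_three_prime_anchor_enforced_when_mismatches_allowed():
    cand = DegenerateSequence("GGACACTGCTATCGGCTT")
    # mismatch in the middle: tolerated at max_mismatches=1
    mid = "GGACACTGATATCGGCTT"
    # mismatch at the 3'-terminal base: never tolerated
    tail = "GGACACTGCTATCGGCTA"
    refs = [("mid", "AAAA" + mid + "GGGG", True),
            ("tail", "AAAA" + tail + "GGGG", True)]
    assert specificity_check(cand, refs, max_mismatches=1) == (1, 0)


def test_merge_trivials():
    same = merge_degenerate({"g": ["ACGTACGTACGTACGT", "ACGTACGTACGTACGT"]})
    assert same.bases == "ACGTACGTACGTACGT" and same.degeneracy == 1
    merged = merge_degenerate({"g1": ["AAGTACGTACGTACGT"],
                               "g2": ["AGGTACGTACGTACGT"]})
    assert merged.bases[1] == "R"


def test_merge_reproduces_published_degenerate_primer():
    groups = {"A": list(PRIMERS["26AF"].expansions()),
              "B": ["GCCTACTGCTATCGGATT"]}
    merged = merge_degenerate(groups, name="26ABF")
    assert merged.bases == PRIMERS["26ABF"].bases
    assert merged.degeneracy == 24 == len(set(merged.expansions()))
    # defining property: the merged primer covers every input site exactly
    all_sites = [s for sites in groups.values() for s in sites]
    report = coverage(merged, [(f"s{i}", s) for i, s in enumerate(all_sites)])
    assert (report["mismatch_count"] == 0).all()


def test_merge_registers_offset_group_windows():
    """A 17-nt group window offset by one base is registered, and the merge
    over the common window reproduces the inner degenerate positions."""
    groups = {"A": list(PRIMERS["26AF"].expansions()),
              "B": [PRIMERS["27BF"].bases]}
    merged = merge_degenerate(groups)
    assert merged.bases == PRIMERS["26ABF"].bases[1:] == "SVYACTGCTATCGGMTT"


def test_merge_degeneracy_cap_reports_offending_positions():
    with pytest.raises(ValueError, match="degenerate positions"):
        merge_degenerate({"a": ["AAAAAAAAAAAAAAAA"],
                          "b": ["CCCCCCCCCCCCCCCC"]}, degeneracy_cap=32)


@pytest.mark.parametrize("primer_name,site,expected", [
    ("4F", SITE_B, 3),       # legacy archaeal primer vs the B-group site
    ("Arch21F", SITE_A, 5),  # universal primer vs the A-group site
])
def test_coverage_of_published_sites(primer_name, site, expected):
    report = coverage(PRIMERS[primer_name], [("s", site)])
    assert report.loc[0, "mismatch_count"] == expected
    assert report.loc[0, "call"] == "mismatching"


def test_primer_covers_its_own_expansion_set():
    primer = PRIMERS["26ABF"]
    report = coverage(primer, [(f"e{i}", s + "ACGTACGT")
                               for i, s in enumerate(primer.expansions())])
    assert (report["mismatch_count"] == 0).all()
    assert (report["call"] == "matching").all()


def test_coverage_flags_too_short_sequences():
    report = coverage(PRIMERS["Arch21F"], [("short", "ACGTACGT")])
    assert report.loc[0, "call"] == "incomplete"
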