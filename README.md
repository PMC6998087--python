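# ssumine

Universal 16S rRNA primers are not universal: lineages whose primer-binding
sites diverge from the consensus are invisible to standard amplicon surveys,
and the rarest of them — the "rare biosphere", below ~0.01% relative
abundance — are exactly the groups most likely to be missed. Meta-
transcriptomic libraries built by ligating an adaptor to the 5′ terminus of
the SSU rRNA yield reads whose 5′ ends are biologically intact, so the
binding sites of universal *forward* primers (8F for Bacteria, Arch21F for
Archaea) can be read off directly and evaluated in silico.

`ssumine` implements that data-mining pipeline for microbial ecologists:

1. **Primer evaluation** — for each 5′-anchored read, extract the binding
   site of the universal primer assigned to its domain call and classify it:
   *incomplete* (read too short to cover the site), *matching* (0 mismatches,
   or 1 mismatch outside the last four 3′ positions), or *mismatching*
   (≥ 2 mismatches, or a single mismatch within the 3′-terminal four
   positions, which abolishes extension in practice). Each mismatching site
   gets a pattern string (`=` for agreement, the read base otherwise), e.g.
   `C==TA===========TA==`.
2. **OTU screening** — greedy centroid clustering at 85% identity, then a
   screen for candidate novel groups: OTU size ≥ 10 reads, taxonomy
   unclassified at the domain and/or phylum level, and every member carrying
   a complete binding site with ≥ 3 mismatches.
3. **Primer design** — exhaustive enumeration of targeted forward primers in
   the first 100 nt of a group consensus (16–20 nt, Tm 45–52 °C, every
   expansion of a degenerate candidate inside the window), specificity
   scoring against references with a strict 3′ anchor, and merging of
   several groups' sites into one degenerate primer by per-position IUPAC
   union after mismatch-minimizing registration.
4. **Novelty assessment** — uncorrected pairwise distances on aligned
   near-full-length sequences (> 1200 bp; gap runs count once, shared and
   terminal gaps ignored), per-group distance summaries, 97% full-length
   OTU clustering, and the candidate-phylum call: a group is a candidate
   phylum when its minimum distance to every named phylum exceeds
   1 − 0.75 = 0.25.
5. **Synthetic data** — a seeded generator that plants evader groups with
   exact mismatch patterns at rare-biosphere abundances inside a large
   classified background, with a ground-truth manifest for every read.

## Worked example

```python
from ssumine import PRIMERS, apply_pattern, evaluate_read, AnchoredRead
from ssumine.design import coverage, merge_degenerate

arch21f = PRIMERS["Arch21F"]          # TTCCGGTTGATCCTGCCGGA

# Rebuild the binding site of an archaeal evader group from its pattern:
site = apply_pattern(arch21f, "C==TA===========TA==")
print(site)                            # CTCTAGTTGATCCTGCTAGA  (== primer 21AF)

ev = evaluate_read(AnchoredRead("r1", site + "A" * 200), arch21f)
print(ev.mismatch_count, ev.status)    # 5 mismatching

# Merge the two evader groups' target windows into one degenerate primer:
merged = merge_degenerate({
    "A": ["GGACACTGCTATCGGCTT", "GGGCACTGCTATCGGCTT"],
    "B": ["GCCTACTGCTATCGGATT"],
})
print(merged.bases, merged.degeneracy) # GSVYACTGCTATCGGMTT 24
print(coverage(merged, [("b", "GCCTACTGCTATCGGATT")]).mismatch_count[0])  # 0
```

The five-mismatch site is itself the targeted primer for that group; the
merged 18-mer covers every site of both groups with zero mismatches while
expanding to only 24 concrete oligos.

From the shell, the same pipeline runs end to end on simulated data:

```bash
ssumine simulate --seed 7 --out-dir sim
ssumine pipeline --reads sim/reads.fasta --taxonomy sim/taxonomy.tsv --out-dir out
# -> 32 OTUs, 2 novel, ... primer candidates -> out
```

`out/screened.tsv` lists the recovered evader OTUs with their dominant
mismatch patterns and read support; `out/candidates.tsv` holds designed
primers sorted by off-target hits.

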