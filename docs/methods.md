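# Methods

## Problem setting

Meta-transcriptomic SSU rRNA libraries built by 5′-adaptor ligation yield
reads that start at the biological 5′ terminus of the molecule. The binding
site of a universal forward primer therefore sits at the read start and can
be compared to the primer base by base — no PCR, no amplification bias.
`ssumine` exploits this to find lineages that universal primers would miss,
to design primers that target them, and to judge whether the recovered
full-length sequences constitute new phylum-level diversity.

## Degenerate-nucleotide algebra

Every operation reduces to set algebra over IUPAC ambiguity codes: a code
matches a concrete base iff the base lies in the code's expansion set;
degeneracy is the product of per-position set sizes; the reverse complement
complements each code's set (R↔Y, K↔M, B↔V, D↔H; S, W, N are their own
complements); the union consensus of aligned sites is, per position, the
minimal code whose set equals the union of observed bases. Ambiguous bases
in *reads* are handled conservatively: a read base matches a primer code
only when the read base's expansion set is a subset of the code's set, so
ambiguity can never manufacture agreement. All input is uppercased and
RNA `U` is normalized to `T`. Primer files may use either IUPAC codes or
the parenthetical table dialect `(C/T)`; both are normalized on ingest.

## Read classification

For each read, the primer assigned to its domain call (8F for Bacteria,
Arch21F for Archaea and domain-unclassified reads) is placed at the 5′
terminus. `max_offset` (default 0, capped at 5) allows a scan over a few
leading offsets for residual adaptor bases; the placement with the fewest
mismatches wins, ties going to the smallest offset, so enlarging the budget
can never worsen the count. A read shorter than the site is *incomplete*.
A site with more than 10% ambiguous bases (configurable) is *unevaluable*
rather than silently dropped. Otherwise the 3′-weighted rule applies: 0
mismatches, or exactly 1 outside the last four primer positions (L−3..L,
1-based) → *matching*; anything else → *mismatching*. The last-four rule
encodes the empirical fact that a 3′-terminal mismatch blocks polymerase
extension. Patterns record the read base at mismatched positions and `=`
elsewhere; at degenerate primer positions a consistent read base prints `=`.
Applying a pattern back to the primer's canonical (lexicographically
smallest) expansion reconstructs the site exactly at all non-degenerate
positions — which is how the targeted primer for a five-mismatch archaeal
evader group equals that group's reconstructed binding site.

## OTU clustering and screening

Clustering is greedy centroid assignment over length-sorted input: each
sequence joins the first centroid (in founding order) whose identity
reaches the cutoff (0.85 for reads, 0.97 for full-length), else founds a
new centroid; the procedure is deterministic and partitions the input.
Identity is computed with edlib edit-distance alignment. The default
definition is one-way: the shorter sequence aligned end-gap-free inside the
longer, identity = 1 − d/len(shorter) — the natural convention when
5′-anchored fragments of very different lengths come from one molecule. A
two-way global definition (1 − d/len(longer)) is available via
`identity_mode`. Reference sequences may be co-clustered but never count
toward OTU size: the size criterion means read support.

Screening keeps OTUs with (i) ≥ 10 reads, (ii) a consensus lineage
unclassified at the domain and/or phylum level (value missing or matching
/unclassified|unknown|uncultured/i; positional SILVA-style ranks), and
(iii) every member complete and ≥ 3 mismatches against its universal
primer. Consensus taxonomy takes the modal value per rank, and the dominant
pattern is the modal pattern with lexicographic tie-break. Relaxing any
single criterion can only grow the passing set (tested property).

## Primer design

Candidates are all substrings of the target-group consensus within the
first 100 nt, length 16–20 nt, whose melting temperature lies in 45–52 °C.
Two Tm models are provided. The default is the Wallace rule
2(A+T) + 4(G+C) — transparent and hand-checkable, adequate as a coarse
gate. The `nn` mode uses nearest-neighbor thermodynamics (Biopython's
unified parameters) at 50 mM monovalent salt and 25 nM per strand; these
concentrations were chosen so that the published targeted primers (e.g. the
20-mer evader-site primer at 47.2 °C) fall inside the 45–52 °C window —
the Wallace rule overestimates short-oligo Tm by several degrees, so under
Wallace the same window effectively selects slightly GC-poorer candidates.
Degenerate candidates are gated strictly: *every* expansion must sit inside
the window, guaranteeing all covered variants are amplifiable; the
degeneracy cap defaults to 32 (the merged two-group primer's 24 passes).
Enumeration is exhaustive over (start, length), verified against brute
force in the tests.

Specificity counts reference sequences containing a site for the candidate
on the forward strand; with 0 allowed mismatches (default) the search is a
character-class regex, and when mismatches are allowed the four 3′-terminal
positions must still match exactly. Candidates are ranked by off-target
hits, then max Tm.

Merging several groups into one degenerate primer first registers each
group's consensus window against the first group's at the offset minimizing
disjoint-set positions (the registration is *computed*, not assumed), crops
to the common window, and unions all sites per position; the result
provably covers every input site with zero mismatches. Reverse primers are
treated as user-supplied and validated only via reverse-complement
coverage; the package does not design them.

## Distances and the candidate-phylum call

Uncorrected distance = differences / compared columns on an existing
alignment, with the conventions standard in 16S distance work: columns
gapped in both sequences are skipped; a run of consecutive columns gapped
in one sequence counts as a single difference (one indel event; switchable
to per-column counting); terminal overhangs are ignored (switchable). An
optional column filter drops columns gapped in > 50% of rows. Full-length
clustering first removes sequences with ungapped length ≤ 1200 bp (strict).
Group summaries report min/mean/max and pair counts for every intra and
inter pair of labels; singleton groups report an undefined intra summary
rather than zero. The candidate-phylum call uses the proposed 75%
phylum-level identity boundary: a group qualifies against a named phylum
when the *minimum* inter-group distance strictly exceeds 0.25.

## Synthetic data

`build_templates` draws one random ancestor and mutates an independent copy
per group at the rate that produces the requested expected between-group
identity (matching probability (1−r)² + r²/3; infeasible below the random
floor of 0.25), then writes the universal forward-primer site verbatim at
the 5′ terminus and the 1492R site at the 3′ end — emulating conserved
primer loci flanking variable regions. `plant_and_fragment` cuts
5′-anchored reads with Normal(250, 30) lengths clipped to [130, 300] and
plants evader groups from `PlantSpec`s: the group's site is replaced by the
pattern-reconstructed variant, its taxonomy by the spec's (typically
phylum-unclassified) lineage. The defaults are the study regime the
package is built around: two archaeal evader groups at 12 and 25 reads —
carrying the five- and three-mismatch site variants — in a 50,000-read,
30-group classified background with 98% complete 5′ ends.

Simplifications to note. An evaluator anchored at the read 5′ end can
recognize an incomplete binding site only by read length, so simulated
5′-truncated reads are cut below primer length; real incompleteness (reads
starting mid-gene at full length) is not representable without an rRNA
alignment model, which is out of scope. Sequencing error is off by default;
when enabled, substitutions are injected *before* the planted site is
rewritten, so manifests remain exact. Templates evolve by substitution
only (no indels), which is also what keeps the aligned distance-analysis
generator trivially gap-free. Passing tests therefore demonstrate the
pipeline's bookkeeping and decision rules under clean conditions, not
robustness to chimeras, indels, or platform-specific error profiles.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery experiment at
50,000 background reads per seed (10 seeds in the suite), the evader-panel
screen at 287 reads, and the distance oracle at 1,000 random aligned pairs
— sizes chosen so the whole suite completes in about two minutes on one
CPU while still exercising the rare-group regime (planted groups at
~1/2,000 relative abundance). Distance comparisons in tests are exact;
Tm cross-checks allow 0.5 °C against an independently coded
nearest-neighbor oracle. All randomness flows from explicit seeds through
`numpy.random.default_rng`; equal seeds give byte-identical outputs
(tested). Boundary conventions: the candidate-phylum inequality is strict
(min distance exactly 0.25 fails); the >1200 bp filter is strict; "last
four nucleotides" means primer positions L−3..L inclusive.

## Known limitations

- The greedy clustering reproduces the centroid contract, not the k-mer
  heuristics of any particular external clustering binary; absolute OTU
  counts on real data will differ from tools with different acceptance
  orders.
- Tm models ignore mismatch and dangling-end corrections; no primer-dimer,
  hairpin, or amplicon simulation is attempted.
- Taxonomy handling is positional (domain; phylum; ...) with a regex
  notion of "unclassified"; rank-annotated lineages are not parsed.
- The distance module consumes pre-aligned FASTA; it does not align.
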