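# Methods

This note documents the models, numerical choices and limitations
behind orthoprimer, in the order the pipeline runs.

## Sequence model and coordinates

All coordinates are 0-based, half-open; only human-readable reports are
1-based. Residues are uppercased on read and `U` maps to `T` in DNA.
`-` is the gap character and, together with `N` (DNA), `X` (protein)
and quality-masked bases, is treated as missing data by every
statistic: a missing cell contributes no state and no constraint.

## Orthology search

**Similarity.** Pairwise similarity is the exact Smith–Waterman local
alignment score with affine gaps, computed by Biopython's
`PairwiseAligner` (BLOSUM62, gap open −11 / extend −1 for proteins;
+5/−4 with open −12 / extend −2 for DNA). An exact algorithm was chosen
over a heuristic database search deliberately: it is deterministic,
desk-scale fast, and checkable against an independent Gotoh dynamic
programme, which the test suite does on every instance up to 60
residues. The 40 %/156 paralog thresholds are treated as operating on
whatever Z the configured scorer produces.

**Z statistic.** Raw scores are standardised as
`z = (raw − mean) / sd` against scores obtained by re-aligning the
query to `n_shuffles` random permutations of the subject (default 100;
the packaged planted-quartet experiments use 50, which puts the Monte
Carlo error of z well below every decision margin while halving
runtime). Shuffling preserves length and composition, so z measures
order-specific similarity. The per-pair random stream is derived from
(seed, query id, subject id), which makes every hit list invariant
under re-ordering of proteome records. A zero-spread null (e.g. a
homopolymer subject) raises an error rather than returning ±inf.

**Search.** Best hits are ranked by z, ties broken by higher raw score
then lexicographically smaller subject id. A best hit with z below a
floor (default 3.0) is reported as absent so that noise matches cannot
close a boomerang. The triple-boomerang closure accepts a trio when
the chain of best hits p1→p2→p3→p1 returns to its starting gene; the
fourth genome is attached by a plain reciprocal best match anchored on
the third member. The paralog filter is applied to *all* retained legs
(three boomerang legs plus both reciprocal legs of the fourth-genome
check): a leg fails when its second-best z exceeds `ratio × best_z`
(ratio 0.40) or the absolute ceiling `zmax` (156). Whether the original
procedure applied the rule to all five legs is not documented;
all-legs is the stricter, configurable default.

## Window scan and fragment sift

A column counts as "identical in all organisms" only when every row
carries the same unambiguous base — gaps and IUPAC-ambiguous bases
never count, because a primer must bind real bases. The profile is a
length-(L−w+1) vector of per-window counts (w = 20). Separation is
measured as amplicon length, forward-window start to reverse-window
end, since the 350–850 bp operating range describes fragment length.
The original manual sifting step is mechanised as the separation filter
plus a ranking (descending n-level, then combined identity, then
position); nothing interactive remains. Gapped columns inside the
candidate amplicon are not penalised — only the primer windows
themselves are constrained.

## Primer construction

Per window column the observed base set maps to the minimal IUPAC code.
Columns observing 3–4 bases become inosine while the budget (default 2)
lasts, assigned 5′-most first in the primer's own orientation and never
in the 3′-terminal three positions: a universal base at the extension
end impairs priming, and published degenerate primers keep their 3′
ends literal. Anything beyond the inosine budget falls back to the
3/4-fold IUPAC code; more than `max_degenerate` (default 4) non-ACGT
positions is a hard error. Reverse primers are reported 5′→3′ on the
antisense strand (standard primer-table dialect); the complement of
inosine is inosine. Annealing temperatures are carried as metadata
only — no thermodynamic model is attempted.

In-silico PCR scans the forward primer along the sense strand and the
reverse-complement of the reverse primer as a sense-strand pattern. A
site matches when at most `max_mismatch` positions fail IUPAC
compatibility (inosine matches anything; an ambiguous template base is
always a mismatch) and the primer's 3′-terminal `three_prime_exact`
positions (default 3) match with zero tolerance. All compatible site
pairs with product length inside the configured bounds are reported.

## Variability statistics

Parsimony-informative: ≥ 2 states each observed in ≥ 2 rows; columns
with < 2 non-missing cells are constant by convention. The per-column
minimum-change bound is (distinct observed states − 1), floored at 0.
Fitch small parsimony uses unit costs on unordered states; missing
leaves behave as the universal state set. The score is invariant to
where the unrooted topology is rooted, which the tests exercise. CI
excludes columns with a zero bound from both numerator and denominator
(matching the default behaviour of standard parsimony software) and is
defined as 1.0 in the degenerate no-variation case, so CI = 1 holds
exactly when the tree needs no homoplasy.

Exhaustive search enumerates all (2n−5)!! unrooted topologies by leaf
insertion (capped at 9 taxa) and re-scores only parsimony-informative
column patterns: a column in which at most one state occurs more than
once costs its minimum bound on every binary tree, so those columns are
a constant offset. The returned score equals the full Fitch length of
the winners; ties are all reported.

Strain polymorphism counts columns with ≥ 2 distinct trusted non-gap
states; a base is trusted iff its Phred quality is ≥ 40 (expected
error ≤ 10⁻⁴), so quality 40 itself is trusted and 39 is missing.

## Synthetic study conditions

The generators' defaults define the conditions every planted experiment
runs under; they were fixed once, from the scale of the system the
pipeline targets:

* **Proteome quartets** — 20 families of 150-aa proteins (published
  marker fragments run 121–279 aa), pairwise identity 0.70 between
  species (per-branch substitution rate 1 − √0.70 from a random
  ancestor, uniform replacement), 5 families carrying a within-species
  duplicate at similarity 0.95 in species 2. The truth table predicts
  the filter outcome per family.
* **Marker alignments** — 4 species × 800 columns; background columns
  identical with probability 0.40 (divergent coding DNA; at that level
  a random 20-mer window reaches ≥ 18/20 identities with probability
  ~10⁻⁵ per start, so planted windows dominate), planted windows of
  17/20 identity (published primers carry 2–4 degenerate sites,
  i.e. 16–18 conserved bases) at starts 60 and 540, amplicon 500 bp,
  flanked by guard columns forced to vary so windows cannot silently
  extend.
* **Tree-evolved alignments** — Jukes–Cantor-style uniform replacement,
  no indels; the recovery experiment uses 6 taxa, 300 sites and
  substitution probability 0.08 per branch (≈ 24 expected changes per
  internal branch — clearly low-noise but not trivial).
* **Strain panels** — 16 strains in 3 lineages over 600 sites
  (the resequencing panels being emulated span 12–26 strains and
  428–845 sites), 21 lineage-diagnostic planted SNPs (observed range
  7–23), zero within-lineage divergence by default (a config knob adds
  private singletons), and 2 % of bases below Q40.

What the generators do **not** emulate: indels and alignment error,
codon structure and usage bias, rate heterogeneity across sites,
lineage sorting and recombination within species, base-composition
bias, and sequencing error beyond the quality mask. Passing the planted
tests therefore demonstrates the correctness of the machinery —
closure logic, filters, window arithmetic, primer semantics, parsimony
counts — not the field performance of the primers on real genomes.

## Packaged tables and a known discrepancy

The three study tables ship as plain TSV with a sha256 manifest;
`load_study_tables` refuses a corrupted fixture. `check_study_tables`
recomputes 53 quantities. Fifty-two pass. The one failure is internal
to the printed tables: the *PDA1* indicator column sums to 18 newly
sequenced species, and 18 + 18 published genomes = 36, while the gene
table prints 35 (equivalently, the printed per-species counts total
257 and 257 + 250 published sequences = 507, one more than the printed
506). The audit — and the `tablecheck` exit code — reports this
honestly instead of patching either table.

The strain-panel CI observation from the original resequencing data
(CI = 1 for all fragments except one at 0.958) depends on that external
dataset and is not asserted by any test; the packaged panels
demonstrate the CI = 1 case by construction.

## Problem sizes and runtime

The test suite and the acceptance script run the quartet search at 20
families × ~25 genes × 150 aa with 50 shuffles (~10⁵ exact local
alignments, under a minute), 10 marker replicates, 50 topology-recovery
replicates and 15 Fitch-oracle instances; these sizes were chosen as
the smallest at which every planted signal is unambiguous.

## Known limitations

* The Z statistic is shuffle-based, not the library-regression
  statistic of heuristic search tools; absolute z values are not
  comparable across scorers, only the ratio/ceiling logic is.
* No k-mer seeding: the search is quadratic in proteome size and is
  meant for desk-scale experiments, not whole-proteome scans.
* No melting-temperature, GC-clamp, hairpin or dimer screening; primer
  quality beyond the degeneracy budget is out of scope.
* Maximum-likelihood phylogenetics, bootstrap resampling and heuristic
  tree search at realistic taxon counts are out of scope; the
  exhaustive search is a correctness reference, not a search tool.
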