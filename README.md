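# orthoprimer

Discovery of PCR-able protein-coding marker regions across divergent
genomes, for people who need phylogenetic or population-genetic markers
beyond rDNA — e.g. resolving deep nodes among yeasts, or delineating
cryptic species complexes with multiple unlinked loci.

Given a handful of published genomes, the pipeline

1. finds one-to-one ortholog quartets by chained reciprocal best hits:
   a gene in genome 1 is aligned to every gene in genome 2 (exact
   Smith–Waterman local alignment, affine gaps, BLOSUM62), the best hit
   by a shuffle-standardised score *Z* = (S − μ̂)/σ̂ is followed into
   genome 3 and back, and the trio is accepted only when the chain
   returns to the starting gene (a "triple boomerang"), with a fourth
   genome attached by a plain reciprocal best match;
2. guards against recent paralogs: every search leg also records the
   second-best *Z*, and a leg fails when that score exceeds 40 % of the
   best or an absolute ceiling (156);
3. scans each ortholog alignment with a 20-nt sliding window, counting
   columns identical in *all* species, and enumerates window pairs with
   ≥ *n*/20 identities (12 ≤ *n* ≤ 18) whose implied amplicon is a
   PCR-able 350–850 bp;
4. builds one degenerate primer per window — each column's observed
   base set becomes the minimal IUPAC code, three/four-fold sites
   become inosine while a budget lasts (≤ 4 degenerate sites,
   ~2 inosines, none in the 3′-terminal three bases) — and verifies the
   pair by in-silico PCR with a 3′-exact matching rule;
5. characterises marker variability: variable and parsimony-informative
   sites, the per-column minimum-change bound (distinct states − 1),
   the Fitch parsimony length on a tree, the consistency index
   CI = min changes / tree length, exhaustive parsimony search at desk
   scale, and Q40-masked polymorphism counts for low-coverage strain
   panels (bases under Phred 40 are missing data).

The package also ships, as checksummed TSV fixtures, the printed tables
of the yeast marker study this design reproduces (25 species × 14 gene
fragments, per-gene character statistics, and the 28 published
degenerate primers), together with a cross-consistency audit.

A seeded synthetic module generates every test substrate — proteome
quartets with planted orthologs and paralogs, alignments with planted
conserved windows, tree-evolved alignments, and strain panels with
planted SNPs — each with a truth table, so the whole pipeline is tested
end-to-end without downloading any genome.

## Worked example

```sh
python examples/03_marker_scan.py
```

```
alignment: 4 rows x 800 columns
planted windows at 60 and 540 (17/20 and 17/20 identical), amplicon 500 bp
profile maximum: 18/20 identical bases

maximum primer-site separation per conservation level n:
  n=12: 748
  ...
  n=17: 503
  n=18: no qualifying pair

6 candidate pairs at n=17 within 350-850 bp; top 3:
  fwd 60 (17/20)  rev 542 (18/20)  amplicon 502 bp
  ...
```

The scan found the planted conserved windows (start 60 and 540; nearby
starts shifted into the conserved region are equally valid sites) and
reports, per conservation level *n*, how far apart two usable primer
sites can be. `examples/04_primer_design.py` continues the story:

```
forward  5'-AGATTATCATYTKTARAACG-3'  3 degenerate sites, 0 inosines, pool of 8 oligos
reverse  5'-KTCCGCCATAGTACTTCGRK-3'  3 degenerate sites, 0 inosines, pool of 8 oligos
  sp1: single amplicon [60, 560) = 500 bp   (... one per design genome)
published SA-4 = CCGGTIGCGCAICCMARGTT: 4 degenerate sites (2 inosines), expands to 64 concrete oligos
```

The other examples cover the table audit, the ortholog search with
paralog exclusion, parsimony statistics with exhaustive tree search,
and Q40-masked strain polymorphism.

## Command line

`orthoprimer` exposes the same capabilities as subcommands —
`tablecheck`, `orthofind`, `markerscan`, `primerbuild`, `ispcr`,
`alnstats`, `simulate` — with flags > TOML config > built-in defaults,
deterministic outputs for a fixed seed, and exit codes 0 (success) /
1 (validation failure, including failed table checks) / 2 (internal
error). A planted end-to-end run:

```sh
orthoprimer simulate marker --seed 13 --out sim/
orthoprimer markerscan --alignment sim/marker_alignment.fasta --nmin 17 --out cands.tsv
orthoprimer primerbuild --alignment sim/marker_alignment.fasta \
    --fwd-start 60 --rev-start 540 --out primers.tsv
orthoprimer ispcr --primers primers.tsv --templates templates.fasta --out amps.tsv
```

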