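# tagscout

Targeted identification of genomic regions from paired short-read "genome
tags" — without whole-genome assembly.

Many crop and other non-model genomes are large, complex, or polyploid, and
assembling them is costly; yet identifying a gene of interest and its
promoter needs only modest read coverage. `tagscout` searches a paired
short-read library (Illumina-style, FR orientation, approximately known
insert size) for reads that share identity with a query sequence of up to
5,000 bp. Because reads come in pairs, a fragment whose coding-side mate
aligns localizes its partner even when that partner — say, a diverged
promoter tag — matches nothing: pair geometry confines it to a bounded
*placement envelope* on the extended query axis. Tags selected this way,
direct hits and placed "no match" mates alike, feed a planner that pairs
forward/reverse tags into overlapping PCR amplicons covering a gene and
its flanking regions in the target genome.

## Method

- **Alignment** — each read (both strands) is aligned to the query with a
  k-mer-seeded, gap-free X-drop extension (the greedy MEGABLAST recipe
  restricted to ungapped hits): exact k-mer seeds (default k = 12) from a
  query index are extended left and right, stopping when the running score
  drops more than X (default 10) below the running best, with scores
  +1/−2 per match/mismatch. Hits pass at ≥ 20 aligned columns and ≥ 80%
  identity. A brute-force optimal gap-free aligner (max-subarray over
  every diagonal, both strands) serves as the test oracle.
- **Pair geometry** — per fragment, the best hit per mate is kept. With
  both mates hit, the pair is concordant iff strands oppose, the plus
  mate lies left, and the implied outer fragment length L (5′ end to 5′
  end via full-read projection) satisfies L_min ≤ L ≤ L_max. With one
  mate hit on '+' projected to [s,e), the missing mate (length r) lies on
  '−' within the envelope [s+L_min−r, s+L_max); a '−' anchor mirrors to
  [e−L_max, e−L_min+r) on '+'. Envelope width is always
  (L_max−L_min)+r. The insert model can be supplied or re-estimated
  robustly (median / scaled MAD) from concordant pairs.
- **Amplicon planning** — forward (+) and reverse (−) tag candidates near
  a target interval are paired greedily into the fewest products (≤
  max_product, pairwise overlap ≥ min_overlap) tiling the target. Product
  size is 5′ end to 5′ end; an extrapolated tag widens the product range
  by exactly its envelope width.
- **Simulation** — a region-wise divergence model (per-base substitution
  at 1 − target identity; defaults 41% upstream / 86% coding / 60%
  downstream identity) and an FR read simulator (truncated-normal outer
  length, per-base errors) generate libraries with full ground truth.

## Worked example

```
$ python examples/01_search_tags.py
library: ortholog_library
read pairs (both mates hit):   87
single reads (one mate hit):   401
total hits:                    575
coding-region enrichment:      98.6%
```

A 30× 2×75 paired library simulated from a 20-kb genome carrying a
diverged ortholog of the 4.5-kb query: 87 fragments have both mates
aligning, 401 have exactly one (disjoint counts; total hits =
2·87 + 401). Nearly all hit midpoints fall in the conserved coding
interval — the diverged flanks are reached by mate placement instead:

```
$ python examples/02_mate_placement.py
single-end fragments with the missing mate placed upstream of the
coding region: 138
  sim000051: anchor - hit at [1003,1067) -> mate on '+' within [-81,294)
  ...
$ python examples/03_amplicon_planning.py
plan 1: fwd sim003187 (extrapolated, 5' in (-7, 368)) x rev sim002318 ... -> product 2248-2998 bp
plan 2: fwd sim003822 (direct_hit, 5' in (2106, 2106)) x rev sim001989 ... -> product 2622-2997 bp  [overlaps previous]
```

Two overlapping ≤ 3-kb products tile the gene plus flanks; the 5′-most
plan is anchored by a placed no-match tag — the route into promoters.

## Command line

```
tagscout search query.fasta reads_1.fastq reads_2.fastq --out results/
tagscout plan results/ --target 0:4500 --max-product 3000 --min-overlap 100
tagscout simulate --scenario wd40 --seed 42 --out fixture/
```

Exit codes: 0 success (zero hits included — absence of an ortholog is a
result, not an error), 2 validation error, 3 infeasible tiling, 1 crash.
Outputs: `hits.bed` (BED6 direct hits), `placements.tsv` (signed
extended-axis envelopes), `report.tsv` (per-library tally), `coverage.tsv`,
`map.txt` (ASCII pile-up), `tags.fasta` (primer substrates), `params.log`.

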