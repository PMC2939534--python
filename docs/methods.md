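# Methods

## Problem setting

Given a nucleotide query of at most 5,000 bp and a library of paired short
reads from a target genome (typically a related species without an
assembly), the task is threefold: find the reads ("tags") sharing
significant identity with the query; use pair geometry to place the
partners of one-sided matches, including partners falling outside the
query; and select tag pairs that can serve as PCR primer substrates to
amplify the orthologous region and its flanks in the target genome.

## Alignment model

The search is seed-and-extend, gap-free. A hash index maps every A/C/G/T
k-mer of the query to its occurrence positions (k-mers containing N are
excluded). For each read, both the read and its reverse complement are
scanned; seeds sharing a diagonal are merged (one extension per diagonal),
and each seed is extended left and right greedily, stopping a direction
when the running score falls more than `xdrop` below that direction's
best; the reported hit is the maximal-scoring gap-free segment through the
seed. Scoring is +1 match / −2 mismatch; N never matches anything.

Defaults: k = 12, xdrop = 10, minimum aligned length 20, minimum identity
0.80, query cap 5,000 bp. The seed length targets cross-species capture at
~86% coding identity — a 75-nt read at that identity contains an exact
12-mer with high probability (roughly 4 in 5 reads), while two unrelated
sequences of these sizes essentially never share one. The identity and
length floors are the transparent analog of a significance threshold: with
a ≤ 5-kb query and a finite library, E-values add nothing that a plain
identity/length filter does not, so none are computed. Equal-scoring hits
order by (score desc, q_start asc, '+' before '−'); all outputs are
byte-deterministic.

Gap-free only: short reads rarely span an indel *and* retain a seedable
conserved block, and a gapped extension would complicate exact score
recomputation for little capture gain. Reads crossing indels are simply
lost to the tally, which the simulator can quantify via its indel switch.

The brute-force reference (`gapfree_local_oracle`) computes the true
optimal gap-free local score by maximum-subarray over every diagonal of
both strands. It is quadratic, used only at test scale, and is the
independent standard the heuristic is compared against: the heuristic can
never exceed it, and attains it whenever a clean seed exists.

## Pair geometry

Libraries are FR ("innie"): mate 1 reads the fragment's left end on the
forward strand, mate 2 its right end on the reverse strand. The *outer
fragment length* L (5′ end to 5′ end, both reads inclusive) is modelled by
(mean, sd) with hard bounds [L_min, L_max]; defaults 1000 ± 50, bounds
[850, 1150].

All geometry uses each hit's *projected* full-read interval — the
alignment extended to the read's ends along its diagonal — so a partially
aligned cross-species tag is positioned by its whole read, under the
assumption that the unaligned flanks are collinear (no indel within the
read). A both-mapped pair is concordant iff strands oppose, the plus mate
lies left of the minus mate, and the implied L is within bounds.

For a fragment with exactly one mapped mate, the missing mate of length r
is confined to an envelope on the extended query axis:

- '+' anchor projected to [s, e): mate on '−' within [s+L_min−r, s+L_max)
- '−' anchor projected to [s, e): mate on '+' within [e−L_max, e−L_min+r)

The envelope is the union of feasible mate intervals, hence always exactly
(L_max−L_min)+r wide. Coordinates are signed: envelopes extending 5′ of
the query (negative) or 3′ past its end are the promoter/flank-capture
case and are first-class in `placements.tsv` and downstream planning (BED
cannot carry negative coordinates, so direct hits go to BED6 and envelopes
to TSV).

When the insert model is not known it can be estimated from
orientation-valid both-mapped pairs (≥ 30 required): median for the mean,
1.4826 × MAD for the sd, bounds at mean ± 3 sd floored at twice the read
length. Median/MAD resist the contamination typical of implied-length
distributions (chimeras, mis-seeded hits).

Tallies are disjoint by construction: "read pairs" counts fragments with
both mates hit, "single reads" fragments with exactly one; total hits =
2·pairs + singles. The report header states this definition, since the
two counts could also be read as overlapping.

## Coverage, enrichment, map

Coverage counts direct alignments only — inference (envelopes) is never
mixed into observed depth — and obeys the conservation rule sum(depth) =
sum of hit lengths. Region enrichment uses the hit-midpoint rule, which is
unambiguous for tags straddling a boundary; zero hits yields an undefined
sentinel rather than 0. The ASCII map packs one row per fragment (greedy
first-free-row), '>'/'<' for strands, '·' bridging a mapped pair, '?' for
envelopes, on the extended axis with its origin and any negative start
stated in the header.

## Amplicon planning

Candidates near a target window are direct-hit tags (wanted orientation,
interval intersecting the window) plus extrapolated tags (expected
orientation, envelope intersecting), sorted by midpoint proximity.
Product size is 5′ end to 5′ end (the convention product sizes are
reported in). A direct hit has a point 5′ end; an extrapolated tag's 5′
end is taken over its envelope extremes, so each extrapolated endpoint
adds exactly its envelope width to the product-size range. A plan's span
is likewise evaluated at the envelope outer extremes — its length equals
product_max — and the greedy tiler repeatedly picks the admissible pair
reaching farthest right (ties: leftmost start, then fragment ids),
requiring pairwise overlap ≥ min_overlap and product_max ≤ max_product,
and reports the exact uncovered sub-interval when stuck.

Tags are primer *substrates*: sequences are reported 5′→3′ on the forward
axis with GC fraction and a melting temperature (Wallace rule 2(A+T)+4(G+C)
under 14 nt, else 64.9 + 41·((G+C)−16.4)/len). Both metrics are
orientation-invariant. Real primer optimization (nearest-neighbor Tm,
dimer screening) is out of scope.

## Synthetic data

The generator emulates the cross-species search condition. Divergence is
region-wise: each base substitutes independently with probability
1 − target identity (targets are direct per-base probabilities; no
back-substitution correction — simpler and sufficient at 40–90%
identity). Defaults mirror the motivating comparison: upstream/promoter
41%, coding 86%, downstream 60% identity. Indels (length 1–3) are off by
default because the aligner is gap-free; the switch exists to measure
robustness, not correctness.

Read simulation: fragment count = round(coverage × genome / (2 ×
read_len)); outer length Normal(mean, sd) truncated to [L_min, L_max] by
rejection and rounded; start uniform; mate 1 = first read_len bases,
mate 2 = reverse complement of the last read_len; per-base substitution
errors (default 0.5%); constant quality 'I' (qualities are parsed but
never used — the search is identity-based). Everything is a pure function
of (inputs, seed).

The standard scenario: a random 4,500-nt query (1 kb upstream, 1.5 kb
coding, 2 kb downstream), its ortholog embedded mid-way in a 20-kb random
background genome, a 30× 2×75 library (insert 1000 ± 50, bounds
[850, 1150]), plus a second library from an unrelated random genome as
the expected-zero control. Sizes were chosen so a full pipeline run takes
about a second while leaving hundreds of hits and placements to assert
on; truth tables record every fragment's origin.

What the simulation does *not* emulate, and hence what passing tests do
not show: real divergence is patchy (conserved islands inside an
"on-average 60%" flank), real base-calling errors are position- and
quality-dependent, coverage has GC bias and duplicates, and libraries
contain chimeras. In particular, under uniform per-base divergence the
60% downstream flank yields only rare direct hits (a percent or two of
its reads), so how far beyond the conserved coding region an amplicon
tiling can reach varies from library to library — visible in the
acceptance script's supported-span figures. On real data, conserved
patches make flanking tags more common than the uniform model predicts.

## Numerical and edge-case choices

Coordinates are 0-based half-open everywhere internally; the extended
axis is signed. Lowercase and U are normalized; non-ACGTN IUPAC ambiguity
codes map to N with a warning (common in read data), anything else is an
error. Mate naming resolves in fixed priority: `/1`–`/2`, `_1`–`_2`,
Casava 1.8 comment, then file of origin. Zero hits is a success
everywhere (an empty report row, not an error). Degenerate inserts
(L_min = L_max) give envelopes exactly one read length wide. The
insert-model estimator returns its fallback unchanged (with a logged
reason) below 30 usable pairs.

## Known limitations

Gap-free alignment misses indel-spanning tags; RF/mate-pair libraries are
unsupported; enrichment and coverage ignore multi-mapping beyond the
per-mate best hit; the Tm formulas are the classical approximations, not
nearest-neighbor thermodynamics; and the planner treats the envelope
extremes as feasible 5′ ends, which overstates the feasible range by up
to one read length on each extrapolated side (the conservative
interpretation would instead forbid any envelope-anchored first amplicon;
the chosen convention matches how overlapping ~3-kb products are tiled in
practice).
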