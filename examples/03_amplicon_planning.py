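"""Pair flanking tags into overlapping PCR amplicon plans.

Selects forward/reverse tag candidates around the gene (direct hits plus
extrapolated no-match mates) and greedily tiles the gene-plus-flanks span
with products of at most 3 kb overlapping by at least 100 bp — the
strategy used to amplify an orthologous genomic region from tags alone.
"""

from tagscout import TilingError, candidate_tags, plan_amplicons, scenario_wd40, search

bundle = scenario_wd40(seed=42)
result = search(bundle.query, bundle.library, insert=bundle.insert)

L = bundle.insert.L_max
fwd = candidate_tags(result.pairhits, (-L, 4500), "+", library=bundle.library)
rev = candidate_tags(result.pairhits, (-L, 4500 + L), "-", library=bundle.library)
print(f"forward candidates: {len(fwd)}  reverse candidates: {len(rev)}")

try:
    plans = plan_amplicons(fwd, rev, (0, 4500), max_product=3000, min_overlap=100)
except TilingError as exc:
    raise SystemExit(f"tiling infeasible: {exc}")

for i, p in enumerate(plans, 1):
    print(
        f"plan {i}: fwd {p.forward.fragment_id} ({p.forward.source}, "
        f"5' in {p.forward.five_prime_range}) x rev {p.reverse.fragment_id} "
        f"({p.reverse.source}, 5' in {p.reverse.five_prime_range}) -> "
        f"product {p.product_min}-{p.product_max} bp"
        + ("  [overlaps previous]" if p.overlap_ok else "")
    )
print()
print("Each product size is measured 5' end to 5' end; an extrapolated tag")
print("widens the product range by exactly its envelope width, a direct hit")
print("contributes a single point.")
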