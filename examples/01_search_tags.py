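"""Search a paired short-read library for tags matching a query sequence.

Builds the bundled cross-species scenario (a 4.5-kb query whose ortholog
diverges by region: 41% upstream / 86% coding / 60% downstream identity),
aligns a 30x 2x75 paired library from the ortholog genome against the
query, and prints the Table-style tally plus coding-region enrichment.
"""

from tagscout import enrichment, scenario_wd40, search

bundle = scenario_wd40(seed=42)
result = search(bundle.query, bundle.library, insert=bundle.insert)

rep = result.report
print(f"library: {rep.library_name}")
print(f"read pairs (both mates hit):   {rep.n_read_pairs}")
print(f"single reads (one mate hit):   {rep.n_single_reads}")
print(f"total hits:                    {rep.n_total_hits}")

frac = enrichment(result.pairhits, bundle.coding)
print(f"coding-region enrichment:      {frac:.1%}")
print()
print("Most tags concentrate in the conserved coding interval [1000,2500);")
print("the diverged flanks contribute few direct alignments, so flanking")
print("sequence is reached through mate placement instead (example 02).")
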