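"""Place an unmapped mate from its partner's alignment and the insert model.

A fragment whose coding-side mate aligns but whose promoter-side mate does
not ("no match") still localizes that mate: with FR orientation and outer
fragment length in [L_min, L_max], the missing mate must occupy a bounded
envelope on the extended query axis — possibly upstream of coordinate 0.
"""

from tagscout import InsertModel, scenario_wd40, search

bundle = scenario_wd40(seed=42)
result = search(bundle.query, bundle.library, insert=bundle.insert)

upstream = [
    p for p in result.pairhits
    if p.placement is not None and p.placement.envelope_end <= bundle.coding[0]
]
print(f"single-end fragments with the missing mate placed upstream of the")
print(f"coding region: {len(upstream)}")
for p in upstream[:3]:
    anchor = p.hit1 or p.hit2
    pl = p.placement
    print(
        f"  {p.fragment_id}: anchor {anchor.strand} hit at "
        f"[{anchor.q_start},{anchor.q_end}) -> mate on '{pl.strand}' within "
        f"[{pl.envelope_start},{pl.envelope_end})"
    )
model = bundle.insert
width = (model.L_max - model.L_min) + bundle.read_len
print(f"\nevery envelope is exactly (L_max-L_min)+read_len = {width} bp wide;")
print("negative coordinates denote positions 5' of the query — these")
print("promoter-side tags are usable as forward primers (example 03).")
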