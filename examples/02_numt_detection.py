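"""NUMT detection from read evidence: discordant pairs mark the insertion
locus, split reads define its junctions to the base, and mt-mt junctions
(more than two supporting split reads) betray a concatenated mega-NUMT.
"""

from meganumt import PlantedNumt, detect_numts_sample, group_numts, mt_span
from meganumt.synthetic import make_references, simulate_numt_reads

nuclear, mt = make_references(seed=3)
planted = PlantedNumt(
    numt_id="demo",
    nuclear_contig="chr1",
    insertion_pos=50_000,
    fragments=((4_000, 4_900, +1), (9_800, 9_100, -1)),  # second fragment reversed
    copies=4,
    source_sites=(),
)
reads = simulate_numt_reads(planted, dp_nu=42, read_length=150, seed_or_rng=3,
                            nuclear_ref=nuclear, mt_ref=mt, sample_id="S1")

calls = detect_numts_sample("S1", reads, {"chr1": nuclear}, mt)
grouped = group_numts(calls, cohort_size=1_000)

for call in grouped:
    print(f"{call.numt_id}: {call.nuclear_contig}:{call.nuclear_interval[0]}-"
          f"{call.nuclear_interval[1]}  discordant={call.n_discordant} "
          f"split={call.n_split}")
    print("  mtDNA breakpoints:",
          ", ".join(f"{s.pos}({s.strand})" for s in call.mt_breakpoints),
          f" span={mt_span(call)} bp")
    for j in call.junctions:
        print(f"  {j.kind} junction {j.side_a.contig}:{j.side_a.pos}({j.side_a.strand})"
              f" | {j.side_b.contig}:{j.side_b.pos}({j.side_b.strand})"
              f"  support={j.split_support}")
    print("  mega-NUMT evidence (mt-mt junction, >2 split reads):", call.mega_evidence)

# Expected: nu-mt breakpoints at the planted insertion (chr1:50000/50001,
# mt 4000(+) and mt 9100(-)), plus mt-mt junctions between consecutive
# concatemer fragments (4900->9800 and the tandem wrap 9100->4000).
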