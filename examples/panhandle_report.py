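"""Terminal complementarity (panhandle) analysis of bunyavirus-like
segments.

Negative-sense RNA virus segments pair their 5' and 3' termini into a
duplex ("panhandle") that the polymerase binds. The duplex is 20-30
complementary nucleotides with kinks and bulges, and its last eight
nucleotides (the terminal octamer) are family-specific — canonically
ACACAAAG. Here two leishbuvirus clades are compared: one carrying the
canonical octamer and one carrying the variant AAGAAACA.
"""

import virago
from virago.simulate import LBV1_SPEC, LBV4_SPEC, gen_virus

duplexes, groups = [], []
for spec, window in ((LBV1_SPEC, 22), (LBV4_SPEC, 26)):
    genome = gen_virus(spec, 1)
    for seg in genome.segments:
        d = virago.panhandle_align(seg.sequence, window=window,
                                   segment_id=f"{spec.name}-{seg.name}")
        duplexes.append(d)
        groups.append(spec.name)
        print(f"{d.segment_id}: {d.n_pairs} pairs, "
              f"{d.n_mismatches} mismatches, {len(d.bulges)} bulges, "
              f"octamer {d.octamer_5} (edit distance "
              f"{d.octamer_distance} to {virago.CANONICAL_OCTAMER})")

print()
print(duplexes[-1].render())  # the duplex as two-line text
print()

comp = virago.compare_panhandles(duplexes, groups)
for group, (consensus, dist, flagged) in comp.octamer_table.items():
    tag = "VARIANT" if flagged else "canonical"
    print(f"{group}: consensus octamer {consensus} ({tag}, distance {dist})")
print("Most canonical clade:", comp.most_canonical_group)
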