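"""Prevalence and coinfection tallies from the bundled isolate survey.

The survey covers 106 trypanosomatid cultures isolated from firebugs
across Europe; each row records the locality's trypanosomatid prevalence,
the dsRNA bands the culture showed on a gel, and the viral species
identified in it.
"""

import virago

table = virago.read_survey(virago.bundled_survey_path())
rep = virago.prevalence_summary(table)
prof = virago.coinfection_profile(table)

print("Trypanosomatids in firebugs:",
      f"{rep.trypanosomatid_pos}/{rep.trypanosomatid_n}",
      f"({rep.trypanosomatid_percent:.0f}%)")
print("dsRNA-positive isolates:   ",
      f"{rep.dsrna_pos}/{rep.dsrna_n} ({rep.dsrna_percent:.0f}%)")
for virus, (count, p_pos, p_all) in rep.virus_counts.items():
    print(f"  {virus:4s}: {count:2d} isolates "
          f"({p_pos:.1f}% of positive, {p_all:.1f}% of tested)")
print("Coinfected isolates (>= 2 species):", prof.n_coinfected)
print("Most viruses in one isolate:", prof.max_species)

cont = virago.cooccurrence_containment(table, "OV", "TLV")
print("Every Ostravirus isolate also carries the tombus-like virus:",
      cont.contained, cont.counts[0])
# The containment is the satellite signature: the Ostravirus never
# appears without its helper.
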