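"""Reproduce the study's variant-table bookkeeping from the packaged fixtures.

Loads the transcribed common / rare-inherited / de novo variant tables, then
runs the tally, cross-family-overlap and hub-ranking operations on them.  The
printed counts are the study's headline numbers: how many variants fall in
each category, how many recur in all four families, the consequence-class
split of the rare variants, and which genes pass the hub criterion
(degree >= 50) in the Family 1 interaction network.
"""

from famnet import (
    cross_family_overlap,
    hub_genes,
    load_table1_common,
    load_table2_rare,
    load_table3_dnm,
    load_table4_degrees,
    tally_by_consequence,
)

ALL = {"1", "2", "3", "4"}

common = load_table1_common()
rare = load_table2_rare()
dnm = load_table3_dnm()

print(f"common variants: {len(common)}, "
      f"in all four families: {cross_family_overlap(common, ALL)[1]}")
print(f"rare inherited variants: {len(rare)}, "
      f"in all four families: {cross_family_overlap(rare, ALL)[1]}")
for conseq, (n, pct) in tally_by_consequence(rare).items():
    print(f"  rare {conseq}: {n} ({pct}%)")
print(f"de novo mutations: {len(dnm)}; "
      f"child AU209 carries {sum(1 for r in dnm if r.trio_child == 'AU209')}; "
      f"family 3 carries {sum(1 for r in dnm if '3' in r.families)}")

print("Family 1 hub genes (degree >= 50):")
for gene, degree in hub_genes(load_table4_degrees()["1"], 50):
    print(f"  {gene}\t{degree}")
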