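"""Plant variant events in simulated families and recover them by triage.

Generates four multiplex families with Mendelian genotypes, planted rare
BAP-to-ASD transmissions and planted de novo heterozygotes, then runs the
three triage rules.  With zero genotyping error the de novo calls must match
the planted set exactly (recall 1, no false positives) — the printed
numbers verify that.
"""

from famnet import simulate_families, simulate_genotypes, triage_variants, trios
from famnet.simulate import SimConfig
from famnet.triage import detect_dnm

cfg = SimConfig(rng_seed=42, genotype_error_rate=0.0)
ped, _ = simulate_families(cfg)
gm, variants, truth = simulate_genotypes(ped, cfg)
print(f"{len(ped.families)} families, {len(gm.individual_ids)} individuals, "
      f"{len(gm.variant_ids)} variants")

cats = triage_variants(variants, gm, ped)
for cat, results in cats.items():
    print(f"{cat}: {len(results)} variants")

called = {
    (v.variant_id, trio[2])
    for v in variants
    for trio in trios(ped)
    if detect_dnm(v, gm, trio)
}
tp = len(called & truth.planted_dnms)
print(f"planted de novo events: {len(truth.planted_dnms)}, recovered: {tp}, "
      f"false positives: {len(called - truth.planted_dnms)}")
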