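"""Population-scale burden and drug-risk aggregation under Hardy-Weinberg.

Aggregates per-population allele frequencies of deleterious variants
into the expected number of variant alleles per individual, the rare
(MAF < 1%) share of that burden, and per-drug "individuals at risk per
1000" figures from simple actionability rules.
"""

from apf2 import (
    RiskRule,
    at_risk_fraction,
    carrier_frequency,
    default_config,
    expected_burden,
    simulate_frequency_table,
)

print(f"carrier frequency at allele frequency 0.1: {carrier_frequency(0.1):.2f}")
print("(2 x 0.1 x 0.9 heterozygotes + 0.1^2 homozygotes = 0.19)\n")

cfg = default_config(seed=1)
freqs = simulate_frequency_table(cfg)

print(f"{'population':<26} {'variants/individual':>20} {'rare share':>11}")
for pop in cfg.populations:
    e = expected_burden(freqs, None, pop)
    print(
        f"{pop:<26} {e.expected_variants_per_individual:>20.1f} "
        f"{e.rare_fraction:>10.1%}"
    )

rules = [
    RiskRule("drug-A", (freqs.genes[0],), "any_variant_allele",
             "one deleterious allele warrants a dose adjustment"),
    RiskRule("drug-B", (freqs.genes[0],), "two_variant_alleles",
             "only homozygous carriers are at risk"),
]
print()
for rule in rules:
    r = at_risk_fraction(freqs, None, rule, cfg.populations[0])
    print(
        f"{rule.drug}: {r.at_risk_per_1000:.0f} / 1000 individuals at risk "
        f"({rule.trigger}, {cfg.populations[0]})"
    )
print(
    "\nBurden is the expected deleterious allele count per diploid "
    "individual (sum of 2p); risk figures convert aggregated gene-level "
    "frequencies into the fraction of a population meeting the rule's "
    "genotype trigger."
)
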