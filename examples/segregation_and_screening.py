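"""Segregation filtering of candidate variants and cohort carrier screening.

Builds the packaged 23-variant segregation fixture (fully genotyped
pedigrees with known rule violations), applies the dominant-model
segregation rules, then screens one surviving variant in a simulated
88-patient unrelated cohort and converts carrier counts to allele-frequency
percentages. Finally prints the frequency-threshold derivation that justifies
the 0.02 panel filter.
"""

from famvar import (
    allele_frequency_percent,
    apply_segregation,
    carrier_burden_percent,
    causal_frequency_threshold,
    screen_carriers,
)
from famvar.simulate import (
    make_segregation_fixture,
    screen_genotype_map,
    simulate_screen_cohort,
)

fixture = make_segregation_fixture(seed=0)
retained, verdicts = apply_segregation(fixture.assignments, fixture.families)
print(f"segregation: {len(retained)} of {len(verdicts)} candidate variants retained")
reasons = {}
for verdict in verdicts.values():
    reasons[verdict.reason.value] = reasons.get(verdict.reason.value, 0) + 1
for reason, count in sorted(reasons.items()):
    print(f"  {reason}: {count}")

# screen one retained variant in an unrelated cohort with 2 carriers among 88
key = retained[0]
cohort = simulate_screen_cohort([(key, 2)], n=88, seed=3)
result = screen_carriers(key, screen_genotype_map(cohort, key))
print(
    f"\nscreen {key[0]}:{key[1]} {key[2]}>{key[3]}: "
    f"{result.carrier_count} carriers of {result.n} "
    f"-> allele frequency {result.allele_freq_percent}%"
)
print(f"carrier burden for 7 carriers among 88 patients: "
      f"{carrier_burden_percent(7, 88)}%")

expected, threshold = causal_frequency_threshold(0.004, 0.5, 10)
print(f"\nexpected causal-allele frequency (prevalence 0.004, half familial): "
      f"{expected}; panel filter threshold (10x): {threshold}")
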