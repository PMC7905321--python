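"""Single-locus polled/horned genetics: transmission, counting, projection.

Samples calves from carrier-by-carrier matings, counts alleles the way the
simulator does each year, and projects genotype shares from an allele
frequency under Hardy-Weinberg proportions.
"""

import numpy as np

from polledsim import (
    allele_frequency,
    hwe_genotype_frequencies,
    sample_offspring_genotypes,
)

rng = np.random.default_rng(7)

# Pp x Pp matings segregate 1 PP : 2 Pp : 1 pp
n = 100_000
calves = sample_offspring_genotypes(np.ones(n, int), np.ones(n, int), 0.0, rng)
counts = np.bincount(calves, minlength=3)
print("Pp x Pp segregation (pp, Pp, PP):", (counts / n).round(3))

# allele counting on a genotyped sample: 1051 horned, 443 het, 39 PP
q = allele_frequency({"pp": 1051, "Pp": 443, "PP": 39})
print(f"HORNED allele frequency of the sample: {100 * q:.1f}%  (POLLED {100 * (1 - q):.1f}%)")

# what a population at q = 0.78 looks like under random mating
pp, het, hom = hwe_genotype_frequencies(0.78)
print(
    f"HWE at q=0.78: {100 * pp:.0f}% horned, {100 * het:.0f}% het polled, "
    f"{100 * hom:.0f}% homozygous polled"
)
# the baseline scenario's year-20 state: still a horned majority
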