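"""Single-locus genotype algebra for the polled/horned system.

Horns in cattle are inherited as an autosomal recessive trait at the BTA1
polled locus.  The dominant *POLLED* allele (P) suppresses horn growth, so
homozygous polled (PP) and heterozygous polled (Pp) animals are hornless
while homozygous recessive (pp) animals are horned.

Genotypes are coded internally as the number of POLLED alleles an animal
carries (0 = pp, 1 = Pp, 2 = PP), which makes Mendelian transmission a pair
of Bernoulli draws and allele counting a dot product.  The string labels
"pp", "Pp", "PP" are used in every user-facing table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

#: Genotype codes: index = number of POLLED alleles carried.
PP, Pp, pp = 2, 1, 0

GENOTYPE_LABELS = ("pp", "Pp", "PP")
_LABEL_TO_CODE = {"pp": 0, "Pp": 1, "PP": 2}


def genotype_code(genotype: int | str) -> int:
    """Normalise a genotype given as code (0/1/2) or label ("pp"/"Pp"/"PP")."""
    if isinstance(genotype, str):
        try:
            return _LABEL_TO_CODE[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype label {genotype!r}") from None
    g = int(genotype)
    if g not in (0, 1, 2):
        raise ValueError(f"genotype code must be 0, 1 or 2, got {g}")
    return g


def genotype_label(code: int) -> str:
    return GENOTYPE_LABELS[genotype_code(code)]


def sample_offspring_genotypes(
    sire_genotypes: np.ndarray,
    dam_genotypes: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw offspring genotypes for paired parents (vectorised).

    One allele is sampled uniformly at random from each parent.  Calves that
    come out homozygous for the major (HORNED) allele are converted to
    heterozygous with probability ``mutation_rate``; this one-directional
    mutation prevents the minor POLLED allele from being lost to drift.

    Parameters
    ----------
    sire_genotypes, dam_genotypes
        Integer arrays of equal length, coded 0/1/2 (POLLED allele count).
    mutation_rate
        Probability that a pp calf is converted to Pp at creation.
    rng
        NumPy random generator.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    s = np.asarray(sire_genotypes, dtype=np.int8)
    d = np.asarray(dam_genotypes, dtype=np.int8)
    n = s.shape[0]
    # P(allele transmitted is POLLED) = genotype / 2
    child = (rng.random(n) < s / 2.0).astype(np.int8)
    child += rng.random(n) < d / 2.0
    if mutation_rate > 0.0:
        mut = (child == 0) & (rng.random(n) < mutation_rate)
        child[mut] = 1
    return child


def sample_offspring_genotype(
    sire_genotype: int | str,
    dam_genotype: int | str,
    mutation_rate: float,
    rng: np.random.Generator,
) -> int:
    """Single-calf convenience wrapper around :func:`sample_offspring_genotypes`."""
    s = np.array([genotype_code(sire_genotype)])
    d = np.array([genotype_code(dam_genotype)])
    return int(sample_offspring_genotypes(s, d, mutation_rate, rng)[0])


def allele_frequency(genotype_counts: Mapping[str, int] | Sequence[int]) -> float:
    """HORNED (recessive) allele frequency from genotype counts.

    ``genotype_counts`` may be a mapping with keys "pp"/"Pp"/"PP" or a
    sequence ``(n_pp, n_Pp, n_PP)``.  Returns q = (2 n_pp + n_Pp) / (2 N);
    the POLLED frequency is ``1 - q``.
    """
    if isinstance(genotype_counts, Mapping):
        counts = [genotype_counts.get(lab, 0) for lab in GENOTYPE_LABELS]
    else:
        counts = list(genotype_counts)
        if len(counts) != 3:
            raise ValueError("expected three genotype counts (pp, Pp, PP)")
    n_pp, n_het, n_hom = (int(c) for c in counts)
    if min(n_pp, n_het, n_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_pp + n_het + n_hom
    if total == 0:
        raise ValueError("cannot compute an allele frequency for an empty population")
    return (2 * n_pp + n_het) / (2 * total)


def horned_frequency_from_codes(codes: np.ndarray) -> float:
    """HORNED allele frequency of a population of coded genotypes."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("cannot compute an allele frequency for an empty population")
    # codes count POLLED alleles, so q = 1 - mean(code)/2
    return 1.0 - float(codes.mean()) / 2.0


def hwe_genotype_frequencies(q_horned: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions implied by a HORNED frequency.

    Returns ``(freq_pp, freq_Pp, freq_PP) = (q^2, 2q(1-q), (1-q)^2)``.
    """
    if not 0.0 <= q_horned <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    p = 1.0 - q_horned
    return (q_horned * q_horned, 2.0 * q_horned * p, p * p)
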