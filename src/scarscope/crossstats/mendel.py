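"""Multi-locus Mendelian genotype expectations with lethality filtering.

Loci assort independently (the modeled crosses involve genes on distinct
chromosomes). All probabilities are exact ``fractions.Fraction`` values so
that expectations match exhaustive gamete enumeration bit-for-bit.

Genotype labels: per-locus allele pairs are sorted (e.g. "Aa", never "aA")
and loci joined with ";" in the order declared by ``CrossSpec.loci``, e.g.
"Aa;bb".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product as iproduct
from typing import Mapping, Sequence

__all__ = ["CrossSpec", "GenotypeCounts", "genotype_distribution", "mendelian_expected",
           "genotype_label"]


def genotype_label(alleles_by_locus: Sequence[tuple[str, str]]) -> str:
    return ";".join("".join(sorted(pair)) for pair in alleles_by_locus)


@dataclass(frozen=True)
class CrossSpec:
    """A multi-locus cross: parental allele pairs per locus plus an optional
    set of lethal genotype predicates.

    ``lethal`` maps a genotype predicate to a survival fraction in [0, 1].
    A predicate is a mapping locus -> per-locus genotype string (sorted
    alleles, e.g. "aa"); an offspring matches if every listed locus matches.
    """

    loci: tuple[str, ...]
    parent1: Mapping[str, tuple[str, str]]
    parent2: Mapping[str, tuple[str, str]]
    lethal: tuple[tuple[Mapping[str, str], float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("cross spec must declare at least one locus")
        for parent, name in ((self.parent1, "parent1"), (self.parent2, "parent2")):
            missing = [l for l in self.loci if l not in parent]
            if missing:
                raise ValueError(f"{name} missing loci: {missing}")
            for locus in self.loci:
                if len(parent[locus]) != 2:
                    raise ValueError(f"{name} locus {locus!r} must have exactly 2 alleles")
        for predicate, survival in self.lethal:
            if not 0.0 <= survival <= 1.0:
                raise ValueError("survival fractions must be in [0, 1]")
            unknown = [l for l in predicate if l not in self.loci]
            if unknown:
                raise ValueError(f"lethal predicate references unknown loci: {unknown}")

    def survival_of(self, genotype: Mapping[str, str]) -> Fraction:
        """Combined survival fraction of a genotype across matching predicates."""
        surv = Fraction(1)
        for predicate, fraction in self.lethal:
            if all(genotype.get(l) == g for l, g in predicate.items()):
                surv *= Fraction(fraction).limit_denominator(10**6)
        return surv


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed counts and expected proportions, aligned by genotype label."""

    observed: Mapping[str, int]
    expected: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.observed.values()):
            raise ValueError("observed counts must be >= 0")
        if sum(self.expected.values()) != 1:
            raise ValueError("expected proportions must sum to 1")


def _locus_offspring(pair1: tuple[str, str], pair2: tuple[str, str]) -> dict[str, Fraction]:
    """Offspring genotype probabilities at one locus (each parent transmits
    either allele with probability 1/2)."""
    out: dict[str, Fraction] = {}
    for a1 in pair1:
        for a2 in pair2:
            label = "".join(sorted((a1, a2)))
            out[label] = out.get(label, Fraction(0)) + Fraction(1, 4)
    return out


def genotype_distribution(cross: CrossSpec) -> dict[str, Fraction]:
    """Pre-lethality multi-locus genotype distribution (sums to 1 exactly)."""
    per_locus = [
        _locus_offspring(tuple(cross.parent1[l]), tuple(cross.parent2[l])) for l in cross.loci
    ]
    dist: dict[str, Fraction] = {}
    for combo in iproduct(*(d.items() for d in per_locus)):
        label = ";".join(g for g, _ in combo)
        prob = Fraction(1)
        for _, p in combo:
            prob *= p
        dist[label] = dist.get(label, Fraction(0)) + prob
    return dist


def mendelian_expected(cross: CrossSpec) -> dict[str, Fraction]:
    """Expected surviving-offspring genotype proportions.

    Per-locus transmission probabilities are multiplied across loci, thinned
    by each lethal predicate's survival fraction, and renormalized to sum to
    1. Raises if every genotype is lethal.
    """
    dist = genotype_distribution(cross)
    thinned: dict[str, Fraction] = {}
    for label, prob in dist.items():
        genotype = dict(zip(cross.loci, label.split(";")))
        surv = cross.survival_of(genotype)
        if surv > 0:
            thinned[label] = prob * surv
    total = sum(thinned.values())
    if total == 0:
        raise ValueError("all genotypes are lethal: expected proportions undefined")
    return {label: prob / total for label, prob in thinned.items()}
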