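"""Breed-level haplotype inference from per-animal SLA class I genotypes.

The three classical class I loci are tightly linked and inherited as a block,
so an animal's expressed alleles decompose into two haplotypes.  A haplotype
is defined as a set of SLA-1/SLA-2/SLA-3 alleles observed together in an
individual fully homozygous animal, or detected together in a heterozygous
animal of the same breed that also expresses another already-defined
haplotype.  A haplotype may lack a locus entirely (a null locus) or carry two
alleles at one locus (a locus duplication).

The inference here is the deterministic fixpoint of that definition:

1. every fully homozygous animal seeds the pool with its allele set;
2. for each unresolved animal, a pool haplotype whose alleles form a
   sub-multiset of the animal's alleles proposes the residual as the
   complementary haplotype, which joins the pool (subject to a per-locus
   allele cap) and resolves the animal;
3. repeat until no animal changes state.

Group-specific allele labels (e.g. ``SLA-1*1501/1502``) are matched as single
tokens throughout.
"""

from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .library import LOCI, UNASSIGNED

logger = logging.getLogger(__name__)

ALL_LOCI = LOCI + (UNASSIGNED,)

# one (locus, allele-token) pair per carried allele
AlleleKey = tuple[str, str]


def _multiset(alleles_by_locus: Mapping[str, Sequence[str]]) -> Counter:
    c: Counter = Counter()
    for locus, names in alleles_by_locus.items():
        for name in names:
            c[(locus, name)] += 1
    return c


@dataclass(frozen=True)
class Haplotype:
    """A set of co-inherited alleles, up to a few per locus (0 = null)."""

    id: str
    alleles: tuple[tuple[str, tuple[str, ...]], ...]  # (locus, sorted names)

    @classmethod
    def from_dict(cls, hap_id: str, alleles: Mapping[str, Sequence[str]]) -> "Haplotype":
        items = tuple(sorted(
            (locus, tuple(sorted(names)))
            for locus, names in alleles.items() if names
        ))
        if not items:
            raise ValueError(f"haplotype {hap_id!r} has no alleles at any locus")
        return cls(hap_id, items)

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.alleles)

    def multiset(self) -> Counter:
        return _multiset(self.as_dict())

    def key(self) -> tuple[AlleleKey, ...]:
        """Canonical identity: the sorted allele multiset."""
        return tuple(sorted(self.multiset().elements()))

    def allele_count(self) -> int:
        return sum(len(names) for _, names in self.alleles)


RESOLVED, PARTIAL, UNRESOLVED = "resolved", "partial", "unresolved"
MULTI_HAPLOTYPE = "multi_haplotype"


@dataclass
class HaplotypeAssignment:
    animal: str
    status: str
    haplotypes: tuple[str, ...] = ()          # resolved pair or partial single
    residual: tuple[AlleleKey, ...] = ()      # leftover alleles (partial)
    note: str = ""


@dataclass
class HaplotypeInference:
    population: str
    pool: list[Haplotype]
    assignments: dict[str, HaplotypeAssignment]
    n_typed: int


def _new_id(n: int) -> str:
    # Hp-A.0, Hp-B.0, ... Hp-AA.0 after Z
    letters = string.ascii_uppercase
    label = ""
    n0 = n
    while True:
        label = letters[n0 % 26] + label
        n0 = n0 // 26 - 1
        if n0 < 0:
            break
    return f"Hp-{label}.0"


def infer_haplotypes(
    genotypes: Mapping[str, Mapping[str, Sequence[str]]],
    population: str = "population",
    known_haplotypes: Iterable[Haplotype] = (),
    max_dup_per_locus: int = 2,
) -> HaplotypeInference:
    """Infer a haplotype pool and per-animal diplotypes for one population.

    ``genotypes`` maps animal id -> locus -> called allele tokens.  Animals
    with zero calls are skipped with a warning (typing-failed upstream).
    Published haplotypes may be supplied as priors; they are consulted before
    new ids are proposed.
    """
    animals: dict[str, Counter] = {}
    for animal in sorted(genotypes):
        ms = _multiset(genotypes[animal])
        if not ms:
            logger.warning("animal %s has no allele calls; skipped", animal)
            continue
        animals[animal] = ms

    pool: list[Haplotype] = []
    pool_keys: dict[tuple[AlleleKey, ...], Haplotype] = {}
    n_new = 0

    def add_haplotype(alleles_by_locus: Mapping[str, Sequence[str]],
                      preset_id: str | None = None) -> Haplotype:
        nonlocal n_new
        hap = Haplotype.from_dict(preset_id or "tmp", alleles_by_locus)
        key = hap.key()
        if key in pool_keys:
            return pool_keys[key]
        if preset_id is None:
            hap = Haplotype.from_dict(_new_id(n_new), alleles_by_locus)
            n_new += 1
        pool.append(hap)
        pool_keys[key] = hap
        return hap

    for hap in known_haplotypes:
        add_haplotype(hap.as_dict(), preset_id=hap.id)

    assignments: dict[str, HaplotypeAssignment] = {}

    # 1. seed with fully homozygous animals: at most one distinct allele at
    #    every locus (a locus with one token but another with two is not a seed)
    for animal, ms in animals.items():
        by_locus: dict[str, list[str]] = {}
        for (locus, name) in ms:
            by_locus.setdefault(locus, []).append(name)
        if all(len(set(v)) == 1 and len(v) == 1 for v in by_locus.values()):
            hap = add_haplotype(by_locus)
            assignments[animal] = HaplotypeAssignment(
                animal, RESOLVED, (hap.id, hap.id))

    def sub_multiset(small: Counter, big: Counter) -> bool:
        return all(big[k] >= v for k, v in small.items())

    def residual_by_locus(ms: Counter) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for (locus, name), cnt in ms.items():
            out.setdefault(locus, []).extend([name] * cnt)
        return out

    # 2/3. iterate to fixpoint
    changed = True
    while changed:
        changed = False
        for animal in sorted(animals):
            if animal in assignments:
                continue
            ms = animals[animal]
            # prefer an exact decomposition into two pool haplotypes
            done = False
            for h1 in pool:
                m1 = h1.multiset()
                if not sub_multiset(m1, ms):
                    continue
                rest = ms - m1
                if not rest:
                    assignments[animal] = HaplotypeAssignment(
                        animal, RESOLVED, (h1.id, h1.id))
                    done = True
                    break
                for h2 in pool:
                    if h2.multiset() == rest:
                        assignments[animal] = HaplotypeAssignment(
                            animal, RESOLVED, (h1.id, h2.id))
                        done = True
                        break
                if done:
                    break
            if done:
                changed = True
                continue
            # a set explained by three established haplotypes is reported as
            # an anomaly, never force-resolved into a diplotype
            triple = _exact_triple_cover(ms, pool)
            if triple is not None:
                assignments[animal] = HaplotypeAssignment(
                    animal, MULTI_HAPLOTYPE, triple,
                    note="allele set decomposes into three pool haplotypes; "
                         "reported, not force-resolved")
                changed = True
                continue
            # otherwise let the first containing haplotype propose a complement
            for h1 in pool:
                m1 = h1.multiset()
                if not sub_multiset(m1, ms):
                    continue
                rest = residual_by_locus(ms - m1)
                if all(len(v) <= max_dup_per_locus for v in rest.values()):
                    h2 = add_haplotype(rest)
                    assignments[animal] = HaplotypeAssignment(
                        animal, RESOLVED, (h1.id, h2.id))
                    changed = True
                    break

    # 4. classify the remainder
    for animal in sorted(animals):
        if animal in assignments:
            continue
        ms = animals[animal]
        triple = _exact_triple_cover(ms, pool)
        if triple is not None:
            assignments[animal] = HaplotypeAssignment(
                animal, MULTI_HAPLOTYPE, triple,
                note="allele set decomposes into three pool haplotypes; "
                     "reported, not force-resolved")
            continue
        containing = [h for h in pool if sub_multiset(h.multiset(), ms)]
        if containing:
            h1 = containing[0]
            residual = tuple(sorted((ms - h1.multiset()).elements()))
            assignments[animal] = HaplotypeAssignment(
                animal, PARTIAL, (h1.id,), residual)
        else:
            assignments[animal] = HaplotypeAssignment(animal, UNRESOLVED)

    return HaplotypeInference(population, pool, assignments, len(animals))


def _exact_triple_cover(ms: Counter, pool: list[Haplotype]) -> tuple[str, ...] | None:
    candidates = [h for h in pool
                  if all(ms[k] >= v for k, v in h.multiset().items())]
    for a, b, c in combinations(candidates, 3):
        if a.multiset() + b.multiset() + c.multiset() == ms:
            return (a.id, b.id, c.id)
    return None


@dataclass
class HaplotypePrevalence:
    haplotype: str
    carriers: int
    carrier_pct: float
    chromosome_freq: float


def prevalence(inference: HaplotypeInference) -> list[HaplotypePrevalence]:
    """Carrier percentage per haplotype (animals carrying it in any resolved,
    partial or multi-haplotype slot, over animals with at least one call).
    Chromosome frequency (slots / 2N) is reported as a secondary figure."""
    if inference.n_typed == 0:
        raise ValueError(f"population {inference.population!r} has no typed animals")
    carriers: Counter = Counter()
    slots: Counter = Counter()
    for asg in inference.assignments.values():
        for hap_id in set(asg.haplotypes):
            carriers[hap_id] += 1
        for hap_id in asg.haplotypes:
            slots[hap_id] += 1
    out = []
    for hap in inference.pool:
        n = carriers.get(hap.id, 0)
        out.append(HaplotypePrevalence(
            haplotype=hap.id,
            carriers=n,
            carrier_pct=100.0 * n / inference.n_typed,
            chromosome_freq=slots.get(hap.id, 0) / (2 * inference.n_typed),
        ))
    return out
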