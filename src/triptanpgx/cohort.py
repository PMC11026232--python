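"""In-memory cohort container: one record per study participant.

A :class:`Cohort` is a list of :class:`Individual` records plus the variant
definitions in force.  Genotypes are unordered allele pairs (stored sorted)
or ``None`` for a failed/absent call.  Clinical answers are kept raw — a
list of selected categories per question — so the "keep the most severe
answer" survey rule is applied explicitly by the clinical module rather than
silently at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .variants import VARIANTS, VariantDef

USER = "user"
NON_USER = "non_user"
TABLET_ONLY = "tablet_only"
USAGE_GROUPS = (USER, NON_USER, TABLET_ONLY)

Genotype = tuple[str, str]


def normalize_genotype(a: str, b: str) -> Genotype:
    """Return the unordered pair in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    id: str
    sex: str  # "male" | "female"
    age: float
    usage_group: str
    age_at_onset: Optional[float] = None
    chronic: Optional[bool] = None
    heredity: Optional[bool] = None
    triptan_unresponsive: bool = False
    # question id -> list of selected categories (possibly >1, survey quirk)
    answers: dict[str, list[str]] = field(default_factory=dict)
    # numeric survey fields, e.g. disease_duration in years
    numerics: dict[str, Optional[float]] = field(default_factory=dict)
    genotypes: dict[str, Optional[Genotype]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.usage_group not in USAGE_GROUPS:
            raise ValueError(f"unknown usage group {self.usage_group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        for vid, g in self.genotypes.items():
            if g is None:
                continue
            alleles = VARIANTS[vid].alleles if vid in VARIANTS else None
            if alleles is not None and not set(g) <= set(alleles):
                raise ValueError(f"{self.id}: genotype {g} invalid for {vid}")
            self.genotypes[vid] = normalize_genotype(*g)


@dataclass
class Cohort:
    individuals: list[Individual]
    variants: dict[str, VariantDef] = field(default_factory=lambda: dict(VARIANTS))

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def subset(self, groups: Iterable[str]) -> "Cohort":
        groups = set(groups)
        return Cohort([i for i in self.individuals if i.usage_group in groups],
                      self.variants)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in USAGE_GROUPS}
        for ind in self.individuals:
            sizes[ind.usage_group] += 1
        return sizes

    def genotypes_for(self, variant_id: str) -> list[Optional[Genotype]]:
        if variant_id not in self.variants:
            raise KeyError(f"variant {variant_id!r} not in cohort")
        return [ind.genotypes.get(variant_id) for ind in self.individuals]
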