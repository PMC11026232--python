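"""Tri-allelic 5-HTTLPR/rs25531 genotype calling from BcnI restriction fragments.

The PCR-RFLP assay digests the 5-HTTLPR amplicon with BcnI.  Every allele
yields the constant 126 bp and 62 bp fragments (they confirm digestion
worked); the diagnostic fragments are

    L_A : 341 bp
    L_G : 174 bp + 167 bp
    S   : 298 bp

A gel lane is a multiset of observed band lengths.  Because all expected
fragment lengths are distinct and a homozygote's two alleles produce the
same fragments, the expected *band* pattern of a diploid genotype is the set
union of the per-allele fragment sets; the six diploid patterns are pairwise
distinct, so an exactly-matching lane has a unique call.

Lanes that match the L_G/S pattern but carry an additional 341 bp band are
called L_G/S with a ``sequencing_required`` flag: such samples need Sanger
confirmation before use, mirroring wet-lab practice for this assay.

The 174/167 bp pair is treated as a co-migrating doublet: 7 bp is below
agarose resolution, so a single observed band within tolerance of both
lengths satisfies both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Optional

from .cohort import Genotype, normalize_genotype

TRI_ALLELES = ("L_A", "L_G", "S")
CONSTANT_FRAGMENTS = (126, 62)
DIAGNOSTIC_FRAGMENTS = {"L_A": (341,), "L_G": (174, 167), "S": (298,)}
DEFAULT_TOLERANCE = 0.04

SEQUENCING_REQUIRED = "sequencing_required"
UNMATCHED_BANDS = "unmatched_bands"
MISSING_CONSTANT_BANDS = "missing_constant_bands"

DIPLOID_GENOTYPES: tuple[Genotype, ...] = tuple(
    normalize_genotype(a, b)
    for a, b in combinations_with_replacement(TRI_ALLELES, 2)
)


@dataclass(frozen=True)
class BandPattern:
    """Observed restriction-fragment lengths (bp) for one gel lane."""

    sample_id: str
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.fragment_lengths):
            raise ValueError(f"{self.sample_id}: fragment lengths must be positive")


@dataclass
class TriallelicCall:
    sample_id: str
    genotype: Optional[Genotype]
    flags: set[str] = field(default_factory=set)

    @property
    def is_call(self) -> bool:
        """Usable without confirmation: flagged lanes await Sanger results."""
        return self.genotype is not None and not self.flags


def expected_bands(genotype: Iterable[str]) -> frozenset[int]:
    """Expected gel band lengths for an unordered diploid genotype.

    Union of the two alleles' fragment sets: the constant 126/62 fragments
    appear once regardless of genotype, and shared diagnostic fragments of a
    homozygote co-migrate into a single band.
    """
    alleles = tuple(genotype)
    if len(alleles) != 2:
        raise ValueError("genotype must be an allele pair")
    bands: set[int] = set(CONSTANT_FRAGMENTS)
    for allele in alleles:
        if allele not in DIAGNOSTIC_FRAGMENTS:
            raise ValueError(f"unknown allele symbol {allele!r}")
        bands.update(DIAGNOSTIC_FRAGMENTS[allele])
    return frozenset(bands)


def _pairwise_distinct_patterns() -> None:
    patterns = [expected_bands(g) for g in DIPLOID_GENOTYPES]
    assert len(set(patterns)) == len(patterns), \
        "expected band patterns are not genotype-diagnostic"


_pairwise_distinct_patterns()


def _within(observed: int, expected: int, tolerance: float) -> bool:
    return abs(observed - expected) <= tolerance * expected


def _compatible(observed: tuple[int, ...], genotype: Genotype,
                tolerance: float) -> bool:
    """All expected bands seen and every observed band explained."""
    exp = expected_bands(genotype)
    for e in exp:
        if not any(_within(o, e, tolerance) for o in observed):
            return False
    for o in observed:
        if not any(_within(o, e, tolerance) for e in exp):
            return False
    return True


def call_genotype(pattern: BandPattern,
                  tolerance: float = DEFAULT_TOLERANCE) -> TriallelicCall:
    """Call the tri-allelic genotype whose band pattern matches the lane.

    Matching is tolerance-based (|observed − expected| ≤ tolerance·expected).
    Unique match → clean call.  L_G/S pattern plus an extra 341 bp band →
    L_G/S flagged ``sequencing_required``.  Absent constant bands, leftover
    unexplained bands, or an ambiguous/partial pattern → no-call with the
    corresponding flag.
    """
    if not 0 <= tolerance <= 0.1:
        raise ValueError("tolerance must be in [0, 0.1]")
    obs = pattern.fragment_lengths
    if not obs:
        raise ValueError(f"{pattern.sample_id}: empty band pattern")

    constants_seen = all(
        any(_within(o, c, tolerance) for o in obs) for c in CONSTANT_FRAGMENTS
    )
    if not constants_seen:
        return TriallelicCall(pattern.sample_id, None, {MISSING_CONSTANT_BANDS})

    candidates = [g for g in DIPLOID_GENOTYPES if _compatible(obs, g, tolerance)]
    if len(candidates) == 1:
        return TriallelicCall(pattern.sample_id, candidates[0], set())

    if not candidates:
        # L_G/S lane with an extra L_A-diagnostic 341 bp band: flag for Sanger
        lgs = normalize_genotype("L_G", "S")
        exp = expected_bands(lgs)
        leftovers = [o for o in obs
                     if not any(_within(o, e, tolerance) for e in exp)]
        covered = all(any(_within(o, e, tolerance) for o in obs) for e in exp)
        if covered and leftovers and all(_within(o, 341, tolerance)
                                         for o in leftovers):
            return TriallelicCall(pattern.sample_id, lgs, {SEQUENCING_REQUIRED})

    # zero or multiple candidates: the lane does not identify one genotype
    return TriallelicCall(pattern.sample_id, None, {UNMATCHED_BANDS})


def recode_biallelic(genotype: Iterable[str]) -> Genotype:
    """Collapse to presence (L) / absence (S) of the 43 bp insertion."""
    mapping = {"L_A": "L", "L_G": "L", "S": "S"}
    return _recode(genotype, mapping)


def recode_collapsed(genotype: Iterable[str]) -> Genotype:
    """Collapse L_G with S (similar expression level): alleles L_A vs S*."""
    mapping = {"L_A": "L_A", "L_G": "S*", "S": "S*"}
    return _recode(genotype, mapping)


def _recode(genotype: Iterable[str], mapping: dict[str, str]) -> Genotype:
    alleles = tuple(genotype)
    if len(alleles) != 2:
        raise ValueError("genotype must be an allele pair")
    try:
        recoded = tuple(mapping[a] for a in alleles)
    except KeyError as exc:
        raise ValueError(f"unknown allele symbol {exc.args[0]!r}") from exc
    return normalize_genotype(*recoded)
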