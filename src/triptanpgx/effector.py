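"""Cumulative genetic effector score and its covariate-adjusted regression.

The effector allele of each variant is the allele more common in triptan
non-users than in users; an individual's effector score is the unweighted
sum of effector-allele copies over the five variants (0–10).  5-HTTLPR is
scored on its bi-allelic recoding (S is the effector allele; L_A and L_G are
jointly non-effector).  The score is analysed as a continuous predictor of
non-usage in a logistic regression with sex and age covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .association import AlleleCountTable, count_alleles
from .cohort import Cohort, NON_USER, USER
from .logistic import LogisticFit, fit_logistic
from .rflp import recode_biallelic
from .variants import HTTLPR, SNP_IDS

DATA_DRIVEN = "data_driven"
LITERATURE = "literature"
OVERRIDE = "override"

SCORE_VARIANTS = (*SNP_IDS, HTTLPR)


class TiedFrequencyError(ValueError):
    """Both alleles equally common in non-users: an explicit override is needed."""


@dataclass
class EffectorSpec:
    """Per-variant effector-allele designation with provenance tags."""

    alleles: dict[str, str]
    sources: dict[str, str] = field(default_factory=dict)
    rationale: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vid in self.alleles:
            self.sources.setdefault(vid, DATA_DRIVEN)
        if HTTLPR in self.alleles and self.alleles[HTTLPR] != "S":
            raise ValueError("5-HTTLPR is scored bi-allelically with effector S "
                             "(L_A and L_G are non-effector)")


@dataclass
class EffectorScoreResult:
    scores: dict[str, int]
    n_complete: int
    fit: LogisticFit

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.fit.names, map(float, self.fit.coef)))

    @property
    def p_values(self) -> dict[str, float]:
        return dict(zip(self.fit.names, map(float, self.fit.p_wald)))


def identify_effector_alleles(
        tables: Mapping[str, AlleleCountTable],
        overrides: Optional[Mapping[str, str]] = None) -> EffectorSpec:
    """Designate, per variant, the allele more frequent in non-users.

    Exact frequency ties raise :class:`TiedFrequencyError` unless an override
    resolves them.  Overrides always win and are tagged as such (as done for
    rs6724624, where the in-cohort direction contradicted the literature and
    C was fixed as the effector allele).
    """
    overrides = dict(overrides or {})
    alleles: dict[str, str] = {}
    sources: dict[str, str] = {}
    for vid, table in tables.items():
        if vid in overrides:
            choice = overrides.pop(vid)
            if choice not in table.alleles:
                raise ValueError(f"override allele {choice!r} not in {vid}")
            alleles[vid] = choice
            sources[vid] = OVERRIDE
            continue
        tot_nu = table.total(NON_USER)
        tot_u = table.total(USER)
        if tot_nu == 0 or tot_u == 0:
            raise ValueError(f"{vid}: empty usage group, cannot compare")
        # effector = allele whose relative frequency is higher in non-users
        excess = {a: table.non_users[a] / tot_nu - table.users[a] / tot_u
                  for a in table.alleles}
        ranked = sorted(table.alleles, key=lambda a: -excess[a])
        if len(ranked) > 1 and excess[ranked[0]] == excess[ranked[1]]:
            raise TiedFrequencyError(
                f"{vid}: allele frequencies identical across usage groups; "
                "supply an explicit override")
        alleles[vid] = ranked[0]
        sources[vid] = DATA_DRIVEN
    if overrides:
        raise ValueError(f"overrides for unknown variants: {sorted(overrides)}")
    return EffectorSpec(alleles=alleles, sources=sources)


def default_effector_spec() -> EffectorSpec:
    """Effector designation of the source study.

    Data-driven (more common in non-users) for all variants; rs6724624 is
    tagged as an override of the literature direction, and 5-HTTLPR uses the
    bi-allelic S rule.
    """
    return EffectorSpec(
        alleles={"rs1024905": "C", "rs6724624": "C", "rs5443": "T",
                 "rs2651899": "T", HTTLPR: "S"},
        sources={"rs6724624": OVERRIDE},
        rationale={"rs6724624": "C more common in non-users in-cohort; "
                                "literature reports G for migraine"})


def effector_copies(genotype, variant_id: str, spec: EffectorSpec) -> int:
    """Effector-allele dosage (0/1/2) of one genotype under the spec."""
    if variant_id == HTTLPR:
        genotype = recode_biallelic(genotype)
    return sum(1 for allele in genotype if allele == spec.alleles[variant_id])


def compute_scores(cohort: Cohort, spec: EffectorSpec,
                   variants: Sequence[str] = SCORE_VARIANTS) -> dict[str, int]:
    """Unweighted cumulative effector score per individual.

    Individuals missing a genotype for any scored variant are excluded; the
    score of a complete individual lies in [0, 2·n_variants].
    """
    missing_spec = [v for v in variants if v not in spec.alleles]
    if missing_spec:
        raise ValueError(f"effector spec lacks variants: {missing_spec}")
    for v in variants:
        if v not in cohort.variants:
            raise ValueError(f"cohort lacks variant {v!r}")
    scores: dict[str, int] = {}
    for ind in cohort:
        genotypes = [ind.genotypes.get(v) for v in variants]
        if any(g is None for g in genotypes):
            continue
        scores[ind.id] = sum(effector_copies(g, v, spec)
                             for g, v in zip(genotypes, variants))
    return scores


def score_regression(cohort: Cohort, scores: Mapping[str, int],
                     covariates: Sequence[str] = ("sex", "age")) -> EffectorScoreResult:
    """Logistic regression of non-usage on the continuous effector score.

    Outcome is 1 for non-users, 0 for users (tablet-only excluded); sex is
    coded male = 1 and age enters in years.  Fitted with the shared IRLS
    engine; Wald inference.
    """
    y, cols = [], []
    for ind in cohort:
        if ind.usage_group not in (USER, NON_USER) or ind.id not in scores:
            continue
        row = [1.0, float(scores[ind.id])]
        for cov in covariates:
            if cov == "sex":
                row.append(1.0 if ind.sex == "male" else 0.0)
            elif cov == "age":
                row.append(float(ind.age))
            else:
                raise ValueError(f"unknown covariate {cov!r}")
        cols.append(row)
        y.append(1.0 if ind.usage_group == NON_USER else 0.0)
    X = np.array(cols)
    y_arr = np.array(y)
    if X.size == 0 or len(y_arr) < X.shape[1]:
        raise ValueError("fewer complete individuals than parameters")
    names = ["intercept", "score"]
    names += ["male" if c == "sex" else c for c in covariates]
    fit = fit_logistic(X, y_arr, names)
    used = {ind.id for ind in cohort
            if ind.usage_group in (USER, NON_USER) and ind.id in scores}
    return EffectorScoreResult(scores={k: int(v) for k, v in scores.items()},
                               n_complete=len(used), fit=fit)
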