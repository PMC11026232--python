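"""Seeded synthetic cluster-headache cohorts with the study's data structure.

The generator emulates the published cohort: five variants drawn in
Hardy-Weinberg proportions at the pooled allele frequencies of the genotyped
sample, triptan-usage groups driven by a logistic model on the individual's
true effector score, sex and age (the published regression estimates are the
default coefficients), group-conditional clinical answer profiles that
approximate the published demographic and clinical tables, and independent
per-variant genotype missingness.

One root seed spawns fixed-order substreams (sex, age, genotypes, tablet
assignment, usage, onset, clinical, missingness) so a cohort regenerates
byte-identically for a given configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort, Individual, NON_USER, TABLET_ONLY, USER
from .effector import EffectorSpec, default_effector_spec, effector_copies
from .variants import HTTLPR, VARIANTS, VariantDef, pooled_frequencies

# Published effector-score regression estimates (log-odds; outcome = non-user)
DEFAULT_COEF_SCORE = 0.204
DEFAULT_COEF_MALE = -0.483
DEFAULT_COEF_AGE = 0.031

# Cohort composition of the genotyped sample: 409 users, 109 non-users,
# 27 tablet-only of 545; demographics from the published summary table.
DEFAULT_NONUSER_FRACTION = 109 / 518
DEFAULT_TABLET_FRACTION = 27 / 545
DEFAULT_MALE_FRACTION = 0.656
DEFAULT_AGE_MEAN, DEFAULT_AGE_SD = 50.3, 14.3
AGE_LO, AGE_HI = 18.0, 90.0

# Group-conditional clinical category probabilities (approximate published
# percentages; user profile reused for tablet-only where no figure exists).
CLINICAL_PROFILES: dict[str, dict[str, dict[str, float]]] = {
    "attack_frequency": {
        USER: {"<1": 0.051, "1-2": 0.406, "3-5": 0.395, ">6": 0.148},
        NON_USER: {"<1": 0.136, "1-2": 0.442, "3-5": 0.313, ">6": 0.109},
    },
    "attack_duration": {
        USER: {"15-30 min": 0.140, "30-120 min": 0.530,
               "120-180 min": 0.181, ">180 min": 0.149},
        NON_USER: {"15-30 min": 0.172, "30-120 min": 0.477,
                   "120-180 min": 0.172, ">180 min": 0.179},
    },
    "period_duration": {
        USER: {"0-1 m": 0.270, "1-2 m": 0.305, "2-4 m": 0.210,
               "4-7 m": 0.074, "7-12 m": 0.052, ">12 m": 0.089},
        NON_USER: {"0-1 m": 0.340, "1-2 m": 0.271, "2-4 m": 0.201,
                   "4-7 m": 0.035, "7-12 m": 0.063, ">12 m": 0.090},
    },
    "severity_score": {
        USER: {"2-4S": 0.073, "5-6S": 0.463, "7-9S": 0.374, ">10S": 0.089},
        NON_USER: {"2-4S": 0.086, "5-6S": 0.429, "7-9S": 0.364, ">10S": 0.121},
    },
    "autonomic_symptoms": {
        USER: {"yes": 0.951, "no": 0.049},
        NON_USER: {"yes": 0.881, "no": 0.119},
    },
    "smoking": {
        USER: {"current": 0.270, "previous": 0.406, "never": 0.324},
        NON_USER: {"current": 0.219, "previous": 0.519, "never": 0.262},
    },
    "alcohol_trigger": {
        USER: {"yes": 0.574, "no": 0.426},
        NON_USER: {"yes": 0.434, "no": 0.566},
    },
    "specific_triggers": {
        USER: {"yes": 0.560, "no": 0.440},
        NON_USER: {"yes": 0.477, "no": 0.523},
    },
}

BOOLEAN_PROFILES = {
    "chronic": {USER: 0.123, NON_USER: 0.121, TABLET_ONLY: 0.171},
    "heredity": {USER: 0.131, NON_USER: 0.083, TABLET_ONLY: 0.154},
}

ONSET_PROFILES = {  # mean, sd of age at onset per group (years)
    USER: (31.0, 13.0), NON_USER: (35.1, 14.7), TABLET_ONLY: (34.4, 14.8),
}

DISEASE_DURATION = {USER: (18.3, 13.7), NON_USER: (17.3, 14.5),
                    TABLET_ONLY: (18.0, 14.0)}


@dataclass
class GeneratorConfig:
    """Complete, seedable description of one synthetic cohort draw."""

    n_individuals: int
    allele_freqs: dict[str, dict[str, float]]
    intercept: float
    coef_score: float = DEFAULT_COEF_SCORE
    coef_male: float = DEFAULT_COEF_MALE
    coef_age: float = DEFAULT_COEF_AGE
    tablet_only_fraction: float = DEFAULT_TABLET_FRACTION
    missing_rate: dict[str, float] = field(default_factory=dict)
    male_fraction: float = DEFAULT_MALE_FRACTION
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    multi_answer_fraction: float = 0.05
    clinical_missing_rate: float = 0.03
    onset_missing_rate: float = 0.10
    seed: int = 0
    effector_spec: EffectorSpec = field(default_factory=default_effector_spec)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for vid, freqs in self.allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{vid}: allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{vid}: negative allele frequency")
        for name in ("tablet_only_fraction", "male_fraction",
                     "multi_answer_fraction", "clinical_missing_rate",
                     "onset_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for vid, r in self.missing_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {vid} outside [0, 1]")


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _score_distribution(allele_freqs, spec: EffectorSpec) -> np.ndarray:
    """Exact pmf of the true effector score under HWE and independence."""
    pmf = np.array([1.0])
    for vid, freqs in allele_freqs.items():
        if vid == HTTLPR:
            p = sum(f for a, f in freqs.items() if a == "S")
        else:
            p = freqs[spec.alleles[vid]]
        per = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        pmf = np.convolve(pmf, per)
    return pmf


def solve_intercept(config_like: "GeneratorConfig",
                    target_nonuser_fraction: float = DEFAULT_NONUSER_FRACTION
                    ) -> float:
    """Intercept giving the target marginal non-user fraction (non-tablet).

    Integrates the logistic model over the exact effector-score distribution,
    the sex mix and a quadrature grid on the truncated age distribution, then
    solves by bisection.
    """
    c = config_like
    score_pmf = _score_distribution(c.allele_freqs, c.effector_spec)
    scores = np.arange(score_pmf.size)
    age_dist = _truncnorm(c.age_mean, c.age_sd, AGE_LO, AGE_HI)
    ages = np.linspace(AGE_LO, AGE_HI, 513)
    age_w = age_dist.pdf(ages)
    age_w /= age_w.sum()
    age_centred = ages - age_dist.mean()
    sex_vals = np.array([1.0, 0.0])
    sex_w = np.array([c.male_fraction, 1 - c.male_fraction])

    def marginal(b0: float) -> float:
        eta = (b0
               + c.coef_score * scores[:, None, None]
               + c.coef_male * sex_vals[None, :, None]
               + c.coef_age * age_centred[None, None, :])
        p = 1.0 / (1.0 + np.exp(-eta))
        return float(np.einsum("i,j,k,ijk->", score_pmf, sex_w, age_w, p))

    return float(optimize.brentq(
        lambda b0: marginal(b0) - target_nonuser_fraction, -30.0, 30.0,
        xtol=1e-10))


def default_config(n_individuals: int, seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-condition defaults: pooled allele frequencies, published
    regression coefficients, published group mix, per-variant missingness
    matching the reported call rates (2% for the qPCR SNPs, 2.4% for the
    PCR-RFLP 5-HTTLPR assay)."""
    missing = {vid: 0.02 for vid in VARIANTS}
    missing[HTTLPR] = 0.024
    cfg = GeneratorConfig(
        n_individuals=n_individuals,
        allele_freqs=pooled_frequencies(),
        intercept=0.0,
        missing_rate=missing,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.__post_init__()
    cfg.intercept = solve_intercept(cfg)
    return cfg


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort; deterministic for a fixed configuration and seed."""
    c = config
    streams = np.random.SeedSequence(c.seed).spawn(8)
    rng_sex, rng_age, rng_geno, rng_tablet, rng_usage, rng_onset, \
        rng_clin, rng_miss = (np.random.default_rng(s) for s in streams)
    n = c.n_individuals

    sex = np.where(rng_sex.random(n) < c.male_fraction, "male", "female")
    age_dist = _truncnorm(c.age_mean, c.age_sd, AGE_LO, AGE_HI)
    ages = age_dist.ppf(rng_age.random(n)).round(1)
    age_centre = age_dist.mean()

    genotypes: dict[str, list] = {}
    for vid, freqs in c.allele_freqs.items():
        alleles = list(freqs)
        probs = np.array([freqs[a] for a in alleles])
        draws = rng_geno.choice(len(alleles), size=(n, 2), p=probs)
        genotypes[vid] = [tuple(sorted((alleles[i], alleles[j])))
                          for i, j in draws]

    scores = np.array([
        sum(effector_copies(genotypes[vid][i], vid, c.effector_spec)
            for vid in c.allele_freqs)
        for i in range(n)], dtype=float)

    tablet = rng_tablet.random(n) < c.tablet_only_fraction
    eta = (c.intercept + c.coef_score * scores
           + c.coef_male * (sex == "male")
           + c.coef_age * (ages - age_centre))
    non_user = rng_usage.random(n) < 1.0 / (1.0 + np.exp(-eta))
    groups = np.where(tablet, TABLET_ONLY,
                      np.where(non_user, NON_USER, USER))

    group_list = [str(g) for g in groups]

    # age at onset: group-conditional truncated normal on [5, min(age, 85)]
    onset_mean = np.array([ONSET_PROFILES[g][0] for g in group_list])
    onset_sd = np.array([ONSET_PROFILES[g][1] for g in group_list])
    onset_hi = np.minimum(ages, 85.0)
    onset_vals = np.round(stats.truncnorm.ppf(
        rng_onset.random(n), (5.0 - onset_mean) / onset_sd,
        (onset_hi - onset_mean) / onset_sd,
        loc=onset_mean, scale=onset_sd), 1)
    onset_missing = rng_onset.random(n) < c.onset_missing_rate

    # clinical answers: per question, vectorised inverse-cdf category draws
    multi_q = ("attack_frequency", "attack_duration", "period_duration")
    answers_by_q: dict[str, list[list[str]]] = {}
    for qid, profile in CLINICAL_PROFILES.items():
        cats = list(profile[USER])
        cum = {}
        for g in (USER, NON_USER, TABLET_ONLY):
            probs = np.array([profile.get(g, profile[USER])[cat]
                              for cat in cats])
            cum[g] = np.cumsum(probs / probs.sum())
        cums = np.stack([cum[g] for g in group_list])
        missing = rng_clin.random(n) < c.clinical_missing_rate
        pick1 = (rng_clin.random(n)[:, None] > cums).sum(axis=1)
        extra = rng_clin.random(n) < (c.multi_answer_fraction
                                      if qid in multi_q else 0.0)
        pick2 = (rng_clin.random(n)[:, None] > cums).sum(axis=1)
        col = []
        for i in range(n):
            if missing[i]:
                col.append([])
            elif extra[i]:
                col.append([cats[pick1[i]], cats[pick2[i]]])
            else:
                col.append([cats[pick1[i]]])
        answers_by_q[qid] = col

    booleans = {}
    for fieldname, profile in BOOLEAN_PROFILES.items():
        p = np.array([profile.get(g, profile[USER]) for g in group_list])
        missing = rng_clin.random(n) < c.clinical_missing_rate
        vals = rng_clin.random(n) < p
        booleans[fieldname] = [None if m else bool(v)
                               for m, v in zip(missing, vals)]

    dd_mean = np.array([DISEASE_DURATION[g][0] for g in group_list])
    dd_sd = np.array([DISEASE_DURATION[g][1] for g in group_list])
    dd_missing = rng_clin.random(n) < c.clinical_missing_rate
    dd_vals = np.round(stats.truncnorm.ppf(
        rng_clin.random(n), (0.0 - dd_mean) / dd_sd, (70.0 - dd_mean) / dd_sd,
        loc=dd_mean, scale=dd_sd), 1)
    unresponsive = rng_clin.random(n) < 0.1

    individuals: list[Individual] = []
    for i in range(n):
        group = group_list[i]
        individuals.append(Individual(
            id=f"CH{i + 1:05d}", sex=str(sex[i]), age=float(ages[i]),
            usage_group=group,
            age_at_onset=(None if onset_missing[i] else float(onset_vals[i])),
            chronic=booleans["chronic"][i], heredity=booleans["heredity"][i],
            triptan_unresponsive=bool(group == NON_USER and unresponsive[i]),
            answers={qid: answers_by_q[qid][i] for qid in CLINICAL_PROFILES},
            numerics={"disease_duration":
                      None if dd_missing[i] else float(dd_vals[i])},
            genotypes={vid: genotypes[vid][i] for vid in c.allele_freqs}))

    for vid, rate in c.missing_rate.items():
        if rate <= 0:
            continue
        drop = rng_miss.random(n) < rate
        for i in np.flatnonzero(drop):
            individuals[i].genotypes[vid] = None

    variants = {vid: VARIANTS[vid] if vid in VARIANTS
                else VariantDef(vid, tuple(c.allele_freqs[vid]))
                for vid in c.allele_freqs}
    return Cohort(individuals, variants)
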