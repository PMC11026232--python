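"""Clinical-feature comparison between triptan users and non-users.

Survey answers are categorical (with a declared severity order where
participants could tick several boxes — the most severe answer is kept),
boolean, or numeric.  Categorical features are compared with Pearson
chi-square (Yates continuity correction on 2×2 tables only), numeric
features with the two-sample Wilcoxon rank-sum test (exact for small
untied samples).  Missing answers are excluded from percentages and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, NON_USER, TABLET_ONLY, USER

CATEGORICAL = "categorical"
NUMERIC = "numeric"
BOOLEAN = "boolean"


@dataclass(frozen=True)
class ClinicalQuestion:
    """One survey question with its category labels in severity order."""

    question_id: str
    categories: tuple[str, ...]
    answer_type: str = CATEGORICAL
    most_severe_rule: bool = False


# Default questionnaire layout: categories ordered least → most severe.
DEFAULT_QUESTIONS: dict[str, ClinicalQuestion] = {
    q.question_id: q for q in [
        ClinicalQuestion("attack_frequency", ("<1", "1-2", "3-5", ">6"),
                         most_severe_rule=True),
        ClinicalQuestion("attack_duration",
                         ("15-30 min", "30-120 min", "120-180 min", ">180 min"),
                         most_severe_rule=True),
        ClinicalQuestion("period_duration",
                         ("0-1 m", "1-2 m", "2-4 m", "4-7 m", "7-12 m", ">12 m"),
                         most_severe_rule=True),
        ClinicalQuestion("severity_score", ("2-4S", "5-6S", "7-9S", ">10S")),
        ClinicalQuestion("autonomic_symptoms", ("no", "yes")),
        ClinicalQuestion("smoking", ("never", "previous", "current")),
        ClinicalQuestion("alcohol_trigger", ("no", "yes")),
        ClinicalQuestion("specific_triggers", ("no", "yes")),
    ]
}


@dataclass
class GroupComparison:
    question_id: str
    counts: Optional[np.ndarray]  # group × category, None for numeric tests
    test: str  # chisq_yates_2x2 | chisq_rxc | wilcoxon
    statistic: float
    p: float
    df: Optional[int] = None
    flags: set[str] = field(default_factory=set)

    @property
    def p_display(self) -> float:
        return min(self.p, 1.0)


def keep_most_severe(answers: Sequence[str],
                     question: ClinicalQuestion) -> Optional[str]:
    """Resolve multiple ticked boxes to the most severe category.

    Severity is the question's declared category order; an empty answer list
    is missing data.  Idempotent and order-invariant.
    """
    if not answers:
        return None
    try:
        return max(answers, key=question.categories.index)
    except ValueError as exc:
        bad = [a for a in answers if a not in question.categories]
        raise ValueError(
            f"{question.question_id}: invalid categories {bad}") from exc


def compare_categorical(counts, question_id: str = "") -> GroupComparison:
    """Pearson chi-square on a group × category count table.

    2×2 tables get the Yates continuity correction; larger tables are
    uncorrected, df = (r−1)(c−1).  A structurally empty category (expected
    count 0) is an error; expected counts below 5 set a warning flag.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2-D table with at least 2 rows and columns")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("structural zero: a row or column total is 0")
    is_2x2 = table.shape == (2, 2)
    stat, p, df, expected = stats.chi2_contingency(table, correction=is_2x2)
    flags = {"expected_below_5"} if (expected < 5).any() else set()
    return GroupComparison(question_id=question_id, counts=table,
                           test="chisq_yates_2x2" if is_2x2 else "chisq_rxc",
                           statistic=float(stat), p=float(p), df=int(df),
                           flags=flags)


def compare_numeric(values_users, values_nonusers,
                    question_id: str = "",
                    exact_limit: int = 50) -> GroupComparison:
    """Two-sample Wilcoxon rank-sum test.

    The exact null distribution is used when the combined sample size is at
    most ``exact_limit`` and there are no ties; otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(values_users, dtype=float)
    y = np.asarray(values_nonusers, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = ("exact" if (combined.size <= exact_limit and no_ties)
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(question_id=question_id, counts=None,
                           test="wilcoxon", statistic=float(res.statistic),
                           p=float(min(res.pvalue, 1.0)))


def _resolved_answer(ind, question: ClinicalQuestion) -> Optional[str]:
    answers = ind.answers.get(question.question_id, [])
    return keep_most_severe(answers, question)


def question_counts(cohort: Cohort, question: ClinicalQuestion,
                    groups: Sequence[str] = (USER, NON_USER)) -> np.ndarray:
    """Group × category counts after the most-severe rule, missing excluded."""
    table = np.zeros((len(groups), len(question.categories)))
    for ind in cohort:
        if ind.usage_group not in groups:
            continue
        answer = _resolved_answer(ind, question)
        if answer is None:
            continue
        table[groups.index(ind.usage_group),
              question.categories.index(answer)] += 1
    return table


def _mean_sd(values: list[float]) -> str:
    if not values:
        return "–"
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return f"{arr.mean():.1f} ± {sd:.1f}"


def _pct_n(count: int, total: int) -> str:
    if total == 0:
        return "–"
    return f"{100.0 * count / total:.1f}% ({count})"


def summary_table(cohort: Cohort) -> dict[str, dict[str, str]]:
    """Demographics / clinical summary by usage group (Table-1 style).

    Numeric fields as mean ± SD (n−1 denominator); categorical and boolean
    fields as % (n) excluding missing; tablet-only column included.
    """
    groups = {"all": list(cohort),
              USER: [], NON_USER: [], TABLET_ONLY: []}
    for ind in cohort:
        groups[ind.usage_group].append(ind)
    out: dict[str, dict[str, str]] = {}

    def row(label):
        out[label] = {}
        return out[label]

    r = row("n")
    for g, members in groups.items():
        r[g] = str(len(members))
    r = row("age")
    for g, members in groups.items():
        r[g] = _mean_sd([i.age for i in members if i.age is not None])
    r = row("age_at_onset")
    for g, members in groups.items():
        r[g] = _mean_sd([i.age_at_onset for i in members
                         if i.age_at_onset is not None])
    for label, attr, true_value in [("male", "sex", "male"),
                                    ("chronic", "chronic", True),
                                    ("heredity", "heredity", True)]:
        r = row(label)
        for g, members in groups.items():
            known = [getattr(i, attr) for i in members
                     if getattr(i, attr) is not None]
            r[g] = _pct_n(sum(v == true_value for v in known), len(known))
    return out


def compare_all(cohort: Cohort,
                questions: Optional[dict[str, ClinicalQuestion]] = None
                ) -> list[GroupComparison]:
    """Run the user vs non-user comparison across the questionnaire.

    Categorical questions (including booleans recoded yes/no) use the
    chi-square rules; numeric survey fields and ages use Wilcoxon.
    """
    questions = questions if questions is not None else DEFAULT_QUESTIONS
    results: list[GroupComparison] = []
    for q in questions.values():
        table = question_counts(cohort, q)
        keep = table.sum(axis=0) > 0  # drop structurally empty categories
        if keep.sum() < 2:
            continue
        results.append(compare_categorical(table[:, keep], q.question_id))

    for label, getter in [
            ("chronic", lambda i: i.chronic), ("heredity", lambda i: i.heredity)]:
        counts = np.zeros((2, 2))
        for ind in cohort:
            if ind.usage_group not in (USER, NON_USER):
                continue
            v = getter(ind)
            if v is None:
                continue
            counts[0 if ind.usage_group == USER else 1, 1 if v else 0] += 1
        if counts.sum(axis=0).all() and counts.sum(axis=1).all():
            results.append(compare_categorical(counts, label))

    for label, getter in [("age", lambda i: i.age),
                          ("age_at_onset", lambda i: i.age_at_onset),
                          ("disease_duration",
                           lambda i: i.numerics.get("disease_duration"))]:
        users = [getter(i) for i in cohort
                 if i.usage_group == USER and getter(i) is not None]
        non_users = [getter(i) for i in cohort
                     if i.usage_group == NON_USER and getter(i) is not None]
        if users and non_users:
            results.append(compare_numeric(users, non_users, label))
    return results
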