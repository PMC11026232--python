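"""Effector-allele identification, cumulative scoring and score regression."""

import dataclasses

import numpy as np
import pytest

from oracles import grid_logistic_mle
from conftest import hand_cohort
from triptanpgx.association import AlleleCountTable
from triptanpgx.cohort import Cohort, Individual, NON_USER, USER
from triptanpgx.effector import (
    DATA_DRIVEN, OVERRIDE, EffectorSpec, TiedFrequencyError, compute_scores,
    default_effector_spec, identify_effector_alleles, score_regression,
)
from triptanpgx.logistic import SingularDesignError
from triptanpgx.simulate import default_config, generate_cohort
from triptanpgx.variants import REFERENCE_ALLELE_COUNTS


def reference_tables() -> dict[str, AlleleCountTable]:
    tables = {}
    for key in ("rs1024905", "rs6724624", "rs5443", "rs2651899",
                "5-HTTLPR:biallelic"):
        counts = REFERENCE_ALLELE_COUNTS[key]
        vid = "5-HTTLPR" if key.startswith("5-HTTLPR") else key
        tables[vid] = AlleleCountTable(
            vid, tuple(counts), {a: c[0] for a, c in counts.items()},
            {a: c[1] for a, c in counts.items()})
    return tables


class TestIdentification:
    def test_published_counts_reproduce_the_study_designation(self):
        spec = identify_effector_alleles(reference_tables())
        assert spec.alleles == {"rs1024905": "C", "rs6724624": "C",
                                "rs5443": "T", "rs2651899": "T",
                                "5-HTTLPR": "S"}
        assert all(src == DATA_DRIVEN for src in spec.sources.values())

    def test_effector_need_not_be_the_majority_allele(self):
        # rs5443 T: 28.9% in users vs 29.0% in non-users — minority in both,
        # but relatively more common in non-users, hence the effector.
        spec = identify_effector_alleles(
            {"rs5443": reference_tables()["rs5443"]})
        assert spec.alleles["rs5443"] == "T"

    def test_exact_tie_demands_an_override(self):
        tied = AlleleCountTable("v", ("A", "B"), {"A": 50, "B": 50},
                                {"A": 25, "B": 25})
        with pytest.raises(TiedFrequencyError):
            identify_effector_alleles({"v": tied})
        spec = identify_effector_alleles({"v": tied}, overrides={"v": "B"})
        assert spec.alleles["v"] == "B"
        assert spec.sources["v"] == OVERRIDE

    def test_override_beats_data_and_is_tagged(self):
        tables = reference_tables()
        spec = identify_effector_alleles(tables,
                                         overrides={"rs6724624": "C"})
        assert spec.alleles["rs6724624"] == "C"
        assert spec.sources["rs6724624"] == OVERRIDE

    def test_httlpr_effector_must_be_s(self):
        with pytest.raises(ValueError, match="bi-allelically"):
            EffectorSpec(alleles={"5-HTTLPR": "L_A"})


class TestScores:
    def test_hand_counted_example(self):
        # C/C, C/C, C/T, L_A/S, T/C with effectors (C, C, T, S, T):
        # 2 + 2 + 1 + 1 + 1 = 7
        cohort = hand_cohort()
        scores = compute_scores(cohort, default_effector_spec())
        assert scores["A1"] == 7

    def test_homozygous_effector_everywhere_scores_ten(self):
        g = {"rs1024905": ("C", "C"), "rs6724624": ("C", "C"),
             "rs5443": ("T", "T"), "5-HTTLPR": ("S", "S"),
             "rs2651899": ("T", "T")}
        cohort = Cohort([Individual("x", "male", 40.0, USER, genotypes=g)])
        assert compute_scores(cohort, default_effector_spec()) == {"x": 10}

    def test_missing_genotype_excludes_the_individual(self):
        cohort = hand_cohort()  # A3 has a missing rs1024905 call
        scores = compute_scores(cohort, default_effector_spec())
        assert "A3" not in scores and "A1" in scores

    def test_score_plus_noneffector_copies_conserved_at_ten(self, clean_cohort):
        spec = default_effector_spec()
        scores = compute_scores(clean_cohort, spec)
        from triptanpgx.effector import SCORE_VARIANTS, effector_copies
        for ind in clean_cohort:
            if ind.id not in scores:
                continue
            non_effector = sum(
                2 - effector_copies(ind.genotypes[v], v, spec)
                for v in SCORE_VARIANTS)
            assert scores[ind.id] + non_effector == 10

    def test_adding_one_effector_copy_raises_score_by_one(self):
        spec = default_effector_spec()
        g = {"rs1024905": ("G", "C"), "rs6724624": ("C", "G"),
             "rs5443": ("C", "T"), "5-HTTLPR": ("L_A", "S"),
             "rs2651899": ("T", "C")}
        base = compute_scores(
            Cohort([Individual("x", "male", 40.0, USER, genotypes=dict(g))]),
            spec)["x"]
        bumped = dict(g, rs1024905=("C", "C"))
        assert compute_scores(
            Cohort([Individual("x", "male", 40.0, USER, genotypes=bumped)]),
            spec)["x"] == base + 1

    def test_spec_cohort_mismatch_raises(self):
        cohort = hand_cohort()
        with pytest.raises(ValueError, match="lacks"):
            compute_scores(cohort, EffectorSpec(alleles={"rs1024905": "C"}))


class TestRegression:
    def test_estimates_match_grid_oracle_on_small_fixture(self):
        cohort = generate_cohort(default_config(
            60, seed=23, tablet_only_fraction=0.0, missing_rate={}))
        scores = compute_scores(cohort, default_effector_spec())
        res = score_regression(cohort, scores)
        X = np.array([[1.0, scores[i.id], 1.0 if i.sex == "male" else 0.0,
                       i.age] for i in cohort if i.id in scores])
        y = np.array([1.0 if i.usage_group == NON_USER else 0.0
                      for i in cohort if i.id in scores])
        # age in years needs a wider, asymmetric search box for the intercept
        Xs = X.copy()
        Xs[:, 3] /= 50.0
        coef_oracle, _ = grid_logistic_mle(Xs, y, half_width=8.0)
        coef_oracle[3] /= 50.0
        assert np.allclose(res.fit.coef, coef_oracle, atol=1e-4)

    def test_constant_score_is_singular(self):
        inds = [Individual(f"i{k}", "male", 40.0 + k,
                           USER if k % 2 else NON_USER, genotypes={})
                for k in range(12)]
        with pytest.raises(SingularDesignError):
            score_regression(Cohort(inds), {i.id: 5 for i in inds},
                             covariates=("age",))

    def test_direction_consistency_with_data_driven_spec(self):
        """In-sample effector choice makes the fitted score slope positive."""
        from triptanpgx.association import count_alleles
        from triptanpgx.effector import identify_effector_alleles
        cohort = generate_cohort(default_config(
            3000, seed=31, tablet_only_fraction=0.0, missing_rate={}))
        tables = {v: count_alleles(cohort, v,
                                   "biallelic" if v == "5-HTTLPR" else "raw")
                  for v in cohort.variants}
        spec = identify_effector_alleles(tables)
        res = score_regression(cohort, compute_scores(cohort, spec))
        assert res.coefficients["score"] > 0

    def test_recovers_generating_coefficient_in_expectation(self):
        """Mean estimate over replicates near the generating 0.204 slope."""
        cfg = default_config(489, seed=0, tablet_only_fraction=0.0,
                             missing_rate={})
        spec = default_effector_spec()
        estimates = []
        for i in range(40):
            cohort = generate_cohort(dataclasses.replace(cfg, seed=100 + i))
            res = score_regression(cohort, compute_scores(cohort, spec))
            estimates.append(res.coefficients["score"])
        mean = np.mean(estimates)
        mcse = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.204) < 3 * mcse
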