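"""Allele counting, HWE, crude and adjusted association, Bonferroni."""

import numpy as np
import pytest

from oracles import grid_logistic_mle, hwe_enumeration_p
from conftest import hand_cohort
from triptanpgx.association import (
    AlleleCountTable, additive_logistic, bonferroni, call_rate, count_alleles,
    crude_allelic_or, format_corrected_p, genotypic_logistic, hwe_exact_test,
    round_half_up,
)
from triptanpgx.cohort import Cohort, Individual, NON_USER, USER
from triptanpgx.logistic import SeparationError, SingularDesignError
from triptanpgx.variants import REFERENCE_ALLELE_COUNTS


def reference_table(key: str) -> AlleleCountTable:
    counts = REFERENCE_ALLELE_COUNTS[key]
    alleles = tuple(counts)
    return AlleleCountTable(key, alleles,
                            users={a: c[0] for a, c in counts.items()},
                            non_users={a: c[1] for a, c in counts.items()})


class TestCountAlleles:
    def test_enumeration_on_three_users(self):
        inds = [Individual(f"i{k}", "male", 40.0, USER,
                           genotypes={"rs1024905": g})
                for k, g in enumerate([("G", "G"), ("G", "C"), ("C", "C")])]
        inds.append(Individual("n1", "female", 50.0, NON_USER,
                               genotypes={"rs1024905": ("G", "C")}))
        table = count_alleles(Cohort(inds), "rs1024905")
        assert table.users == {"G": 3, "C": 3}
        assert table.percentage(USER, "G") == 50.0

    def test_missing_and_tablet_only_are_excluded(self):
        cohort = hand_cohort()
        table = count_alleles(cohort, "rs1024905")
        # A3 missing, A4 tablet-only: 2 users + 2 non-users remain
        assert table.total(USER) == 4 and table.total(NON_USER) == 4

    def test_empty_group_percentage_is_undefined(self):
        inds = [Individual("u", "male", 40.0, USER,
                           genotypes={"rs5443": ("C", "T")})]
        table = count_alleles(Cohort(inds), "rs5443")
        assert table.total(NON_USER) == 0
        assert table.percentage(NON_USER, "C") is None

    def test_unknown_variant_raises(self):
        with pytest.raises(KeyError):
            count_alleles(hand_cohort(), "rs0")

    def test_biallelic_recoding_collapses_httlpr(self):
        table = count_alleles(hand_cohort(), "5-HTTLPR", "biallelic")
        assert set(table.alleles) == {"L", "S"}

    def test_rounding_is_half_up(self):
        assert round_half_up(41.55, 1) == 41.6
        assert round_half_up(53.44, 1) == 53.4


class TestCallRate:
    def test_complete_and_empty(self, small_cohort):
        inds = [Individual("a", "male", 40.0, USER,
                           genotypes={"rs5443": ("C", "C")}),
                Individual("b", "male", 41.0, USER,
                           genotypes={"rs5443": None})]
        assert call_rate(Cohort(inds), "rs5443") == 0.5
        assert call_rate(Cohort(inds[:1]), "rs5443") == 1.0

    def test_direct_division(self):
        inds = ([Individual(f"c{i}", "male", 40.0, USER,
                            genotypes={"rs5443": ("C", "C")})
                 for i in range(532)]
                + [Individual(f"m{i}", "male", 40.0, USER,
                              genotypes={"rs5443": None}) for i in range(13)])
        assert call_rate(Cohort(inds), "rs5443") == pytest.approx(532 / 545)


class TestHWE:
    def test_modal_configuration_gives_p_one(self):
        assert hwe_exact_test((2, 4, 2)) == pytest.approx(1.0)

    def test_zero_heterozygotes_is_extreme(self):
        assert hwe_exact_test((5, 0, 5)) < 0.05

    def test_monomorphic_is_trivially_in_equilibrium(self):
        assert hwe_exact_test((17, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test((-1, 2, 3))

    @pytest.mark.parametrize("counts", [
        (2, 4, 2), (5, 0, 5), (1, 9, 2), (8, 4, 8), (0, 12, 0), (3, 7, 10),
    ])
    def test_matches_full_enumeration_oracle(self, counts):
        assert hwe_exact_test(counts) == pytest.approx(
            hwe_enumeration_p(*counts), abs=1e-12)

    def test_triallelic_permutation_test_is_seeded_and_calibrated(self):
        rng = np.random.default_rng(5)
        # genotype counts drawn near HWE for allele freqs (.5, .3, .2)
        mat = [[25, 30, 20], [0, 9, 12], [0, 0, 4]]
        p1 = hwe_exact_test(mat, rng=np.random.default_rng(5), n_perm=2000)
        p2 = hwe_exact_test(mat, rng=np.random.default_rng(5), n_perm=2000)
        assert p1 == p2
        assert p1 > 0.05  # HWE-consistent table should not be rejected


class TestCrudeOR:
    def test_cross_product_from_reference_counts(self):
        res = crude_allelic_or(reference_table("rs1024905"))
        assert res.effect_allele == "C"
        assert res.odds_ratio == pytest.approx((125 * 435) / (89 * 379))

    def test_identical_distributions_give_unit_or(self):
        t = AlleleCountTable("v", ("A", "B"), {"A": 40, "B": 60},
                             {"A": 20, "B": 30})
        assert crude_allelic_or(t).odds_ratio == pytest.approx(1.0)

    def test_swapping_groups_inverts_the_or(self):
        t = reference_table("rs1024905")
        swapped = AlleleCountTable("v", t.alleles, t.non_users, t.users)
        assert (crude_allelic_or(swapped, "C").odds_ratio
                == pytest.approx(1 / crude_allelic_or(t, "C").odds_ratio))

    def test_zero_cell_gets_haldane_anscombe_correction(self):
        t = AlleleCountTable("v", ("A", "B"), {"A": 0, "B": 50},
                             {"A": 5, "B": 45})
        res = crude_allelic_or(t, "A")
        assert "haldane_anscombe" in res.flags
        assert np.isfinite(res.odds_ratio)


class TestAdditiveLogistic:
    def test_or_direction_matches_crude_on_clean_cohort(self, clean_cohort):
        crude = crude_allelic_or(count_alleles(clean_cohort, "rs1024905"))
        adjusted = additive_logistic(clean_cohort, "rs1024905")
        assert adjusted.effect_allele == crude.effect_allele
        # sex is independent of genotype in simulation: close agreement
        assert adjusted.odds_ratio == pytest.approx(crude.odds_ratio, rel=0.1)

    def test_fit_matches_likelihood_grid_oracle(self, clean_cohort):
        res = additive_logistic(clean_cohort, "rs5443")
        fit = res.fit
        # rebuild the design the module used and maximise independently
        X = np.empty((fit.n, 3))
        y = np.empty(fit.n)
        k = 0
        for ind in clean_cohort:
            g = ind.genotypes.get("rs5443")
            if ind.usage_group not in (USER, NON_USER) or g is None:
                continue
            X[k] = (1.0, g.count(res.effect_allele),
                    1.0 if ind.sex == "male" else 0.0)
            y[k] = 1.0 if ind.usage_group == NON_USER else 0.0
            k += 1
        coef_oracle, _ = grid_logistic_mle(X[:k], y[:k])
        assert np.allclose(fit.coef, coef_oracle, atol=1e-4)

    def test_all_same_outcome_is_separation(self):
        inds = [Individual(f"i{k}", "male", 40.0, USER,
                           genotypes={"rs5443": ("C", "T")})
                for k in range(10)]
        with pytest.raises(SeparationError):
            additive_logistic(Cohort(inds), "rs5443")


class TestGenotypicLogistic:
    def test_constant_genotype_flagged_singular(self):
        inds = [Individual(f"i{k}", "male", 40.0,
                           USER if k % 2 else NON_USER,
                           genotypes={"rs5443": ("C", "C")})
                for k in range(10)]
        with pytest.raises(ValueError, match="identical"):
            genotypic_logistic(Cohort(inds), "rs5443")

    def test_two_genotype_fixture_reduces_to_one_contrast(self):
        rng = np.random.default_rng(2)
        inds = []
        for k in range(60):
            g = ("C", "C") if k % 2 else ("C", "T")
            grp = NON_USER if rng.random() < 0.3 + 0.2 * (k % 2) else USER
            inds.append(Individual(f"i{k}", "male", 40.0, grp,
                                   genotypes={"rs5443": g}))
        res = genotypic_logistic(Cohort(inds), "rs5443", covariates=())
        assert res.extra["lr_df"] == 1

    def test_lr_statistic_matches_nested_likelihood_oracle(self, clean_cohort):
        res = genotypic_logistic(clean_cohort, "rs5443")
        fit = res.fit
        rows = []
        y = []
        for ind in clean_cohort:
            g = ind.genotypes.get("rs5443")
            if ind.usage_group not in (USER, NON_USER) or g is None:
                continue
            rows.append((g, 1.0 if ind.sex == "male" else 0.0))
            y.append(1.0 if ind.usage_group == NON_USER else 0.0)
        genos = sorted({g for g, _ in rows})
        ref = ("C", "C")
        contrasts = [g for g in genos if g != ref]
        X_full = np.array([[1.0, *[1.0 if g == c else 0.0 for c in contrasts], s]
                           for g, s in rows])
        X_red = np.array([[1.0, s] for _, s in rows])
        y = np.array(y)
        _, ll_full = grid_logistic_mle(X_full, y)
        _, ll_red = grid_logistic_mle(X_red, y)
        assert res.extra["lr_stat"] == pytest.approx(
            2 * (ll_full - ll_red), abs=1e-6)


class TestBonferroni:
    @pytest.mark.parametrize("p, expected", [
        (0.002, 0.010), (0.129, 0.645), (0.048, 0.240), (0.158, 0.790),
        (0.0, 0.0),
    ])
    def test_times_five_correction(self, p, expected):
        assert bonferroni(p, 5) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.933, 0.929])
    def test_rendering_caps_above_one(self, p):
        assert format_corrected_p(p, 5) == "> 1.0"
        assert bonferroni(p, 5) == 1.0

    def test_monotone_and_idempotent_at_bounds(self):
        grid = np.linspace(0, 1, 21)
        corrected = [bonferroni(p, 5) for p in grid]
        assert all(a <= b for a, b in zip(corrected, corrected[1:]))
        assert all(bonferroni(p, 3) <= c for p, c in zip(grid, corrected))
        assert bonferroni(0.0, 7) == 0.0
        assert bonferroni(0.6, 2) == 1.0  # p >= 1/m saturates


class TestWaldCoverage:
    def test_ci_coverage_on_synthetic_dosage_cohorts(self):
        """95% Wald CIs cover a known dosage log-OR at the nominal rate."""
        rng = np.random.default_rng(12345)
        true_beta = 0.35
        n, reps, covered = 2000, 500, 0
        from triptanpgx.logistic import fit_logistic
        for _ in range(reps):
            dosage = rng.binomial(2, 0.4, size=n).astype(float)
            sex = rng.binomial(1, 0.65, size=n).astype(float)
            eta = -1.3 + true_beta * dosage - 0.5 * sex
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(n), dosage, sex])
            fit = fit_logistic(X, y)
            lo, hi = fit.ci()[1]
            covered += lo <= true_beta <= hi
        assert 0.92 <= covered / reps <= 0.97
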