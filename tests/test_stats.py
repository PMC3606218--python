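"""Lobar aggregation, covaried models and difference reporting."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tractconn.atlas import Parcellation
from tractconn.connectome import ConnectionMatrix
from tractconn.edge_filter import EdgeMask
from tractconn.phantoms import CohortConfig, simulate_cohort
from tractconn.reference import GLOBAL_PCT, REPORTED_DIFFERENCES
from tractconn.stats import (
    adjusted_group_means,
    age_regressions,
    aggregate_to_lobes,
    ancova_group_difference,
    correct_multiple,
    difference_percentages,
    lobar_analysis,
    lobar_connection_families,
    mancova_wilks,
    regional_posthoc,
)


# ----------------------------------------------------------------------
# independent normal-equations oracle (kept free of statsmodels)


def oracle_partial_f(y, X_full, drop_col):
    """Extra-sum-of-squares F test for one column via normal equations."""
    X0 = np.delete(X_full, drop_col, axis=1)

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    n, k = X_full.shape
    rss_full, rss_0 = rss(X_full), rss(X0)
    F = (rss_0 - rss_full) / (rss_full / (n - k))
    p = scipy.stats.f.sf(F, 1, n - k)
    return F, p


def random_subjects(rng, n):
    return pd.DataFrame(
        dict(
            id=[f"s{i}" for i in range(n)],
            group=["control"] * (n // 2) + ["patient"] * (n - n // 2),
            age=rng.uniform(7, 25, n),
            sex=rng.integers(0, 2, n),
        )
    )


def _design(subjects):
    g = (subjects["group"] == "patient").astype(float).to_numpy()
    return np.column_stack(
        [np.ones(len(subjects)), g, subjects["age"].to_numpy(), subjects["sex"].to_numpy(float)]
    )


class TestAncova:
    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 21))
            subjects = random_subjects(rng, n)
            if subjects.groupby("group")["sex"].nunique().min() == 0:
                continue
            y = rng.normal(size=n)
            res = ancova_group_difference(y, subjects)
            F, p = oracle_partial_f(y, _design(subjects), 1)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_zero_noise_equal_means_f_zero(self):
        rng = np.random.default_rng(1)
        subjects = random_subjects(rng, 20)
        y = 2.0 + 0.1 * subjects["age"].to_numpy()  # no group signal at all
        res = ancova_group_difference(y, subjects)
        assert res.F == pytest.approx(0.0, abs=1e-16)

    def test_single_subject_group_rejected(self):
        rng = np.random.default_rng(2)
        subjects = random_subjects(rng, 10)
        subjects.loc[subjects.index[1:], "group"] = "patient"
        with pytest.raises(ValueError):
            ancova_group_difference(rng.normal(size=10), subjects)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        subjects = random_subjects(rng, 12)
        subjects["age"] = 10.0  # constant covariate: collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            ancova_group_difference(rng.normal(size=12), subjects)

    def test_planted_reduction_detected_in_majority(self):
        # 10% group reduction, 12% subject noise, n=30/30
        rng = np.random.default_rng(4)
        hits = 0
        reps = 40
        for _ in range(reps):
            subjects = random_subjects(rng, 60)
            g = (subjects["group"] == "patient").to_numpy()
            y = 47000 * np.where(g, 0.9, 1.0) * rng.lognormal(0, 0.115, 60)
            if ancova_group_difference(y, subjects).p < 0.05:
                hits += 1
        assert hits / reps > 0.5


class TestMancova:
    def test_single_response_reduces_to_ancova(self):
        rng = np.random.default_rng(5)
        subjects = random_subjects(rng, 24)
        subjects["total_fibers"] = rng.normal(47000, 5000, 24)
        y = rng.normal(size=24)
        uni = ancova_group_difference(y, subjects, ("age", "sex", "total_fibers"))
        multi = mancova_wilks(y[:, None], subjects)
        assert multi.F == pytest.approx(uni.F, abs=1e-8)
        assert multi.p == pytest.approx(uni.p, abs=1e-8)

    def test_agrees_with_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 30
            subjects = random_subjects(rng, n)
            subjects["total_fibers"] = rng.normal(0, 1, n)
            Y = rng.normal(size=(n, 3))
            mine = mancova_wilks(Y, subjects)
            X = np.column_stack(
                [
                    np.ones(n),
                    (subjects["group"] == "patient").astype(float),
                    subjects["age"],
                    subjects["sex"].astype(float),
                    subjects["total_fibers"],
                ]
            )
            mv = MANOVA(Y, X)
            L = np.zeros((1, 5))
            L[0, 1] = 1.0
            tbl = mv.mv_test(hypotheses=[("group", L, None)])
            stat = tbl.results["group"]["stat"]
            assert mine.wilks_lambda == pytest.approx(
                float(stat.loc["Wilks' lambda", "Value"]), abs=1e-8
            )
            assert mine.p == pytest.approx(
                float(stat.loc["Wilks' lambda", "Pr > F"]), abs=1e-8
            )

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(2000):
            n = 30
            subjects = random_subjects(rng, n)
            subjects["total_fibers"] = rng.normal(0, 1, n)
            Y = rng.normal(size=(n, 3))
            ps.append(mancova_wilks(Y, subjects).p)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_too_many_responses_rejected(self):
        rng = np.random.default_rng(8)
        subjects = random_subjects(rng, 10)
        subjects["total_fibers"] = rng.normal(size=10)
        with pytest.raises(ValueError, match="subjects"):
            mancova_wilks(rng.normal(size=(10, 8)), subjects)


class TestAggregation:
    def _toy(self):
        table = pd.DataFrame(
            dict(
                id=[1, 2, 3, 4],
                name=["a", "b", "c", "d"],
                hemisphere=["L", "L", "L", "L"],
                lobe=["frontal", "frontal", "temporal", "temporal"],
                cls=["cortical"] * 4,
                excluded=[False] * 4,
            )
        )
        parc = Parcellation(roi_table=table)
        count = np.array(
            [[2, 5, 1, 0], [5, 0, 3, 4], [1, 3, 6, 7], [0, 4, 7, 0]], dtype=np.int64
        )
        cm = ConnectionMatrix("t", count, count / 10.0, np.full((4, 4), 0.5))
        return parc, cm

    def test_hand_aggregation_oracle(self):
        parc, cm = self._toy()
        lob = aggregate_to_lobes(cm, parc)
        units = lob.units
        f = units.index(("frontal", "L"))
        t = units.index(("temporal", "L"))
        # hand sums: intra-frontal 2+5+0, intra-temporal 6+7+0, cross 1+0+3+4
        assert lob.count[f, f] == 7
        assert lob.count[t, t] == 13
        assert lob.count[f, t] == 8

    def test_conservation_under_no_mask(self):
        parc, cm = self._toy()
        lob = aggregate_to_lobes(cm, parc)
        assert lob.total() == cm.total_fibers()

    def test_masked_cell_reduces_lobar_cell_exactly(self):
        parc, cm = self._toy()
        keep = np.ones((4, 4), bool)
        keep[0, 2] = keep[2, 0] = False  # exclude the count=1 cross cell
        mask = EdgeMask(keep=keep, threshold=0.1, stop_quantile=1.0)
        lob = aggregate_to_lobes(cm, parc, mask)
        units = lob.units
        f, t = units.index(("frontal", "L")), units.index(("temporal", "L"))
        assert lob.count[f, t] == 8 - 1

    def test_families_counts(self, atlas70):
        fams = lobar_connection_families(atlas70.lobar_units())
        assert len(fams["right_hemisphere"]) == 15
        assert len(fams["left_hemisphere"]) == 15
        assert len(fams["inter_hemisphere"]) == 25


class TestDifferences:
    @pytest.mark.parametrize(
        "absolute, relative",
        [(row[2], row[3]) for row in REPORTED_DIFFERENCES],
    )
    def test_reported_rows_satisfy_relative_identity(self, absolute, relative):
        rep = difference_percentages(absolute, 100.0, GLOBAL_PCT)
        assert rep.absolute_pct == pytest.approx(absolute, abs=1e-12)
        assert rep.relative_pct == pytest.approx(relative, abs=1e-9)

    def test_identity_holds_exactly(self):
        rep = difference_percentages(56.1, 100.0, 90.0)
        assert rep.relative_pct - rep.absolute_pct + rep.global_pct == pytest.approx(0, abs=1e-12)

    def test_equal_to_global_gives_zero_relative(self):
        rep = difference_percentages(90.0, 100.0, 90.0)
        assert rep.relative_pct == pytest.approx(0.0)

    def test_zero_control_mean_reported_missing(self):
        assert difference_percentages(5.0, 0.0, 90.0) is None

    def test_adjusted_means_recover_group_shift(self):
        rng = np.random.default_rng(9)
        subjects = random_subjects(rng, 40)
        g = (subjects["group"] == "patient").to_numpy()
        y = 100.0 + 3.0 * subjects["age"].to_numpy() - 10.0 * g
        pt, ct = adjusted_group_means(y, subjects)
        assert pt - ct == pytest.approx(-10.0, abs=1e-9)


class TestCorrections:
    def test_bh_step_up_hand_case(self):
        flags = correct_multiple([0.01, 0.02, 0.03], "fdr_bh", 0.05)
        assert flags.all()  # 0.03 <= 3/3*0.05, step-up keeps all

    def test_single_p_bonferroni(self):
        assert correct_multiple([0.04], "bonferroni", 0.05).all()

    def test_bonferroni_two_tests_both_fail(self):
        flags = correct_multiple([0.04, 0.04], "bonferroni", 0.05)
        assert not flags.any()  # 0.04 > 0.025

    def test_empty_input(self):
        assert correct_multiple([], "fdr_bh").size == 0


class TestAgeRegressions:
    def _subjects(self, rng, n=20):
        df = random_subjects(rng, n)
        df["white_matter_volume"] = rng.normal(4e5, 1e4, n)
        df["mean_fa"] = rng.normal(0.45, 0.02, n)
        df["total_fibers"] = rng.normal(47000, 5000, n)
        return df

    def test_perfect_line_r_one(self):
        rng = np.random.default_rng(10)
        df = self._subjects(rng)
        df["mean_fa"] = 2.0 * df["age"]
        res = age_regressions(df, measures=("mean_fa",))
        assert all(r.R == pytest.approx(1.0) for r in res)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(200):
            res = age_regressions(self._subjects(rng), measures=("total_fibers",))
            rs.extend(r.R for r in res)
        assert abs(np.mean(rs)) < 0.05

    def test_constant_age_rejected(self):
        rng = np.random.default_rng(12)
        df = self._subjects(rng)
        df["age"] = 14.0
        with pytest.raises(ValueError, match="age"):
            age_regressions(df)

    def test_one_sided_halves_p(self):
        rng = np.random.default_rng(13)
        df = self._subjects(rng)
        two = age_regressions(df, measures=("mean_fa",))
        one = age_regressions(df, measures=("mean_fa",), one_sided=True)
        for a, b in zip(two, one):
            assert b.p == pytest.approx(a.p / 2)


class TestCohortLevel:
    def test_null_cohort_type_one_error_nominal(self):
        # exchangeable groups: the covaried ANCOVA rejects at ~alpha
        rng = np.random.default_rng(14)
        rejections = 0
        reps = 400
        for _ in range(reps):
            subjects = random_subjects(rng, 60)
            y = 47000 * rng.lognormal(0, 0.115, 60)
            if ancova_group_difference(y, subjects).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_lobar_analysis_shapes_and_flags(self, small_cohort, atlas70):
        subjects, matrices = small_cohort
        res = lobar_analysis(subjects, matrices, atlas70)
        assert len(res["connection_tests"]) == 55
        assert len(res["mancovas"]) == 3
        assert {m.family for m in res["mancovas"]} == {
            "right_hemisphere", "left_hemisphere", "inter_hemisphere",
        }
        for t in res["connection_tests"]:
            assert 0.0 <= t.p <= 1.0 and t.F >= 0.0
        for r in res["difference_reports"]:
            assert r.relative_pct == pytest.approx(
                r.absolute_pct - r.global_pct, abs=1e-9
            )

    def test_planted_deficit_flagged_negative_relative(self, atlas70):
        cfg = CohortConfig(
            seed=21,
            n_per_group=30,
            edge_effects={("frontal-L", "temporal-L"): 0.62},
        )
        subjects, matrices = simulate_cohort(cfg, atlas70)
        res = lobar_analysis(subjects, matrices, atlas70)
        rep = next(
            r for r in res["difference_reports"]
            if set(r.connection.split(":")) == {"frontal-L", "temporal-L"}
        )
        assert rep.relative_pct < -15

    def test_regional_posthoc_excludes_unreliable_parcels(self, small_cohort, atlas70):
        subjects, matrices = small_cohort
        units = atlas70.lobar_units()
        pair = (units.index(("frontal", "L")), units.index(("temporal", "L")))
        tests, reports = regional_posthoc(subjects, matrices, atlas70, [pair])
        assert len(tests) > 0
        banned = {"lh.frontalpole", "lh.temporalpole", "lh.bankssts"}
        for t in tests:
            assert t.connection.split("|")[0] not in banned

    def test_regional_posthoc_empty_significant_set(self, small_cohort, atlas70):
        subjects, matrices = small_cohort
        assert regional_posthoc(subjects, matrices, atlas70, []) == ([], [])
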