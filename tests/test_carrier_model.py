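"""Design-matrix construction, logistic fitting, prediction and AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vusclinlr.datamodel import CohortConfig, cohort_to_frame
from vusclinlr.model import (
    DESIGN_COLUMNS,
    CoefficientSet,
    FitError,
    auc_mann_whitney,
    build_design,
    design_matrix,
    fit,
    null_probability,
    predict,
    wald_ci,
)

from conftest import make_proband


def zero_coeffs(r0=0.015, **beta):
    b = {c: 0.0 for c in DESIGN_COLUMNS}
    b.update(beta)
    return CoefficientSet(gene="BRCA1", race_group="european_mixed",
                          intercept=0.0, beta=b, r0=r0)


class TestDesignVector:
    def test_tn_breast_cancer_at_45_with_heavy_family_history(self):
        p = make_proband(bc={"age_dx": 45, "tn_status": "tn_pos"},
                         fam={"n_bc_lt50": 5})
        x = build_design(p)
        on = {k for k, v in x.items() if v}
        assert on == {"tn_pos_lt50", "fam_bc_lt50_3plus"}

    def test_unaffected_proband_is_zero_vector(self):
        x = build_design(make_proband())
        assert set(x.values()) == {0}

    def test_male_er_positive_bc_at_60_sets_both_indicators(self):
        p = make_proband(sex="male",
                         bc={"age_dx": 60, "tn_status": "tn_neg", "male_bc": True})
        x = build_design(p)
        on = {k for k, v in x.items() if v}
        assert on == {"male_bc", "tn_neg_ge50"}

    def test_age_cut_boundaries(self):
        x = build_design(make_proband(bc={"age_dx": 50, "tn_status": "tn_unknown"}))
        assert x["tn_unk_ge50"] == 1 and x["tn_unk_lt50"] == 0
        x = build_design(make_proband(oc_age=60))
        assert x["ov_ge60"] == 1 and x["ov_lt60"] == 0

    def test_bilateral_and_dcis_are_additional_indicators(self):
        p = make_proband(dcis=True,
                         bc={"age_dx": 40, "tn_status": "tn_unknown", "bilateral": True})
        x = build_design(p)
        on = {k for k, v in x.items() if v}
        assert on == {"dcis", "tn_unk_lt50", "bilateral_bc"}

    @settings(deadline=None, max_examples=50)
    @given(
        bc_lt50=st.integers(0, 8), bc_ge50=st.integers(0, 8),
        oc_lt60=st.integers(0, 5), panc=st.integers(0, 5),
        mbc=st.integers(0, 3), prostate=st.integers(0, 5),
    )
    def test_family_blocks_have_at_most_one_indicator_set(
            self, bc_lt50, bc_ge50, oc_lt60, panc, mbc, prostate):
        p = make_proband(fam={
            "n_bc_lt50": bc_lt50, "n_bc_ge50": bc_ge50, "n_oc_lt60": oc_lt60,
            "n_pancreatic": panc, "n_mbc": mbc, "n_prostate": prostate,
        })
        x = build_design(p)
        blocks = {
            "fam_bc_lt50": (bc_lt50, ["fam_bc_lt50_1", "fam_bc_lt50_2", "fam_bc_lt50_3plus"]),
            "fam_bc_ge50": (bc_ge50, ["fam_bc_ge50_1", "fam_bc_ge50_2", "fam_bc_ge50_3plus"]),
            "fam_oc_lt60": (oc_lt60, ["fam_oc_lt60_1", "fam_oc_lt60_2plus"]),
            "fam_panc": (panc, ["fam_panc_1", "fam_panc_2plus"]),
            "fam_prostate": (prostate, ["fam_prostate_1", "fam_prostate_2plus"]),
        }
        for _, (count, cols) in blocks.items():
            assert sum(x[c] for c in cols) == (1 if count >= 1 else 0)
        assert x["fam_mbc"] == (1 if mbc >= 1 else 0)

    def test_vectorized_matrix_matches_per_proband_build(self):
        probands = [
            make_proband("a", bc={"age_dx": 45, "tn_status": "tn_pos"}, oc_age=55),
            make_proband("b", sex="male", pr_age=70, pancreatic=True),
            make_proband("c", fam={"n_bc_ge50": 2, "n_oc_ge60": 3}),
        ]
        X = design_matrix(cohort_to_frame(probands))
        for i, p in enumerate(probands):
            assert dict(X.iloc[i]) == build_design(p)


class TestFit:
    def two_by_two_cohort(self):
        # exposed cases 30, unexposed cases 10, exposed controls 100,
        # unexposed controls 300 -> cross-product OR = 9.0
        cohort = []
        k = 0

        def add(n, exposed, case):
            nonlocal k
            for _ in range(n):
                cohort.append(make_proband(
                    f"p{k}", pancreatic=exposed,
                    brca1="pathogenic" if case else "none"))
                k += 1

        add(30, True, True)
        add(10, False, True)
        add(100, True, False)
        add(300, False, False)
        return cohort

    def test_saturated_2x2_recovers_cross_product_odds_ratio(self):
        coeffs = fit(self.two_by_two_cohort(), "BRCA1", "european_mixed",
                     compute_auc=False)
        assert math.exp(coeffs.beta["pancreatic"]) == pytest.approx(9.0, rel=1e-5)

    def test_r0_is_exact_case_fraction(self):
        coeffs = fit(self.two_by_two_cohort(), "BRCA1", "european_mixed",
                     compute_auc=False)
        assert coeffs.r0 == 40 / 440
        assert (coeffs.n_cases, coeffs.n_controls) == (40, 400)

    def test_published_null_probability_bookkeeping(self):
        assert round(null_probability(1706, 108602), 3) == 0.015

    def test_never_exposed_indicator_dropped_and_flagged(self):
        coeffs = fit(self.two_by_two_cohort(), "BRCA1", "european_mixed",
                     compute_auc=False)
        assert "ov_lt60" in coeffs.dropped
        assert coeffs.beta["ov_lt60"] == 0.0

    def test_single_class_raises(self):
        cohort = [make_proband(f"p{i}") for i in range(10)]
        with pytest.raises(FitError):
            fit(cohort, "BRCA1", "european_mixed")

    def test_vus_and_vlp_carriers_never_enter_the_fit(self):
        cohort = self.two_by_two_cohort()
        spiked = cohort + [
            make_proband("v1", brca1="vus", pancreatic=True),
            make_proband("v2", brca1="vlp", pancreatic=True),
        ]
        a = fit(cohort, "BRCA1", "european_mixed", compute_auc=False)
        b = fit(spiked, "BRCA1", "european_mixed", compute_auc=False)
        assert a.beta == b.beta and a.r0 == b.r0

    def test_wald_ci_covers_point_estimate(self):
        coeffs = fit(self.two_by_two_cohort(), "BRCA1", "european_mixed",
                     compute_auc=False)
        lo, hi = wald_ci(coeffs, "pancreatic")
        assert lo < coeffs.beta["pancreatic"] < hi


class TestPredict:
    def test_zero_vector_gives_logistic_of_intercept(self):
        c = zero_coeffs()
        c.intercept = -1.0
        assert predict(c, {}) == pytest.approx(1 / (1 + math.exp(1.0)))

    def test_single_log9_beta_gives_point_nine(self):
        c = zero_coeffs(dcis=math.log(9.0))
        assert predict(c, {"dcis": 1}) == pytest.approx(0.9, abs=1e-12)

    def test_positive_beta_indicator_never_decreases_risk(self):
        c = zero_coeffs(ov_lt60=1.3, dcis=0.2)
        base = {"dcis": 1}
        assert predict(c, {**base, "ov_lt60": 1}) > predict(c, base)

    def test_coefficient_json_round_trip(self, tmp_path):
        c = zero_coeffs(tn_pos_lt50=2.5)
        c.covariance = np.eye(2)
        c.param_names = ("intercept", "tn_pos_lt50")
        back = CoefficientSet.from_dict(c.to_dict())
        assert back.beta == c.beta
        assert np.array_equal(back.covariance, c.covariance)


class TestAuc:
    def test_perfect_separation_scores_one(self):
        labels = [True] * 5 + [False] * 5
        scores = [2, 3, 4, 5, 6, -1, 0, 1, 1.5, 1.9]
        a, _ = auc_mann_whitney(labels, scores)
        assert a == 1.0

    def test_uninformative_scores_near_half(self, rng):
        n = 10000
        labels = rng.random(n) < 0.3
        scores = rng.normal(size=n)
        a, (lo, hi) = auc_mann_whitney(labels, scores)
        se = (hi - lo) / (2 * 1.96)
        assert abs(a - 0.5) < 3 * max(se, 1e-3)

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.random(500) < 0.2
        scores = rng.integers(0, 5, size=500).astype(float)  # heavy ties
        a, _ = auc_mann_whitney(labels, scores)
        assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(FitError):
            auc_mann_whitney([True, True], [1.0, 2.0])
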