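"""Individual likelihood ratios and per-variant aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vusclinlr.datamodel import cohort_to_frame
from vusclinlr.evidence import (
    combine_variant,
    individual_lr,
    score_cohort,
)
from vusclinlr.io import IntegrityError
from vusclinlr.datamodel import VariantObservation
from vusclinlr.model import DESIGN_COLUMNS, CoefficientSet

from conftest import make_proband


def brute_force_combined(rk_r0_pairs):
    """Independent oracle: direct product of the defining formula."""
    out = 1.0
    for rk, r0 in rk_r0_pairs:
        out *= (rk * (1 - r0)) / ((1 - rk) * r0)
    return out


def flat_coeffs(r0, race="european_mixed", gene="BRCA1", **beta):
    b = {c: 0.0 for c in DESIGN_COLUMNS}
    b.update(beta)
    return CoefficientSet(gene=gene, race_group=race,
                          intercept=math.log(r0 / (1 - r0)), beta=b, r0=r0)


class TestIndividualLR:
    def test_null_individual_contributes_no_evidence(self):
        assert individual_lr(0.015, 0.015).lr == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rk,r0,expected", [
        (0.5, 0.015, 0.985 / 0.015),   # ~65.67
        (0.99, 0.5, 99.0),
    ])
    def test_hand_arithmetic(self, rk, r0, expected):
        assert individual_lr(rk, r0).lr == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("rk,r0", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_degenerate_probabilities_rejected(self, rk, r0):
        with pytest.raises(ValueError):
            individual_lr(rk, r0)

    def test_log10_consistency(self):
        ilr = individual_lr(0.3, 0.01)
        assert ilr.log10_lr == pytest.approx(math.log10(ilr.lr), abs=1e-12)


class TestCombine:
    def ilrs(self, lrs):
        return [individual_lr(lr / (1 + lr), 0.5, proband_id=f"p{i}")
                for i, lr in enumerate(lrs)]  # r0=0.5 makes LR = odds(r_k)

    def test_product(self):
        ev = combine_variant(self.ilrs([2, 5]), "v", "BRCA1")
        assert ev.combined_lr == pytest.approx(10.0, rel=1e-9)

    def test_single_member_identity(self):
        ev = combine_variant(self.ilrs([884]), "v", "BRCA1")
        assert ev.combined_lr == pytest.approx(884.0, rel=1e-9)
        assert ev.n_probands == 1

    def test_cancellation(self):
        ev = combine_variant(self.ilrs([10, 0.1]), "v", "BRCA1")
        assert ev.combined_lr == pytest.approx(1.0, abs=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_variant([], "v", "BRCA1")

    def test_mixed_gene_rejected(self):
        obs = self.ilrs([2])
        bad = individual_lr(0.6, 0.5, gene="BRCA2")
        with pytest.raises(IntegrityError):
            combine_variant(obs + [bad], "v", "BRCA1")

    def test_extreme_evidence_stays_finite_in_log_space(self):
        from vusclinlr.evidence import IndividualLR

        obs = [IndividualLR(proband_id=f"p{i}", gene="BRCA1",
                            race_group="european_mixed", r_k=1 - 1e-16, r0=0.5,
                            lr=1e200, log10_lr=200.0) for i in range(2)]
        ev = combine_variant(obs, "v", "BRCA1")
        assert math.isinf(ev.combined_lr)
        assert ev.sum_log10_lr == pytest.approx(400.0, rel=1e-6)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=5),
           st.randoms(use_true_random=False))
    def test_order_invariance_and_brute_force_oracle(self, lrs, rnd):
        obs = self.ilrs(lrs)
        shuffled = list(obs)
        rnd.shuffle(shuffled)
        a = combine_variant(obs, "v", "BRCA1")
        b = combine_variant(shuffled, "v", "BRCA1")
        assert a.sum_log10_lr == pytest.approx(b.sum_log10_lr, abs=1e-9)
        oracle = brute_force_combined([(o.r_k, o.r0) for o in obs])
        assert a.combined_lr == pytest.approx(oracle, rel=1e-9)


class TestScoreCohort:
    def test_carriers_at_null_risk_give_unit_combined_lr(self):
        cohort = [make_proband(f"p{i}", brca1="vus") for i in range(3)]
        cohort.append(make_proband("case", brca1="pathogenic"))
        cohort.append(make_proband("ctrl"))
        obs = [VariantObservation(proband_id=f"p{i}", gene="BRCA1", variant_id="v1",
                                  lab_class="vus") for i in range(3)]
        sets = {("BRCA1", "european_mixed"): flat_coeffs(0.015)}
        evidence, _ = score_cohort(cohort_to_frame(cohort), obs, sets)
        assert len(evidence) == 1
        assert evidence[0].combined_lr == pytest.approx(1.0, abs=1e-9)
        assert evidence[0].n_probands == 3

    def test_two_race_groups_multiply_their_own_stratum_lrs(self):
        cohort = [
            make_proband("e", race="european_mixed", brca1="vus", oc_age=50),
            make_proband("h", race="hispanic", brca1="vus", oc_age=50),
        ]
        obs = [VariantObservation(proband_id=p, gene="BRCA1", variant_id="v1",
                                  lab_class="vus") for p in ("e", "h")]
        ce = flat_coeffs(0.02, race="european_mixed", ov_lt60=math.log(10.7))
        ch = flat_coeffs(0.01, race="hispanic", ov_lt60=math.log(17.5))
        evidence, breakdown = score_cohort(cohort_to_frame(cohort), obs,
                                           {("BRCA1", "european_mixed"): ce,
                                            ("BRCA1", "hispanic"): ch})
        by_group = dict(zip(breakdown.race_group, breakdown.log10_lr))
        assert evidence[0].sum_log10_lr == pytest.approx(
            by_group["european_mixed"] + by_group["hispanic"], abs=1e-12)
        # each stratum used its own r0 and coefficients
        assert set(breakdown.r0) == {0.02, 0.01}

    def test_excluded_probands_never_contribute(self):
        cohort = [
            make_proband("ok", brca1="vus"),
            make_proband("bad", brca1="vus", other_plp=True),
        ]
        obs = [VariantObservation(proband_id=p, gene="BRCA1", variant_id="v1",
                                  lab_class="vus") for p in ("ok", "bad")]
        evidence, _ = score_cohort(cohort_to_frame(cohort), obs,
                                   {("BRCA1", "european_mixed"): flat_coeffs(0.015)})
        assert evidence[0].n_probands == 1

    def test_shared_proband_flagged_on_both_variants(self):
        cohort = [make_proband("p", brca1="vus")]
        obs = [VariantObservation(proband_id="p", gene="BRCA1", variant_id=v,
                                  lab_class="vus") for v in ("v1", "v2")]
        evidence, _ = score_cohort(cohort_to_frame(cohort), obs,
                                   {("BRCA1", "european_mixed"): flat_coeffs(0.015)})
        assert all(e.shared_proband for e in evidence)

    def test_output_sorted_by_gene_then_variant(self, sim_bundle):
        ev = sim_bundle["evidence"]
        keys = [(e.gene, e.variant_id) for e in ev]
        assert keys == sorted(keys)

    def test_null_generative_model_centers_log_lr_at_zero(self):
        """Smaller-scale version of the null-calibration property: under a
        beta=0 generative model the per-variant log10 LRs are centred at 0."""
        from vusclinlr.model import fit
        from vusclinlr.simulate import (
            SimulationConfig,
            simulate_cohort_frame,
            simulate_vus_assignments,
        )

        cfg = SimulationConfig(
            n_probands=30000, seed=77, race_mix={"european_mixed": 1.0},
            true_or={},
            class_specs=[{"bioinfo_class": "other", "n_variants": 200,
                          "alpha_true": 0.0, "prior_prob": 0.5}],
            singleton_prob=1.0)
        frame = simulate_cohort_frame(cfg)
        frame, obs, _ = simulate_vus_assignments(frame, cfg)
        sets = {("BRCA1", "european_mixed"):
                fit(frame, "BRCA1", "european_mixed", compute_auc=False)}
        evidence, _ = score_cohort(frame, obs, sets)
        logs = np.array([e.sum_log10_lr for e in evidence])
        se = logs.std(ddof=1) / np.sqrt(len(logs))
        assert abs(logs.mean()) < 3 * se
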