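import numpy as np
import pytest

from vusclinlr.datamodel import (
    BreastCancer,
    FamilyHistory,
    PersonalHistory,
    Proband,
)
from vusclinlr.evidence import score_cohort
from vusclinlr.model import fit
from vusclinlr.simulate import (
    SimulationConfig,
    simulate_cohort_frame,
    simulate_vus_assignments,
)


def make_proband(pid="P1", race="european_mixed", sex="female", brca1="none",
                 brca2="none", other_plp=False, sufficient=True, dcis=False,
                 bc=None, oc_age=None, pancreatic=False, pr_age=None,
                 fam=None, **extra) -> Proband:
    """Compact proband factory for unit tests.

    ``bc`` is a dict passed to BreastCancer; ``fam`` a dict passed to
    FamilyHistory.
    """
    return Proband(
        proband_id=pid,
        race_group=race,
        sex=sex,
        brca1_status=brca1,
        brca2_status=brca2,
        other_gene_plp=other_plp,
        history_sufficient=sufficient,
        personal_history=PersonalHistory(
            dcis=dcis,
            breast_cancer=BreastCancer(**bc) if bc else None,
            ovarian_cancer=None if oc_age is None else {"age_dx": oc_age},
            pancreatic_cancer=pancreatic,
            prostate_cancer=None if pr_age is None else {"age_dx": pr_age},
        ),
        family_history=FamilyHistory(**(fam or {})),
        **extra,
    )


@pytest.fixture
def proband_factory():
    return make_proband


@pytest.fixture(scope="session")
def sim_bundle():
    """One medium synthetic study shared across tests: cohort (n=20,000, four
    race groups), VUS assignments, per-stratum fits, scored evidence."""
    cfg = SimulationConfig(n_probands=20000, seed=20)
    frame = simulate_cohort_frame(cfg)
    frame, observations, truth = simulate_vus_assignments(frame, cfg)
    sets = {
        ("BRCA1", g): fit(frame, "BRCA1", g)
        for g in sorted(frame["race_group"].unique())
    }
    evidence, breakdown = score_cohort(frame, observations, sets)
    return {
        "config": cfg,
        "frame": frame,
        "observations": observations,
        "truth": truth,
        "sets": sets,
        "evidence": evidence,
        "breakdown": breakdown,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
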