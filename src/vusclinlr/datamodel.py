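"""Core domain types for the cohort/variant data model.

A cohort is held in two equivalent representations:

* a list of :class:`Proband` objects — validated record-level API used at the
  I/O boundary and in small examples;
* a :class:`pandas.DataFrame` with one row per proband (the *cohort frame*) —
  the vectorized container every numerical stage operates on.

:func:`cohort_to_frame` / :func:`frame_to_cohort` convert between the two.
"""

from __future__ import annotations

import enum
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, NonNegativeInt, model_validator


class RaceGroup(str, enum.Enum):
    """Four analysis strata; mixed/unknown ethnicity is folded into the
    European group at load time."""

    european_mixed = "european_mixed"
    african_american = "african_american"
    asian = "asian"
    hispanic = "hispanic"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class GeneStatus(str, enum.Enum):
    """Laboratory test result for one gene."""

    pathogenic = "pathogenic"
    vlp = "vlp"  # likely pathogenic
    vus = "vus"
    none = "none"  # no reportable variant


class TnStatus(str, enum.Enum):
    """Triple-negative status of a breast tumour (ER-/PR-/HER2- vs not vs
    not reported)."""

    tn_pos = "tn_pos"
    tn_neg = "tn_neg"
    tn_unknown = "tn_unknown"


class LabClass(str, enum.Enum):
    pathogenic = "pathogenic"
    vlp = "vlp"
    vus = "vus"


class BioinfoClass(str, enum.Enum):
    """Bioinformatically defined variant classes used for the heterogeneity
    analysis: missense severity grades (C0..C65) within key functional
    domains, missense outside those domains, and splice-prediction groups."""

    not_in_key_domain = "not_in_key_domain"
    C0 = "C0"
    C15_C25 = "C15_C25"
    C35_C55 = "C35_C55"
    C65 = "C65"
    splice_high_damage = "splice_high_damage"
    splice_moderate_damage = "splice_moderate_damage"
    denovo_donor_increased = "denovo_donor_increased"
    denovo_donor_moderate = "denovo_donor_moderate"
    other = "other"


GENES = ("BRCA1", "BRCA2")


class BreastCancer(BaseModel):
    """Personal invasive breast cancer record."""

    age_dx: float = Field(ge=0, le=120)
    tn_status: TnStatus = TnStatus.tn_unknown
    bilateral: bool = False
    male_bc: bool = False


class OvarianCancer(BaseModel):
    age_dx: float = Field(ge=0, le=120)


class ProstateCancer(BaseModel):
    age_dx: float = Field(ge=0, le=120)


class PersonalHistory(BaseModel):
    dcis: bool = False
    breast_cancer: Optional[BreastCancer] = None
    ovarian_cancer: Optional[OvarianCancer] = None
    pancreatic_cancer: bool = False
    prostate_cancer: Optional[ProstateCancer] = None


class FamilyHistory(BaseModel):
    """Raw counts of affected first/second-degree relatives (maternal and
    paternal combined). Counts are uncapped here; capping into the 0/1/2/3+
    (breast) and 0/1/2+ (other) categories happens at design-matrix build."""

    n_bc_lt50: NonNegativeInt = 0
    n_bc_ge50: NonNegativeInt = 0
    n_oc_lt60: NonNegativeInt = 0
    n_oc_ge60: NonNegativeInt = 0
    n_pancreatic: NonNegativeInt = 0
    n_mbc: NonNegativeInt = 0
    n_prostate: NonNegativeInt = 0


class Proband(BaseModel):
    """One tested individual."""

    proband_id: str
    race_group: RaceGroup
    sex: Sex
    brca1_status: GeneStatus = GeneStatus.none
    brca2_status: GeneStatus = GeneStatus.none
    other_gene_plp: bool = False
    history_sufficient: bool = True
    personal_history: PersonalHistory = Field(default_factory=PersonalHistory)
    family_history: FamilyHistory = Field(default_factory=FamilyHistory)
    # Raw race/ethnicity token as read from the file ("mixed"/"unknown" are
    # folded into european_mixed but remembered here for sensitivity reruns).
    race_raw: Optional[str] = None
    # True if the individual had a prior negative BRCA1/2 test (sensitivity
    # analysis flag); False when not recorded.
    prev_tested_negative: bool = False

    @model_validator(mode="after")
    def _check_male_bc(self) -> "Proband":
        bc = self.personal_history.breast_cancer
        if bc is not None and bc.male_bc and self.sex is not Sex.male:
            raise ValueError("male_bc requires sex = male")
        return self

    def gene_status(self, gene: str) -> GeneStatus:
        if gene == "BRCA1":
            return self.brca1_status
        if gene == "BRCA2":
            return self.brca2_status
        raise KeyError(gene)


class VariantObservation(BaseModel):
    """Link of one proband to one variant; the variant identifier is an
    opaque label (HGVS strings are never parsed)."""

    proband_id: str
    gene: str
    variant_id: str
    lab_class: LabClass
    bioinfo_class: BioinfoClass = BioinfoClass.other
    prior_prob: float = Field(ge=0.0, le=1.0, default=0.5)

    @model_validator(mode="after")
    def _check_gene(self) -> "VariantObservation":
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}")
        return self


class CohortConfig(BaseModel):
    """File-format and category-definition configuration.

    The age cuts are the published category boundaries (breast cancer at 50,
    ovarian/prostate at 60) and should not normally be changed. The key
    functional domain ranges are carried as metadata only — the bioinformatic
    class of each variant is an input, never computed here.
    """

    delimiter: str = "\t"
    missing_token: str = "NA"
    age_cut_bc: float = 50.0
    age_cut_ov_pr: float = 60.0
    key_domain_definitions: dict[str, list[tuple[int, int]]] = Field(
        default_factory=lambda: {
            "BRCA1": [(1, 294), (4987, 5577)],
            "BRCA2": [(7669, 9558)],
        }
    )


# ---------------------------------------------------------------------------
# Cohort frame schema

#: Column layout of the cohort frame / cohort TSV. Optional cancers are
#: encoded by their age column (missing token = cancer absent).
COHORT_COLUMNS = (
    "proband_id",
    "race_group",
    "sex",
    "brca1_status",
    "brca2_status",
    "other_gene_plp",
    "history_sufficient",
    "dcis",
    "bc_age_dx",
    "bc_tn_status",
    "bc_bilateral",
    "bc_male",
    "oc_age_dx",
    "pancreatic",
    "prca_age_dx",
    "fam_bc_lt50",
    "fam_bc_ge50",
    "fam_oc_lt60",
    "fam_oc_ge60",
    "fam_pancreatic",
    "fam_mbc",
    "fam_prostate",
)

#: Optional columns (kept when present, defaulted when absent).
COHORT_OPTIONAL_COLUMNS = ("race_raw", "prev_tested_negative")

VARIANT_COLUMNS = (
    "proband_id",
    "gene",
    "variant_id",
    "lab_class",
    "bioinfo_class",
    "prior_prob",
)


def cohort_to_frame(cohort: list[Proband]) -> pd.DataFrame:
    """Flatten a list of probands into the cohort frame."""
    rows = []
    for p in cohort:
        ph = p.personal_history
        bc = ph.breast_cancer
        rows.append(
            {
                "proband_id": p.proband_id,
                "race_group": p.race_group.value,
                "sex": p.sex.value,
                "brca1_status": p.brca1_status.value,
                "brca2_status": p.brca2_status.value,
                "other_gene_plp": p.other_gene_plp,
                "history_sufficient": p.history_sufficient,
                "dcis": ph.dcis,
                "bc_age_dx": bc.age_dx if bc else np.nan,
                "bc_tn_status": bc.tn_status.value if bc else None,
                "bc_bilateral": bc.bilateral if bc else False,
                "bc_male": bc.male_bc if bc else False,
                "oc_age_dx": ph.ovarian_cancer.age_dx if ph.ovarian_cancer else np.nan,
                "pancreatic": ph.pancreatic_cancer,
                "prca_age_dx": ph.prostate_cancer.age_dx if ph.prostate_cancer else np.nan,
                "fam_bc_lt50": p.family_history.n_bc_lt50,
                "fam_bc_ge50": p.family_history.n_bc_ge50,
                "fam_oc_lt60": p.family_history.n_oc_lt60,
                "fam_oc_ge60": p.family_history.n_oc_ge60,
                "fam_pancreatic": p.family_history.n_pancreatic,
                "fam_mbc": p.family_history.n_mbc,
                "fam_prostate": p.family_history.n_prostate,
                "race_raw": p.race_raw,
                "prev_tested_negative": p.prev_tested_negative,
            }
        )
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS + COHORT_OPTIONAL_COLUMNS))
    return frame


def frame_to_cohort(frame: pd.DataFrame) -> list[Proband]:
    """Materialize probands from a cohort frame (validates every row)."""
    out: list[Proband] = []
    has_raw = "race_raw" in frame.columns
    has_prev = "prev_tested_negative" in frame.columns
    for row in frame.itertuples(index=False):
        bc = None
        if not pd.isna(row.bc_age_dx):
            bc = BreastCancer(
                age_dx=float(row.bc_age_dx),
                tn_status=TnStatus(row.bc_tn_status),
                bilateral=bool(row.bc_bilateral),
                male_bc=bool(row.bc_male),
            )
        ph = PersonalHistory(
            dcis=bool(row.dcis),
            breast_cancer=bc,
            ovarian_cancer=None
            if pd.isna(row.oc_age_dx)
            else OvarianCancer(age_dx=float(row.oc_age_dx)),
            pancreatic_cancer=bool(row.pancreatic),
            prostate_cancer=None
            if pd.isna(row.prca_age_dx)
            else ProstateCancer(age_dx=float(row.prca_age_dx)),
        )
        fh = FamilyHistory(
            n_bc_lt50=int(row.fam_bc_lt50),
            n_bc_ge50=int(row.fam_bc_ge50),
            n_oc_lt60=int(row.fam_oc_lt60),
            n_oc_ge60=int(row.fam_oc_ge60),
            n_pancreatic=int(row.fam_pancreatic),
            n_mbc=int(row.fam_mbc),
            n_prostate=int(row.fam_prostate),
        )
        race_raw = getattr(row, "race_raw", None) if has_raw else None
        if race_raw is not None and (race_raw is np.nan or pd.isna(race_raw)):
            race_raw = None
        out.append(
            Proband(
                proband_id=str(row.proband_id),
                race_group=RaceGroup(row.race_group),
                sex=Sex(row.sex),
                brca1_status=GeneStatus(row.brca1_status),
                brca2_status=GeneStatus(row.brca2_status),
                other_gene_plp=bool(row.other_gene_plp),
                history_sufficient=bool(row.history_sufficient),
                personal_history=ph,
                family_history=fh,
                race_raw=race_raw,
                prev_tested_negative=bool(row.prev_tested_negative) if has_prev else False,
            )
        )
    return out


def as_frame(cohort) -> pd.DataFrame:
    """Accept either a cohort frame or a list of probands."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_to_frame(list(cohort))
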