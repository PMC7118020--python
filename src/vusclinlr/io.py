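"""Delimited-text readers/writers and the cohort exclusion filter.

All files are UTF-8 delimited text with a header row; columns are addressed
by name, never by position. A reported cancer with a missing age of diagnosis
is a validation error (not a silent category), so bad rows surface with their
row numbers instead of biasing the fit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    COHORT_COLUMNS,
    COHORT_OPTIONAL_COLUMNS,
    VARIANT_COLUMNS,
    BioinfoClass,
    CohortConfig,
    GeneStatus,
    LabClass,
    Proband,
    RaceGroup,
    Sex,
    TnStatus,
    VariantObservation,
    as_frame,
    cohort_to_frame,
    frame_to_cohort,
)


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class IntegrityError(ValueError):
    """Duplicate keys or cross-file inconsistencies."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; carries (row_number, message) pairs
    with 1-based row numbers counted from the first data row."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {m}" for r, m in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"{len(problems)} invalid row(s): {lines}{more}")


_TRUE = {"1", "true", "TRUE", "True", "yes"}
_FALSE = {"0", "false", "FALSE", "False", "no", ""}

#: Raw race/ethnicity tokens folded into the European analysis stratum.
_EURO_FOLD = {"european", "caucasian", "mixed", "unknown", "european_mixed"}


def _parse_bool(tok: str, what: str) -> bool:
    if tok in _TRUE:
        return True
    if tok in _FALSE:
        return False
    raise ValueError(f"{what}: cannot parse boolean {tok!r}")


def _fold_race(tok: str) -> RaceGroup:
    t = tok.strip().lower()
    if t in _EURO_FOLD:
        return RaceGroup.european_mixed
    return RaceGroup(t)


def read_cohort(path: str | Path, config: CohortConfig | None = None) -> list[Proband]:
    """Read and validate a cohort TSV into probands.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for duplicate proband ids, and :class:`CohortValidationError` listing the
    offending row numbers for per-row failures.
    """
    config = config or CohortConfig()
    raw = pd.read_csv(
        path,
        sep=config.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing_cols = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    na = config.missing_token
    problems: list[tuple[int, str]] = []
    cohort: list[Proband] = []
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        try:
            cohort.append(_parse_row(rec, na))
        except (ValueError, KeyError) as exc:
            problems.append((i, str(exc)))
    if problems:
        raise CohortValidationError(problems)

    ids = [p.proband_id for p in cohort]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise IntegrityError(f"duplicate proband_id(s): {', '.join(map(str, dupes[:10]))}")
    return cohort


def _parse_row(rec: dict, na: str) -> Proband:
    def opt_float(col: str) -> float | None:
        tok = rec[col].strip()
        return None if tok == na or tok == "" else float(tok)

    bc_age = opt_float("bc_age_dx")
    tn_tok = rec["bc_tn_status"].strip()
    has_tn = tn_tok not in (na, "")
    bc = None
    if bc_age is not None or has_tn:
        if bc_age is None:
            raise ValueError("breast cancer reported (tn status present) but age_dx missing")
        bc = {
            "age_dx": bc_age,
            "tn_status": TnStatus(tn_tok) if has_tn else TnStatus.tn_unknown,
            "bilateral": _parse_bool(rec["bc_bilateral"], "bc_bilateral"),
            "male_bc": _parse_bool(rec["bc_male"], "bc_male"),
        }

    oc_age = opt_float("oc_age_dx")
    pr_age = opt_float("prca_age_dx")

    race_tok = rec["race_group"].strip()
    return Proband(
        proband_id=rec["proband_id"].strip(),
        race_group=_fold_race(race_tok),
        race_raw=race_tok.lower(),
        sex=Sex(rec["sex"].strip()),
        brca1_status=GeneStatus(rec["brca1_status"].strip()),
        brca2_status=GeneStatus(rec["brca2_status"].strip()),
        other_gene_plp=_parse_bool(rec["other_gene_plp"], "other_gene_plp"),
        history_sufficient=_parse_bool(rec["history_sufficient"], "history_sufficient"),
        personal_history={
            "dcis": _parse_bool(rec["dcis"], "dcis"),
            "breast_cancer": bc,
            "ovarian_cancer": None if oc_age is None else {"age_dx": oc_age},
            "pancreatic_cancer": _parse_bool(rec["pancreatic"], "pancreatic"),
            "prostate_cancer": None if pr_age is None else {"age_dx": pr_age},
        },
        family_history={
            "n_bc_lt50": int(rec["fam_bc_lt50"]),
            "n_bc_ge50": int(rec["fam_bc_ge50"]),
            "n_oc_lt60": int(rec["fam_oc_lt60"]),
            "n_oc_ge60": int(rec["fam_oc_ge60"]),
            "n_pancreatic": int(rec["fam_pancreatic"]),
            "n_mbc": int(rec["fam_mbc"]),
            "n_prostate": int(rec["fam_prostate"]),
        },
        prev_tested_negative=_parse_bool(rec.get("prev_tested_negative", "0"), "prev_tested_negative")
        if "prev_tested_negative" in rec
        else False,
    )


def write_cohort(cohort, path: str | Path, config: CohortConfig | None = None) -> None:
    """Write a cohort (frame or proband list) as TSV; inverse of read_cohort."""
    config = config or CohortConfig()
    frame = as_frame(cohort).copy()
    for col in ("bc_age_dx", "oc_age_dx", "prca_age_dx"):
        frame[col] = frame[col].map(
            lambda v: config.missing_token if pd.isna(v) else format(float(v), "g")
        )
    frame["bc_tn_status"] = frame["bc_tn_status"].map(
        lambda v: config.missing_token if v is None or (isinstance(v, float) and np.isnan(v)) else v
    )
    for col in (
        "other_gene_plp",
        "history_sufficient",
        "dcis",
        "bc_bilateral",
        "bc_male",
        "pancreatic",
    ):
        frame[col] = frame[col].astype(int)
    keep = list(COHORT_COLUMNS)
    for col in COHORT_OPTIONAL_COLUMNS:
        if col in frame.columns:
            if col == "prev_tested_negative":
                frame[col] = frame[col].fillna(False).astype(int)
            keep.append(col)
    frame[keep].to_csv(path, sep=config.delimiter, index=False, encoding="utf-8")


def read_variants(path: str | Path, config: CohortConfig | None = None) -> list[VariantObservation]:
    """Read a proband x variant observation table."""
    config = config or CohortConfig()
    raw = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in VARIANT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")
    obs: list[VariantObservation] = []
    problems: list[tuple[int, str]] = []
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        try:
            obs.append(
                VariantObservation(
                    proband_id=rec["proband_id"].strip(),
                    gene=rec["gene"].strip(),
                    variant_id=rec["variant_id"].strip(),
                    lab_class=LabClass(rec["lab_class"].strip()),
                    bioinfo_class=BioinfoClass(rec["bioinfo_class"].strip()),
                    prior_prob=float(rec["prior_prob"]),
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append((i, str(exc)))
    if problems:
        raise CohortValidationError(problems)
    keys = [(o.proband_id, o.gene, o.variant_id) for o in obs]
    if len(set(keys)) != len(keys):
        raise IntegrityError("duplicate (proband_id, gene, variant_id) observation(s)")
    return obs


def write_variants(observations: list[VariantObservation], path: str | Path,
                   config: CohortConfig | None = None) -> None:
    config = config or CohortConfig()
    frame = pd.DataFrame(
        [
            {
                "proband_id": o.proband_id,
                "gene": o.gene,
                "variant_id": o.variant_id,
                "lab_class": o.lab_class.value,
                "bioinfo_class": o.bioinfo_class.value,
                "prior_prob": o.prior_prob,
            }
            for o in observations
        ],
        columns=list(VARIANT_COLUMNS),
    )
    frame.to_csv(path, sep=config.delimiter, index=False, encoding="utf-8")


def read_priors(path: str | Path, config: CohortConfig | None = None) -> dict[BioinfoClass, float]:
    """Read the per-class prior probability table (columns: bioinfo_class, prior_prob)."""
    config = config or CohortConfig()
    raw = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
    for col in ("bioinfo_class", "prior_prob"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column(s): {col}")
    out: dict[BioinfoClass, float] = {}
    for rec in raw.to_dict("records"):
        cls = BioinfoClass(rec["bioinfo_class"].strip())
        p = float(rec["prior_prob"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prior_prob out of [0,1] for class {cls.value}")
        out[cls] = p
    return out


# ---------------------------------------------------------------------------
# Exclusion filter


@dataclasses.dataclass(frozen=True)
class ExclusionReport:
    """Counts removed per rule, in application order. A proband failing
    several rules is counted once, under the first."""

    insufficient_history: int
    other_gene_plp: int
    opposite_gene_variant: int

    def total(self) -> int:
        return self.insufficient_history + self.other_gene_plp + self.opposite_gene_variant


def apply_exclusions(cohort, gene: str):
    """Apply the per-gene analysis exclusions, in fixed order:

    1. insufficient personal/family history information;
    2. pathogenic/likely-pathogenic variant in another (non-BRCA) gene;
    3. any reportable variant (pathogenic, VLP or VUS) in the *opposite*
       BRCA gene.

    Returns ``(retained, ExclusionReport)`` preserving input order and type
    (frame in → frame out; proband list in → proband list out).
    """
    if gene not in ("BRCA1", "BRCA2"):
        raise ValueError(f"gene must be BRCA1 or BRCA2, got {gene!r}")
    frame_in = isinstance(cohort, pd.DataFrame)
    frame = cohort if frame_in else cohort_to_frame(list(cohort))

    opp = "brca2_status" if gene == "BRCA1" else "brca1_status"
    insufficient = ~frame["history_sufficient"].astype(bool)
    other = frame["other_gene_plp"].astype(bool) & ~insufficient
    opposite = (frame[opp] != GeneStatus.none.value) & ~insufficient & ~frame[
        "other_gene_plp"
    ].astype(bool)
    keep = ~(insufficient | other | opposite)

    report = ExclusionReport(
        insufficient_history=int(insufficient.sum()),
        other_gene_plp=int(other.sum()),
        opposite_gene_variant=int(opposite.sum()),
    )
    retained_frame = frame.loc[keep].reset_index(drop=True)
    if frame_in:
        return retained_frame, report
    kept_ids = set(retained_frame["proband_id"])
    return [p for p in cohort if p.proband_id in kept_ids], report


# ---------------------------------------------------------------------------
# Coefficient JSON I/O (the numeric content lives in model.CoefficientSet)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
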