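"""Carrier-status prediction: the 29-indicator design matrix and per-gene,
per-race-group logistic regressions.

The design has 14 personal-history indicators (DCIS; six triple-negative x
age-at-diagnosis cells for invasive breast cancer; bilateral breast cancer;
ovarian cancer by age; pancreatic cancer; male breast cancer; prostate cancer
by age) and 15 family-history indicators (counts of affected first/second-
degree relatives capped at 3+ for breast cancer and 2+ for ovarian,
pancreatic and prostate cancers, plus any male breast cancer in the family).

Cases are probands with a known pathogenic variant in the gene; controls are
probands with no reportable variant. VUS/VLP carriers are scored with the
fitted model but never contribute to the fit.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, rankdata

from .datamodel import CohortConfig, GeneStatus, Proband, as_frame, cohort_to_frame

#: Canonical order of the 29 design indicators.
DESIGN_COLUMNS = (
    # personal history (14)
    "dcis",
    "tn_pos_lt50",
    "tn_pos_ge50",
    "tn_neg_lt50",
    "tn_neg_ge50",
    "tn_unk_lt50",
    "tn_unk_ge50",
    "bilateral_bc",
    "ov_lt60",
    "ov_ge60",
    "pancreatic",
    "male_bc",
    "prostate_lt60",
    "prostate_ge60",
    # family history (15)
    "fam_bc_lt50_1",
    "fam_bc_lt50_2",
    "fam_bc_lt50_3plus",
    "fam_bc_ge50_1",
    "fam_bc_ge50_2",
    "fam_bc_ge50_3plus",
    "fam_oc_lt60_1",
    "fam_oc_lt60_2plus",
    "fam_oc_ge60_1",
    "fam_oc_ge60_2plus",
    "fam_panc_1",
    "fam_panc_2plus",
    "fam_mbc",
    "fam_prostate_1",
    "fam_prostate_2plus",
)


class FitError(RuntimeError):
    """Logistic fit could not be carried out (no cases/controls, separation,
    or non-convergence)."""


def null_probability(n_cases: int, n_controls: int) -> float:
    """Null carrier probability r0 = cases / (cases + controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise FitError("need at least one case and one control for r0")
    return n_cases / (n_cases + n_controls)


# ---------------------------------------------------------------------------
# Design matrix


def design_matrix(cohort, config: CohortConfig | None = None) -> pd.DataFrame:
    """Vectorized design-matrix build from a cohort frame (or proband list).

    Returns a DataFrame with the 29 indicator columns (int8), indexed like
    the input frame.
    """
    config = config or CohortConfig()
    frame = as_frame(cohort)
    n = len(frame)
    X = pd.DataFrame(
        np.zeros((n, len(DESIGN_COLUMNS)), dtype=np.int8),
        columns=list(DESIGN_COLUMNS),
        index=frame.index,
    )

    X["dcis"] = frame["dcis"].astype(bool).astype(np.int8)

    bc_age = pd.to_numeric(frame["bc_age_dx"], errors="coerce")
    has_bc = bc_age.notna()
    lt50 = bc_age < config.age_cut_bc
    tn = frame["bc_tn_status"]
    for status, stem in (("tn_pos", "tn_pos"), ("tn_neg", "tn_neg"), ("tn_unknown", "tn_unk")):
        sel = has_bc & (tn == status)
        X.loc[sel & lt50, f"{stem}_lt50"] = 1
        X.loc[sel & ~lt50, f"{stem}_ge50"] = 1
    X.loc[has_bc & frame["bc_bilateral"].astype(bool), "bilateral_bc"] = 1
    # Male breast cancer sets its own indicator in addition to the TN x age
    # cell (parallel predictors).
    X.loc[has_bc & frame["bc_male"].astype(bool), "male_bc"] = 1

    oc_age = pd.to_numeric(frame["oc_age_dx"], errors="coerce")
    X.loc[oc_age < config.age_cut_ov_pr, "ov_lt60"] = 1
    X.loc[oc_age >= config.age_cut_ov_pr, "ov_ge60"] = 1

    X["pancreatic"] = frame["pancreatic"].astype(bool).astype(np.int8)

    pr_age = pd.to_numeric(frame["prca_age_dx"], errors="coerce")
    X.loc[pr_age < config.age_cut_ov_pr, "prostate_lt60"] = 1
    X.loc[pr_age >= config.age_cut_ov_pr, "prostate_ge60"] = 1

    def cap_block(col: str, stem: str, cap3: bool) -> None:
        c = frame[col].astype(int).clip(lower=0)
        if cap3:
            X.loc[c == 1, f"{stem}_1"] = 1
            X.loc[c == 2, f"{stem}_2"] = 1
            X.loc[c >= 3, f"{stem}_3plus"] = 1
        else:
            X.loc[c == 1, f"{stem}_1"] = 1
            X.loc[c >= 2, f"{stem}_2plus"] = 1

    cap_block("fam_bc_lt50", "fam_bc_lt50", cap3=True)
    cap_block("fam_bc_ge50", "fam_bc_ge50", cap3=True)
    cap_block("fam_oc_lt60", "fam_oc_lt60", cap3=False)
    cap_block("fam_oc_ge60", "fam_oc_ge60", cap3=False)
    cap_block("fam_pancreatic", "fam_panc", cap3=False)
    X.loc[frame["fam_mbc"].astype(int) >= 1, "fam_mbc"] = 1
    cap_block("fam_prostate", "fam_prostate", cap3=False)
    return X


def build_design(p: Proband, config: CohortConfig | None = None) -> dict[str, int]:
    """Design vector for a single proband, keyed by indicator name."""
    X = design_matrix(cohort_to_frame([p]), config)
    return {k: int(v) for k, v in X.iloc[0].items()}


# ---------------------------------------------------------------------------
# Coefficient sets


@dataclasses.dataclass
class CoefficientSet:
    """Fitted (or configured) log-odds parameters for one gene x race group.

    ``beta`` carries every design indicator; members of ``dropped`` were not
    estimable (no exposed cases or no exposed controls) and are pinned at 0,
    mirroring the inestimable cells of the published tables.
    """

    gene: str
    race_group: str
    intercept: float
    beta: dict[str, float]
    r0: float
    dropped: tuple[str, ...] = ()
    n_cases: int = 0
    n_controls: int = 0
    covariance: Optional[np.ndarray] = None  # (1+29)x(1+29), intercept first
    param_names: Optional[tuple[str, ...]] = None  # rows/cols of covariance
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    converged: bool = True

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.beta)
        extra = set(self.beta) - set(DESIGN_COLUMNS)
        if missing or extra:
            raise ValueError(
                f"beta keys must match the design columns (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        if not 0.0 < self.r0 < 1.0:
            raise ValueError("r0 must lie strictly inside (0, 1)")

    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[c] for c in DESIGN_COLUMNS], dtype=float)

    def linear_predictor(self, X) -> np.ndarray:
        Xv = X[list(DESIGN_COLUMNS)].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.intercept + Xv @ self.beta_vector()

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene,
            "race_group": self.race_group,
            "intercept": self.intercept,
            "beta": dict(self.beta),
            "r0": self.r0,
            "dropped": list(self.dropped),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "converged": self.converged,
        }
        if self.covariance is not None:
            d["covariance"] = np.asarray(self.covariance).tolist()
            d["param_names"] = list(self.param_names or ())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        cov = d.get("covariance")
        return cls(
            gene=d["gene"],
            race_group=d["race_group"],
            intercept=float(d["intercept"]),
            beta={k: float(v) for k, v in d["beta"].items()},
            r0=float(d["r0"]),
            dropped=tuple(d.get("dropped", ())),
            n_cases=int(d.get("n_cases", 0)),
            n_controls=int(d.get("n_controls", 0)),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            param_names=tuple(d["param_names"]) if d.get("param_names") else None,
            auc=d.get("auc"),
            auc_ci=tuple(d["auc_ci"]) if d.get("auc_ci") else None,
            converged=bool(d.get("converged", True)),
        )


# ---------------------------------------------------------------------------
# Fitting


def _case_control_mask(frame: pd.DataFrame, gene: str):
    status = frame["brca1_status" if gene == "BRCA1" else "brca2_status"]
    is_case = status == GeneStatus.pathogenic.value
    is_control = status == GeneStatus.none.value
    return is_case, is_control


def fit(cohort, gene: str, race_group: str, config: CohortConfig | None = None,
        compute_auc: bool = True) -> CoefficientSet:
    """Fit the logistic carrier model for one gene x race-group stratum.

    The cohort is expected to have passed :func:`vusclinlr.io.apply_exclusions`
    for this gene. Indicators with no exposed cases or no exposed controls are
    dropped from the likelihood (their coefficient is pinned at 0 and the name
    recorded in ``dropped``) — the maximum-likelihood estimate for such a cell
    is +/- infinity, so dropping doubles as a complete-separation guard.
    """
    config = config or CohortConfig()
    frame = as_frame(cohort)
    frame = frame.loc[frame["race_group"] == race_group]
    is_case, is_control = _case_control_mask(frame, gene)
    sub = frame.loc[is_case | is_control]
    y = (sub["brca1_status" if gene == "BRCA1" else "brca2_status"]
         == GeneStatus.pathogenic.value).to_numpy()
    n_cases, n_controls = int(y.sum()), int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise FitError(
            f"{gene}/{race_group}: need both cases and controls "
            f"(got {n_cases} cases, {n_controls} controls)"
        )

    X = design_matrix(sub, config)
    dropped = []
    for col in DESIGN_COLUMNS:
        x = X[col].to_numpy(dtype=bool)
        if (x & y).sum() == 0 or (x & ~y).sum() == 0:
            dropped.append(col)
    keep = [c for c in DESIGN_COLUMNS if c not in dropped]

    exog = sm.add_constant(X[keep].to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), exog).fit(
                disp=0, maxiter=200, method="newton", tol=1e-10
            )
        except Exception:
            try:
                res = sm.Logit(y.astype(float), exog).fit(disp=0, maxiter=500, method="bfgs")
            except Exception as exc:  # pragma: no cover - defensive
                raise FitError(f"{gene}/{race_group}: logistic fit failed: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", True))

    beta = {c: 0.0 for c in DESIGN_COLUMNS}
    for name, val in zip(keep, res.params[1:]):
        beta[name] = float(val)
    param_names = ("intercept",) + tuple(keep)

    coeffs = CoefficientSet(
        gene=gene,
        race_group=race_group,
        intercept=float(res.params[0]),
        beta=beta,
        r0=null_probability(n_cases, n_controls),
        dropped=tuple(dropped),
        n_cases=n_cases,
        n_controls=n_controls,
        covariance=np.asarray(res.cov_params()),
        param_names=param_names,
        converged=converged,
    )
    if compute_auc:
        scores = coeffs.linear_predictor(X)
        a, ci = auc_mann_whitney(y, scores)
        coeffs.auc, coeffs.auc_ci = a, ci
    return coeffs


def wald_ci(coeffs: CoefficientSet, name: str, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for one log-odds coefficient."""
    if coeffs.covariance is None or coeffs.param_names is None:
        raise ValueError("coefficient set carries no covariance matrix")
    if name not in coeffs.param_names:
        raise KeyError(f"{name} was dropped from the fit or unknown")
    i = coeffs.param_names.index(name)
    est = coeffs.intercept if name == "intercept" else coeffs.beta[name]
    se = math.sqrt(float(coeffs.covariance[i, i]))
    z = norm.ppf(0.5 + level / 2)
    return est - z * se, est + z * se


# ---------------------------------------------------------------------------
# Prediction and AUC


def predict(coeffs: CoefficientSet, x) -> float:
    """Predicted carrier probability r_k for one design vector (dict keyed by
    indicator name, or array in canonical order)."""
    if isinstance(x, dict):
        xv = np.array([x.get(c, 0) for c in DESIGN_COLUMNS], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
    return float(expit(coeffs.intercept + xv @ coeffs.beta_vector()))


def predict_frame(coeffs: CoefficientSet, cohort, config: CohortConfig | None = None) -> np.ndarray:
    """Vectorized r_k for every row of a cohort frame."""
    X = design_matrix(cohort, config)
    return expit(coeffs.linear_predictor(X))


def auc_mann_whitney(labels: Sequence[bool], scores: Sequence[float]):
    """Rank-based (Mann-Whitney) AUC with midrank tie correction, plus a 95%
    Hanley-McNeil confidence interval.

    Returns ``(auc, (lo, hi))``.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise FitError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks handle ties
    a = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # Hanley & McNeil (1982) closed-form variance
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se)
    return float(a), (float(lo), float(hi))


def auc(coeffs: CoefficientSet, cohort, config: CohortConfig | None = None):
    """AUC of the fitted model on a labelled cohort (cases vs controls)."""
    frame = as_frame(cohort)
    frame = frame.loc[frame["race_group"] == coeffs.race_group]
    is_case, is_control = _case_control_mask(frame, coeffs.gene)
    sub = frame.loc[is_case | is_control]
    y = (sub["brca1_status" if coeffs.gene == "BRCA1" else "brca2_status"]
         == GeneStatus.pathogenic.value).to_numpy()
    scores = coeffs.linear_predictor(design_matrix(sub, config))
    return auc_mann_whitney(y, scores)
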