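"""Synthetic cohort and variant-table generator.

The generator mirrors exactly what the inference assumes, rather than
simulating family structure causally: phenotypes (personal and family cancer
history) are drawn from baseline marginal frequencies typical of a hereditary
cancer testing population, and pathogenic-carrier status is then drawn from
the logistic model ``logit P(carrier | x) = b0 + x . beta`` where ``x`` is
the 29-indicator design vector and ``beta`` the configured true log odds
(published odds-ratio tables by default). The intercept ``b0`` is calibrated
per race group so the realized carrier prevalence matches the configured
value (~1.5% per gene in the emulated testing population).

Variants of uncertain significance are attached afterwards: each synthetic
variant is latently pathogenic with class-specific probability ``alpha_true``;
carriers of a pathogenic-latent variant are sampled from the cohort weighted
by their carrier probability (the carrier-conditional phenotype
distribution), benign-latent carriers weighted by the complement. The number
of probands per variant is geometric, so most variants are singletons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from ._tables import published_odds_ratios
from .datamodel import (
    COHORT_COLUMNS,
    BioinfoClass,
    CohortConfig,
    LabClass,
    Proband,
    VariantObservation,
    frame_to_cohort,
)
from .model import DESIGN_COLUMNS, CoefficientSet, design_matrix

RACE_GROUPS = ("european_mixed", "african_american", "asian", "hispanic")


class PhenotypeFrequencies(BaseModel):
    """Baseline (non-carrier-enriched) phenotype marginals of the simulated
    testing population. Defaults describe a cohort ascertained for personal
    or family history of breast/ovarian cancer, hence the high affected
    fraction; phenotype blocks are drawn independently."""

    p_female: float = 0.95
    p_dcis: float = 0.06
    p_bc_female: float = 0.45
    p_bc_male: float = 0.02
    p_bc_lt50: float = 0.50  # given breast cancer
    tn_dist: tuple[float, float, float] = (0.12, 0.53, 0.35)  # TN+, TN-, unknown
    p_bilateral: float = 0.05  # given breast cancer
    p_oc_female: float = 0.06
    p_oc_lt60: float = 0.60  # given ovarian cancer
    p_pancreatic: float = 0.015
    p_prostate_male: float = 0.15
    p_prostate_lt60: float = 0.30  # given prostate cancer
    # family-count category probabilities, index = count (last is the tail)
    fam_bc_lt50: tuple[float, ...] = (0.70, 0.21, 0.06, 0.03)
    fam_bc_ge50: tuple[float, ...] = (0.55, 0.30, 0.11, 0.04)
    fam_oc_lt60: tuple[float, ...] = (0.90, 0.09, 0.01)
    fam_oc_ge60: tuple[float, ...] = (0.92, 0.07, 0.01)
    fam_pancreatic: tuple[float, ...] = (0.92, 0.07, 0.01)
    fam_mbc: tuple[float, ...] = (0.985, 0.015)
    fam_prostate: tuple[float, ...] = (0.82, 0.14, 0.04)


class VusClassSpec(BaseModel):
    """One bioinformatic class of synthetic variants: how many to create,
    the true pathogenic fraction, and the prior carried into classification."""

    bioinfo_class: BioinfoClass
    n_variants: int = Field(gt=0)
    alpha_true: float = Field(ge=0.0, le=1.0)
    prior_prob: float = Field(ge=0.0, le=1.0)


def _default_class_specs() -> list[VusClassSpec]:
    # Class mix and pathogenic fractions shaped like the published
    # heterogeneity table; priors are the external calibration values.
    return [
        VusClassSpec(bioinfo_class=BioinfoClass.not_in_key_domain, n_variants=100,
                     alpha_true=0.02, prior_prob=0.02),
        VusClassSpec(bioinfo_class=BioinfoClass.C0, n_variants=60,
                     alpha_true=0.23, prior_prob=0.03),
        VusClassSpec(bioinfo_class=BioinfoClass.C65, n_variants=40,
                     alpha_true=0.76, prior_prob=0.81),
        VusClassSpec(bioinfo_class=BioinfoClass.splice_high_damage, n_variants=30,
                     alpha_true=0.91, prior_prob=0.97),
        VusClassSpec(bioinfo_class=BioinfoClass.denovo_donor_moderate, n_variants=30,
                     alpha_true=0.15, prior_prob=0.30),
    ]


class SimulationConfig(BaseModel):
    """Full specification of one synthetic study; the seed determines every
    draw."""

    n_probands: int = Field(gt=0)
    gene: str = "BRCA1"
    carrier_prevalence: float = Field(default=0.015, gt=0.0, lt=1.0)
    race_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "european_mixed": 0.80,
            "african_american": 0.07,
            "asian": 0.05,
            "hispanic": 0.08,
        }
    )
    phenotype_freqs: PhenotypeFrequencies = Field(default_factory=PhenotypeFrequencies)
    # Override of the generative odds ratios (indicator -> OR), applied to all
    # race groups. None = published per-group tables; {} = null model (all
    # OR 1). Missing indicators default to OR 1.
    true_or: dict[str, float] | None = None
    class_specs: list[VusClassSpec] = Field(default_factory=_default_class_specs)
    singleton_prob: float = Field(default=0.65, gt=0.0, le=1.0)
    lab_pathogenic_rate: float = Field(default=0.20, ge=0.0, le=1.0)
    lab_vlp_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.gene not in ("BRCA1", "BRCA2"):
            raise ValueError("gene must be BRCA1 or BRCA2")
        if set(self.race_mix) - set(RACE_GROUPS):
            raise ValueError(f"race_mix keys must be among {RACE_GROUPS}")
        if abs(sum(self.race_mix.values()) - 1.0) > 1e-9:
            raise ValueError("race_mix must sum to 1 within 1e-9")
        return self


class CalibrationError(RuntimeError):
    """Requested prevalence unattainable under the phenotype distribution."""


def true_coefficients(config: SimulationConfig, race_group: str) -> CoefficientSet:
    """Generative coefficient set for one race group (intercept = 0; it is
    calibrated separately during simulation)."""
    if config.true_or is None:
        ors = published_odds_ratios(config.gene, race_group)
    else:
        ors = {k: config.true_or.get(k) for k in DESIGN_COLUMNS}
    beta = {k: (0.0 if v is None else float(np.log(v))) for k, v in ors.items()}
    dropped = tuple(k for k, v in ors.items() if v is None)
    return CoefficientSet(
        gene=config.gene,
        race_group=race_group,
        intercept=0.0,
        beta=beta,
        r0=config.carrier_prevalence,
        dropped=dropped,
    )


def calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(b0 + eta)) = target for the intercept b0 by root
    bracketing; raises :class:`CalibrationError` when no bracket exists."""
    if not 0.0 < target < 1.0:
        raise CalibrationError("target prevalence must lie in (0, 1)")

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target

    lo, hi = -40.0, 15.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"prevalence {target} not attainable under the phenotype distribution"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def _draw_categorical(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(len(p), size=n, p=p)


def simulate_cohort_frame(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort frame; includes a ``p_carrier`` column with the
    generative carrier probability (dropped by :func:`vusclinlr.io.write_cohort`,
    used by :func:`simulate_vus_assignments`)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_probands
    pf = config.phenotype_freqs

    groups = sorted(config.race_mix)
    race = rng.choice(groups, size=n, p=[config.race_mix[g] for g in groups])
    female = rng.random(n) < pf.p_female

    dcis = rng.random(n) < pf.p_dcis
    p_bc = np.where(female, pf.p_bc_female, pf.p_bc_male)
    has_bc = rng.random(n) < p_bc
    bc_lt50 = rng.random(n) < pf.p_bc_lt50
    bc_age = np.where(bc_lt50, rng.integers(25, 50, size=n), rng.integers(50, 85, size=n))
    tn_idx = _draw_categorical(rng, pf.tn_dist, n)
    tn_map = np.array(["tn_pos", "tn_neg", "tn_unknown"])
    bilateral = rng.random(n) < pf.p_bilateral

    has_oc = female & (rng.random(n) < pf.p_oc_female)
    oc_lt60 = rng.random(n) < pf.p_oc_lt60
    oc_age = np.where(oc_lt60, rng.integers(30, 60, size=n), rng.integers(60, 85, size=n))

    pancreatic = rng.random(n) < pf.p_pancreatic
    has_pr = ~female & (rng.random(n) < pf.p_prostate_male)
    pr_lt60 = rng.random(n) < pf.p_prostate_lt60
    pr_age = np.where(pr_lt60, rng.integers(40, 60, size=n), rng.integers(60, 85, size=n))

    fam = {
        "fam_bc_lt50": _draw_categorical(rng, pf.fam_bc_lt50, n),
        "fam_bc_ge50": _draw_categorical(rng, pf.fam_bc_ge50, n),
        "fam_oc_lt60": _draw_categorical(rng, pf.fam_oc_lt60, n),
        "fam_oc_ge60": _draw_categorical(rng, pf.fam_oc_ge60, n),
        "fam_pancreatic": _draw_categorical(rng, pf.fam_pancreatic, n),
        "fam_mbc": _draw_categorical(rng, pf.fam_mbc, n),
        "fam_prostate": _draw_categorical(rng, pf.fam_prostate, n),
    }

    frame = pd.DataFrame(
        {
            "proband_id": [f"P{i:07d}" for i in range(n)],
            "race_group": race,
            "sex": np.where(female, "female", "male"),
            "brca1_status": "none",
            "brca2_status": "none",
            "other_gene_plp": False,
            "history_sufficient": True,
            "dcis": dcis,
            "bc_age_dx": np.where(has_bc, bc_age.astype(float), np.nan),
            "bc_tn_status": [tn_map[i] if b else None for i, b in zip(tn_idx, has_bc)],
            "bc_bilateral": has_bc & bilateral,
            "bc_male": has_bc & ~female,
            "oc_age_dx": np.where(has_oc, oc_age.astype(float), np.nan),
            "pancreatic": pancreatic,
            "prca_age_dx": np.where(has_pr, pr_age.astype(float), np.nan),
            **{k: v for k, v in fam.items()},
        },
        columns=list(COHORT_COLUMNS),
    )

    # carrier status from the logistic model, intercept calibrated per group
    X = design_matrix(frame)
    p_carrier = np.empty(n, dtype=float)
    for g in groups:
        mask = (race == g)
        if not mask.any():
            continue
        coeffs = true_coefficients(config, g)
        eta = X.loc[mask].to_numpy(dtype=float) @ coeffs.beta_vector()
        b0 = calibrate_intercept(eta, config.carrier_prevalence)
        p_carrier[mask] = expit(b0 + eta)
    carrier = rng.random(n) < p_carrier
    status_col = "brca1_status" if config.gene == "BRCA1" else "brca2_status"
    frame.loc[carrier, status_col] = "pathogenic"
    frame["p_carrier"] = p_carrier
    return frame


def simulate_cohort(config: SimulationConfig) -> list[Proband]:
    """Proband-object view of :func:`simulate_cohort_frame`."""
    return frame_to_cohort(simulate_cohort_frame(config))


class SizingError(RuntimeError):
    """More variant observations requested than eligible probands."""


def simulate_vus_assignments(cohort_frame: pd.DataFrame, config: SimulationConfig):
    """Attach synthetic VUS to a simulated cohort.

    Returns ``(cohort, observations, truth)`` where ``cohort`` is a copy of
    the input frame with the sampled probands' gene status set to the
    variant's laboratory class, ``observations`` is a list of
    :class:`VariantObservation`, and ``truth`` is a DataFrame mapping
    ``variant_id`` to its latent status (for evaluation only — never an input
    to inference).
    """
    if "p_carrier" not in cohort_frame.columns:
        raise ValueError("cohort frame must come from simulate_cohort_frame "
                         "(missing generative p_carrier column)")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    frame = cohort_frame.copy()
    status_col = "brca1_status" if config.gene == "BRCA1" else "brca2_status"

    pool = np.flatnonzero((frame[status_col] == "none").to_numpy())
    available = np.ones(len(pool), dtype=bool)
    p = frame["p_carrier"].to_numpy()[pool]

    observations: list[VariantObservation] = []
    truth_rows = []
    counter = 0
    for spec in config.class_specs:
        for _ in range(spec.n_variants):
            counter += 1
            vid = f"{config.gene}:synthvar{counter:05d}"
            latent = bool(rng.random() < spec.alpha_true)
            n_obs = int(rng.geometric(config.singleton_prob))
            if latent:
                u = rng.random()
                if u < config.lab_pathogenic_rate:
                    lab = LabClass.pathogenic
                elif u < config.lab_pathogenic_rate + config.lab_vlp_rate:
                    lab = LabClass.vlp
                else:
                    lab = LabClass.vus
            else:
                lab = LabClass.vus

            idx_avail = np.flatnonzero(available)
            if n_obs > idx_avail.size:
                raise SizingError(
                    f"{n_obs} observations requested but only {idx_avail.size} "
                    "eligible probands remain"
                )
            w = p[idx_avail] if latent else 1.0 - p[idx_avail]
            w = np.clip(w, 1e-12, None)
            pick = rng.choice(idx_avail, size=n_obs, replace=False, p=w / w.sum())
            available[pick] = False
            rows = pool[pick]
            frame.iloc[rows, frame.columns.get_loc(status_col)] = lab.value
            for r in rows:
                observations.append(
                    VariantObservation(
                        proband_id=str(frame.iloc[r]["proband_id"]),
                        gene=config.gene,
                        variant_id=vid,
                        lab_class=lab,
                        bioinfo_class=spec.bioinfo_class,
                        prior_prob=spec.prior_prob,
                    )
                )
            truth_rows.append(
                {
                    "variant_id": vid,
                    "bioinfo_class": spec.bioinfo_class.value,
                    "latent_pathogenic": latent,
                    "n_probands": n_obs,
                    "lab_class": lab.value,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return frame, observations, truth


def simulate_class_lrs(n_variants: int, alpha_true: float,
                       rng: np.random.Generator, sigma: float = 2.0):
    """Draw per-variant combined likelihood ratios directly from the admixture
    model with lognormal evidence.

    Benign variants have ``ln LR ~ N(-sigma^2/2, sigma^2)`` (so E[LR] = 1, as
    a calibrated likelihood ratio must under the benign hypothesis) and
    pathogenic variants have the tilted density ``N(+sigma^2/2, sigma^2)``.
    ``sigma`` controls how informative the evidence is. Returns
    ``(lrs, latent)`` arrays.
    """
    if not 0.0 <= alpha_true <= 1.0:
        raise ValueError("alpha_true must lie in [0, 1]")
    latent = rng.random(n_variants) < alpha_true
    ln_lr = rng.normal(-0.5 * sigma**2, sigma, size=n_variants) + latent * sigma**2
    return np.exp(ln_lr), latent
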