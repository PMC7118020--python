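"""Per-individual likelihood ratios and per-variant evidence aggregation.

For tested individual k with predicted carrier probability r_k and null
carrier probability r0 (both from the carrier model of the individual's own
gene x race-group stratum), the clinical-history likelihood ratio in favour
of pathogenicity is

    LR_k = r_k (1 - r0) / ((1 - r_k) r0)

i.e. the odds of the model-predicted carrier probability against the odds
under the null that the variant is unrelated to clinical history. Per-variant
evidence is the product of the LRs of all probands carrying the variant;
all accumulation happens in log10 space.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    BioinfoClass,
    CohortConfig,
    LabClass,
    VariantObservation,
    as_frame,
)
from .io import IntegrityError, apply_exclusions
from .model import CoefficientSet, design_matrix

#: combined_lr is materialized only within this range; beyond it the log form
#: is authoritative and combined_lr carries +/- inf.
_LOG10_CLAMP = 300.0


@dataclasses.dataclass(frozen=True)
class IndividualLR:
    """Evidence contributed by one proband."""

    proband_id: str
    gene: str
    race_group: str
    r_k: float
    r0: float
    lr: float
    log10_lr: float


@dataclasses.dataclass
class VariantEvidence:
    """Combined clinical-history evidence for one variant."""

    variant_id: str
    gene: str
    n_probands: int
    sum_log10_lr: float
    combined_lr: float
    lab_class: LabClass
    bioinfo_class: BioinfoClass
    prior_prob: float
    posterior: float | None = None
    shared_proband: bool = False  # a contributing proband carries >1 VUS in this gene


def individual_lr(r_k: float, r0: float, proband_id: str = "", gene: str = "",
                  race_group: str = "") -> IndividualLR:
    """Likelihood ratio for one individual, computed in log space."""
    if not 0.0 < r_k < 1.0:
        raise ValueError(f"r_k must lie strictly in (0,1), got {r_k}")
    if not 0.0 < r0 < 1.0:
        raise ValueError(f"r0 must lie strictly in (0,1), got {r0}")
    log10_lr = (math.log10(r_k) + math.log10(1.0 - r0)
                - math.log10(1.0 - r_k) - math.log10(r0))
    return IndividualLR(
        proband_id=proband_id,
        gene=gene,
        race_group=race_group,
        r_k=r_k,
        r0=r0,
        lr=10.0 ** log10_lr,
        log10_lr=log10_lr,
    )


def _materialize_lr(sum_log10: float) -> float:
    if sum_log10 > _LOG10_CLAMP:
        return math.inf
    if sum_log10 < -_LOG10_CLAMP:
        return 0.0
    return 10.0 ** sum_log10


def combine_variant(observations: list[IndividualLR], variant_id: str, gene: str,
                    lab_class: LabClass = LabClass.vus,
                    bioinfo_class: BioinfoClass = BioinfoClass.other,
                    prior_prob: float = 0.5) -> VariantEvidence:
    """Multiply individual LRs (sum in log10 space) into per-variant evidence."""
    if not observations:
        raise ValueError("cannot combine an empty list of observations")
    if any(o.gene != gene for o in observations if o.gene):
        raise IntegrityError(f"mixed genes in observations for {variant_id}")
    sum_log10 = float(np.sum([o.log10_lr for o in observations]))
    return VariantEvidence(
        variant_id=variant_id,
        gene=gene,
        n_probands=len(observations),
        sum_log10_lr=sum_log10,
        combined_lr=_materialize_lr(sum_log10),
        lab_class=lab_class,
        bioinfo_class=bioinfo_class,
        prior_prob=prior_prob,
    )


class ConfigurationError(RuntimeError):
    """A required coefficient set is missing."""


def score_cohort(cohort, variant_table: list[VariantObservation],
                 coefficient_sets: dict[tuple[str, str], CoefficientSet],
                 config: CohortConfig | None = None,
                 ) -> tuple[list[VariantEvidence], pd.DataFrame]:
    """Score every variant observation whose proband survives the per-gene
    exclusions.

    ``coefficient_sets`` maps ``(gene, race_group)`` to a fitted model; a
    missing stratum that is actually needed raises
    :class:`ConfigurationError`. Returns the evidence list sorted by gene then
    variant id, plus a per-proband breakdown frame.
    """
    config = config or CohortConfig()
    frame = as_frame(cohort)

    # per-gene retained probands and predicted r_k, computed once
    rk_by_gene: dict[str, pd.Series] = {}
    race_of: dict[str, str] = dict(zip(frame["proband_id"], frame["race_group"]))
    for gene in ("BRCA1", "BRCA2"):
        if not any(o.gene == gene for o in variant_table):
            continue
        retained, _ = apply_exclusions(frame, gene)
        X = design_matrix(retained, config)
        rk = pd.Series(np.nan, index=retained["proband_id"])
        for g in retained["race_group"].unique():
            mask = (retained["race_group"] == g).to_numpy()
            coeffs = coefficient_sets.get((gene, g))
            if coeffs is None:
                needed = {race_of[o.proband_id] for o in variant_table
                          if o.gene == gene and o.proband_id in set(retained["proband_id"])}
                if g in needed:
                    raise ConfigurationError(f"no coefficient set for stratum ({gene}, {g})")
                continue
            rk.iloc[mask] = expit(coeffs.linear_predictor(X.loc[mask]))
        rk_by_gene[gene] = rk

    # count VUS/VLP memberships per (proband, gene) to flag shared probands
    n_vus_of: dict[tuple[str, str], int] = {}
    for o in variant_table:
        key = (o.proband_id, o.gene)
        n_vus_of[key] = n_vus_of.get(key, 0) + 1

    per_variant: dict[tuple[str, str], list[IndividualLR]] = {}
    meta: dict[tuple[str, str], VariantObservation] = {}
    shared: dict[tuple[str, str], bool] = {}
    breakdown_rows = []
    for o in variant_table:
        rk = rk_by_gene.get(o.gene)
        if rk is None or o.proband_id not in rk.index:
            continue  # proband excluded for this gene
        r_k = float(rk.loc[o.proband_id])
        if np.isnan(r_k):
            continue
        g = race_of[o.proband_id]
        coeffs = coefficient_sets[(o.gene, g)]
        ilr = individual_lr(r_k, coeffs.r0, proband_id=o.proband_id, gene=o.gene,
                            race_group=g)
        key = (o.gene, o.variant_id)
        per_variant.setdefault(key, []).append(ilr)
        meta.setdefault(key, o)
        if n_vus_of[(o.proband_id, o.gene)] > 1:
            shared[key] = True
        breakdown_rows.append(
            {
                "gene": o.gene,
                "variant_id": o.variant_id,
                "proband_id": o.proband_id,
                "race_group": g,
                "r_k": r_k,
                "r0": coeffs.r0,
                "log10_lr": ilr.log10_lr,
            }
        )

    evidence = []
    for key in sorted(per_variant):
        gene, vid = key
        o = meta[key]
        ev = combine_variant(per_variant[key], vid, gene, lab_class=o.lab_class,
                             bioinfo_class=o.bioinfo_class, prior_prob=o.prior_prob)
        ev.shared_proband = shared.get(key, False)
        evidence.append(ev)
    breakdown = pd.DataFrame(
        breakdown_rows,
        columns=["gene", "variant_id", "proband_id", "race_group", "r_k", "r0", "log10_lr"],
    )
    return evidence, breakdown


def evidence_frame(evidence: list[VariantEvidence]) -> pd.DataFrame:
    """Tabular view of per-variant evidence (log-LR column is log base 10)."""
    return pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "gene": e.gene,
                "n_probands": e.n_probands,
                "sum_log10_lr": e.sum_log10_lr,
                "combined_lr": e.combined_lr,
                "lab_class": e.lab_class.value,
                "bioinfo_class": e.bioinfo_class.value,
                "prior_prob": e.prior_prob,
                "shared_proband": e.shared_proband,
            }
            for e in evidence
        ]
    )
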