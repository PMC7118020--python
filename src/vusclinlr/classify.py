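"""Posterior probabilities of pathogenicity and the end-to-end pipeline.

The multifactorial combination is Bayes' rule on the odds scale: posterior
odds = prior odds x combined LR, i.e.

    posterior = prior * LR / (prior * LR + 1 - prior)

Qualitative evidence labels use odds thresholds (default 10:1 for, 10:1
against pathogenicity); the five-or-more-probands rule marks variants whose
odds evidence rests on enough independent families to be considered
supporting evidence on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import ClassSummary, class_table
from .datamodel import BioinfoClass, CohortConfig, as_frame, cohort_to_frame
from .evidence import VariantEvidence, evidence_frame, score_cohort
from .io import apply_exclusions, read_cohort, read_priors, read_variants, write_json
from .model import FitError, fit

logger = logging.getLogger("vusclinlr")

#: Default external calibration priors per bioinformatic class (published
#: values from earlier multifactorial studies; user-supplied tables override).
DEFAULT_PRIORS: dict[BioinfoClass, float] = {
    BioinfoClass.not_in_key_domain: 0.02,
    BioinfoClass.C0: 0.03,
    BioinfoClass.C15_C25: 0.29,
    BioinfoClass.C35_C55: 0.66,
    BioinfoClass.C65: 0.81,
    BioinfoClass.splice_high_damage: 0.97,
    BioinfoClass.splice_moderate_damage: 0.34,
    BioinfoClass.denovo_donor_increased: 0.64,
    BioinfoClass.denovo_donor_moderate: 0.30,
    BioinfoClass.other: 0.50,
}


def posterior(prior: float, lr: float) -> float:
    """Bayes posterior probability of pathogenicity on the odds scale,
    computed in log space for numerical stability."""
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must lie in [0, 1]")
    if lr <= 0 and not math.isinf(lr):
        raise ValueError("lr must be positive")
    if prior == 0.0:
        return 0.0
    if prior == 1.0:
        return 1.0
    if math.isinf(lr):
        return 1.0
    # log posterior odds
    lpo = math.log(prior) - math.log1p(-prior) + math.log(lr)
    if lpo > 0:
        return 1.0 / (1.0 + math.exp(-lpo))
    e = math.exp(lpo)
    return e / (1.0 + e)


@dataclasses.dataclass(frozen=True)
class Thresholds:
    lr_pathogenic: float = 10.0
    lr_benign: float = 0.1


def label_evidence(combined_lr: float, thresholds: Thresholds = Thresholds()) -> str:
    """Qualitative label from the odds thresholds: >10:1 in favour supports
    pathogenicity, >10:1 against supports benign impact."""
    if combined_lr > thresholds.lr_pathogenic:
        return "supports_pathogenic"
    if combined_lr < thresholds.lr_benign:
        return "supports_benign"
    return "indeterminate"


@dataclasses.dataclass
class ClassificationRecord:
    variant_id: str
    gene: str
    prior_prob: float
    combined_lr: float
    sum_log10_lr: float
    posterior: float
    evidence_label: str
    n_probands: int
    meets_family_count_rule: bool  # evidence based on >= 5 probands


def classify_evidence(evidence: list[VariantEvidence],
                      priors: dict[BioinfoClass, float] | None = None,
                      thresholds: Thresholds = Thresholds(),
                      min_families: int = 5) -> list[ClassificationRecord]:
    """Attach posteriors and qualitative labels to scored evidence.

    The prior for each variant is taken from ``priors`` by bioinformatic
    class when available, else from the per-variant ``prior_prob`` input.
    """
    records = []
    for e in evidence:
        prior = (priors or {}).get(e.bioinfo_class, e.prior_prob)
        post = posterior(prior, e.combined_lr)
        e.posterior = post
        records.append(
            ClassificationRecord(
                variant_id=e.variant_id,
                gene=e.gene,
                prior_prob=prior,
                combined_lr=e.combined_lr,
                sum_log10_lr=e.sum_log10_lr,
                posterior=post,
                evidence_label=label_evidence(e.combined_lr, thresholds),
                n_probands=e.n_probands,
                meets_family_count_rule=e.n_probands >= min_families,
            )
        )
    return records


def classification_frame(records: list[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def class_table_frame(summaries: list[ClassSummary], mode: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mode": mode,
                "bioinfo_class": s.class_label,
                "n_variants": s.n_variants,
                "alpha_hat": s.alpha_hat,
                "ci_lower": s.ci_lower,
                "ci_upper": s.ci_upper,
                "boundary_flag": s.boundary_flag,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _apply_sensitivity(frame: pd.DataFrame, mode: str | None) -> pd.DataFrame:
    if mode is None:
        return frame
    if mode == "exclude-unknown":
        if "race_raw" not in frame.columns:
            return frame
        raw = frame["race_raw"].fillna("")
        return frame.loc[~raw.isin(["mixed", "unknown"])].reset_index(drop=True)
    if mode == "exclude-prev-tested":
        if "prev_tested_negative" not in frame.columns:
            return frame
        return frame.loc[~frame["prev_tested_negative"].fillna(False).astype(bool)].reset_index(drop=True)
    raise ValueError(f"unknown sensitivity mode {mode!r}")


def run_pipeline(cohort_path, variants_path, priors_path, outdir,
                 config: CohortConfig | None = None,
                 sensitivity: str | None = None,
                 min_cases: int = 2) -> dict:
    """Run validate -> exclude -> fit -> score -> heterogeneity -> classify.

    Writes ``evidence.tsv``, ``class_table.tsv``, ``classifications.tsv`` and
    ``manifest.json`` into ``outdir`` and returns the manifest dict. Strata
    with fewer than ``min_cases`` pathogenic carriers are skipped for fitting;
    scoring fails with a configuration error only if such a stratum is
    actually needed by an observation.
    """
    t0 = time.monotonic()
    config = config or CohortConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(cohort_path, config)
    observations = read_variants(variants_path, config)
    priors = read_priors(priors_path, config) if priors_path else dict(DEFAULT_PRIORS)
    logger.info("loaded %d probands, %d observations", len(cohort), len(observations))

    frame = cohort_to_frame(cohort)
    frame = _apply_sensitivity(frame, sensitivity)

    genes = sorted({o.gene for o in observations})
    coefficient_sets = {}
    reports = {}
    for gene in genes:
        retained, report = apply_exclusions(frame, gene)
        reports[gene] = dataclasses.asdict(report)
        for g in sorted(retained["race_group"].unique()):
            sub = retained.loc[retained["race_group"] == g]
            status = sub["brca1_status" if gene == "BRCA1" else "brca2_status"]
            if (status == "pathogenic").sum() < min_cases or (status == "none").sum() < min_cases:
                logger.warning("skipping fit for sparse stratum (%s, %s)", gene, g)
                continue
            try:
                coefficient_sets[(gene, g)] = fit(retained, gene, g, config)
            except FitError as exc:
                logger.warning("fit failed for (%s, %s): %s", gene, g, exc)
        logger.info("stage fit[%s] done at %.1fs", gene, time.monotonic() - t0)

    evidence, breakdown = score_cohort(frame, observations, coefficient_sets, config)
    logger.info("stage score done at %.1fs (%d variants)", time.monotonic() - t0, len(evidence))

    tables = []
    for mode_name, include_p in (("with_pathogenic", True), ("vus_vlp_only", False)):
        tables.append(class_table_frame(class_table(evidence, include_pathogenic=include_p),
                                        mode_name))
    het_frame = pd.concat(tables, ignore_index=True)

    records = classify_evidence(evidence, priors)
    logger.info("stage classify done at %.1fs", time.monotonic() - t0)

    ev_frame = evidence_frame(evidence)
    ev_frame.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    het_frame.to_csv(outdir / "class_table.tsv", sep="\t", index=False)
    classification_frame(records).to_csv(outdir / "classifications.tsv", sep="\t", index=False)
    breakdown.to_csv(outdir / "per_proband_lr.tsv", sep="\t", index=False)

    cfg_json = json.dumps(config.model_dump(), sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "sensitivity": sensitivity,
        "n_probands": int(len(frame)),
        "n_observations": len(observations),
        "n_variants_scored": len(evidence),
        "exclusion_reports": reports,
        "strata_fitted": [list(k) for k in sorted(coefficient_sets)],
        "auc": {f"{g}/{r}": coefficient_sets[(g, r)].auc for (g, r) in sorted(coefficient_sets)},
        "elapsed_s": round(time.monotonic() - t0, 2),
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
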