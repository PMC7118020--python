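"""Admixture (heterogeneity) analysis of per-variant likelihood ratios.

Within a bioinformatic class of N variants with combined likelihood ratios
LR_i, the probability that a fraction alpha of the class is pathogenic gives
the mixture likelihood

    L(alpha) = prod_i [ alpha * LR_i + (1 - alpha) ]

maximized over alpha in [0, 1]. Approximate 95% confidence limits are the
alpha values where 2 ln L drops 3.84 (the chi-square_1 95% cutoff) below its
maximum, and differences of alpha across partitions of the variant space are
tested with likelihood-ratio chi-square tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .datamodel import BioinfoClass, LabClass

#: 95% chi-square(1) cutoff defining the profile-likelihood CI.
CHI2_95_DROP = 3.84

_BOUNDARY_TOL = 1e-7


@dataclasses.dataclass
class ClassSummary:
    """Estimated pathogenic fraction for one variant class."""

    class_label: str
    n_variants: int
    alpha_hat: float
    ci_lower: float
    ci_upper: float
    loglik_max: float
    boundary_flag: str  # interior | at_zero | at_one
    flat: bool = False  # likelihood carries no information (all LR = 1)


@dataclasses.dataclass
class PartitionTest:
    """Likelihood-ratio test of equal alpha across parts of a partition."""

    pooled: ClassSummary
    parts: list[ClassSummary]
    chi2: float
    df: int
    p_value: float
    boundary_involved: bool  # a part or the pooled fit sits on 0 or 1; the
    # chi-square reference is then conservative (mixture chi-square ignored)


def admixture_loglik(alpha: float, lrs=None, ln_lrs=None) -> float:
    """Log-likelihood sum_i ln(alpha * LR_i + 1 - alpha).

    Accepts raw ``lrs`` or natural-log ``ln_lrs`` (preferred for extreme
    evidence); each term is evaluated as logaddexp(ln alpha + ln LR_i,
    ln(1 - alpha)) so enormous or tiny LRs never overflow.
    """
    if ln_lrs is None:
        if lrs is None:
            raise ValueError("provide lrs or ln_lrs")
        lrs = np.asarray(lrs, dtype=float)
        if np.any(lrs <= 0) or np.any(~np.isfinite(lrs)):
            raise ValueError("all LRs must be positive and finite")
        ln_lrs = np.log(lrs)
    else:
        ln_lrs = np.asarray(ln_lrs, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return 0.0
    if alpha == 1.0:
        return float(np.sum(ln_lrs))
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log(alpha) + ln_lrs, np.log1p(-alpha))
    return float(np.sum(terms))


def estimate_alpha(lrs=None, ln_lrs=None, class_label: str = "",
                   xatol: float = 1e-8) -> ClassSummary:
    """Maximize the admixture log-likelihood over alpha in [0, 1] (bounded
    Brent search) and attach the profile-likelihood CI.

    A flat likelihood (every LR = 1) is unidentifiable: by convention
    alpha_hat = 0 with CI [0, 1], flagged and warned about.
    """
    if ln_lrs is None:
        lrs = np.asarray(lrs, dtype=float)
        if lrs.size == 0:
            raise ValueError("need at least one variant")
        if np.any(lrs <= 0) or np.any(~np.isfinite(lrs)):
            raise ValueError("all LRs must be positive and finite")
        ln_lrs = np.log(lrs)
    else:
        ln_lrs = np.asarray(ln_lrs, dtype=float)
        if ln_lrs.size == 0:
            raise ValueError("need at least one variant")

    if np.all(np.abs(ln_lrs) < 1e-12):
        warnings.warn(
            f"admixture likelihood is flat for class {class_label or '<unnamed>'}; "
            "alpha is unidentifiable",
            stacklevel=2,
        )
        return ClassSummary(
            class_label=class_label,
            n_variants=int(ln_lrs.size),
            alpha_hat=0.0,
            ci_lower=0.0,
            ci_upper=1.0,
            loglik_max=0.0,
            boundary_flag="at_zero",
            flat=True,
        )

    def nll(a: float) -> float:
        return -admixture_loglik(a, ln_lrs=ln_lrs)

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    candidates = [(admixture_loglik(a, ln_lrs=ln_lrs), a)
                  for a in (0.0, 1.0, float(res.x))]
    loglik_max, alpha_hat = max(candidates)

    if alpha_hat < _BOUNDARY_TOL:
        alpha_hat, flag = 0.0, "at_zero"
    elif alpha_hat > 1.0 - _BOUNDARY_TOL:
        alpha_hat, flag = 1.0, "at_one"
    else:
        flag = "interior"
    loglik_max = admixture_loglik(alpha_hat, ln_lrs=ln_lrs)

    lo, hi = profile_ci(ln_lrs=ln_lrs, alpha_hat=alpha_hat, loglik_max=loglik_max)
    return ClassSummary(
        class_label=class_label,
        n_variants=int(ln_lrs.size),
        alpha_hat=alpha_hat,
        ci_lower=lo,
        ci_upper=hi,
        loglik_max=loglik_max,
        boundary_flag=flag,
    )


def profile_ci(lrs=None, ln_lrs=None, alpha_hat: float = None,
               loglik_max: float = None, drop: float = CHI2_95_DROP):
    """Profile-likelihood confidence limits: the alpha values on either side
    of alpha_hat where 2[l(alpha_hat) - l(alpha)] = ``drop``, truncated at the
    parameter bounds 0 and 1."""
    if ln_lrs is None:
        ln_lrs = np.log(np.asarray(lrs, dtype=float))
    ln_lrs = np.asarray(ln_lrs, dtype=float)

    def g(a: float) -> float:
        return 2.0 * (loglik_max - admixture_loglik(a, ln_lrs=ln_lrs)) - drop

    if alpha_hat > 0.0 and g(0.0) > 0.0:
        lo = float(brentq(g, 0.0, alpha_hat, xtol=1e-12))
    else:
        lo = 0.0
    if alpha_hat < 1.0 and g(1.0) > 0.0:
        hi = float(brentq(g, alpha_hat, 1.0, xtol=1e-12))
    else:
        hi = 1.0
    return lo, hi


def partition_test(lrs_by_class: dict) -> PartitionTest:
    """Likelihood-ratio test of a common alpha against class-specific alphas.

    ``lrs_by_class`` maps a class label to its per-variant LR array. Empty
    classes are dropped with a warning and the degrees of freedom adjusted.
    """
    parts_lrs = {}
    for label, lrs in lrs_by_class.items():
        arr = np.asarray(lrs, dtype=float)
        if arr.size == 0:
            warnings.warn(f"dropping empty class {label!r} from partition test",
                          stacklevel=2)
            continue
        parts_lrs[label] = arr
    if len(parts_lrs) < 2:
        raise ValueError("partition test needs at least two non-empty classes")

    parts = [estimate_alpha(lrs, class_label=str(label))
             for label, lrs in parts_lrs.items()]
    pooled = estimate_alpha(np.concatenate(list(parts_lrs.values())),
                            class_label="pooled")
    stat = 2.0 * (sum(p.loglik_max for p in parts) - pooled.loglik_max)
    stat = max(stat, 0.0)
    df = len(parts) - 1
    boundary = pooled.boundary_flag != "interior" or any(
        p.boundary_flag != "interior" for p in parts
    )
    return PartitionTest(
        pooled=pooled,
        parts=parts,
        chi2=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        boundary_involved=boundary,
    )


def class_table(evidence, include_pathogenic: bool = True) -> list[ClassSummary]:
    """Run the admixture analysis per bioinformatic class.

    ``include_pathogenic`` mirrors the two published analysis modes: with all
    variants meeting the class definition (pathogenic + VLP + VUS), or with
    laboratory-pathogenic variants removed (VLP + VUS only).
    """
    groups: dict[str, list[float]] = {}
    for e in evidence:
        if not include_pathogenic and e.lab_class == LabClass.pathogenic:
            continue
        label = e.bioinfo_class.value if isinstance(e.bioinfo_class, BioinfoClass) else str(e.bioinfo_class)
        groups.setdefault(label, []).append(e.sum_log10_lr)
    out = []
    for label in sorted(groups):
        ln_lrs = np.asarray(groups[label], dtype=float) * np.log(10.0)
        out.append(estimate_alpha(ln_lrs=ln_lrs, class_label=label))
    return out
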