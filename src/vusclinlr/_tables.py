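"""Published odds-ratio estimates used to seed the synthetic-cohort generative model.

Each entry maps a design-matrix indicator name to the reported odds ratio for
that predictor of pathogenic-carrier status, per gene and race/ethnicity group.
Cells that could not be estimated in the source regressions (too few exposed
carriers) are absent; the generator treats them as a null effect (OR = 1).
"""

from __future__ import annotations

# Row order matches the design-matrix layout: 14 personal-history indicators
# followed by 15 family-history indicators.
_ROWS = (
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

# Columns: (BRCA1 | BRCA2) x (european_mixed, african_american, asian, hispanic).
# None marks an inestimable cell.
_OR_GRID = {
    "dcis":              ((1.0, 0.2, 0.8, 0.6), (1.3, 0.9, 0.5, 1.6)),
    "tn_pos_lt50":       ((15.9, 15.7, 23.5, 25.9), (3.1, 3.4, 1.5, 2.1)),
    "tn_pos_ge50":       ((5.1, 2.8, 9.0, 4.6), (2.9, 1.5, 1.9, 0.9)),
    "tn_neg_lt50":       ((1.7, 2.5, 3.1, 2.9), (2.5, 2.4, 1.0, 2.0)),
    "tn_neg_ge50":       ((0.5, 0.5, 1.3, 0.7), (1.5, 1.4, 0.9, 1.8)),
    "tn_unk_lt50":       ((3.8, 5.4, 4.2, 4.8), (2.4, 3.2, 0.9, 1.8)),
    "tn_unk_ge50":       ((1.1, 1.2, 2.0, None), (1.4, 1.4, 1.2, 1.2)),
    "bilateral_bc":      ((1.6, 1.8, 1.7, 2.2), (1.2, 2.0, 0.8, 1.1)),
    "ov_lt60":           ((10.7, 8.6, 17.2, 17.5), (4.0, 3.0, 1.4, 3.9)),
    "ov_ge60":           ((4.2, 1.1, 12.0, 14.1), (4.9, 4.3, 4.7, 2.6)),
    "pancreatic":        ((1.3, 2.3, None, None), (3.9, 2.4, 5.1, 6.3)),
    "male_bc":           ((1.1, None, None, None), (6.3, 4.0, 1.8, 5.6)),
    "prostate_lt60":     ((1.1, None, None, None), (1.4, 3.2, None, 10.3)),
    "prostate_ge60":     ((1.9, None, None, None), (2.4, 9.7, 5.1, 16.3)),
    "fam_bc_lt50_1":     ((2.2, 3.1, 2.8, 2.7), (1.5, 1.3, 1.3, 1.5)),
    "fam_bc_lt50_2":     ((3.7, 5.1, 3.0, 5.0), (2.0, 1.4, 1.5, 1.3)),
    "fam_bc_lt50_3plus": ((5.3, 12.0, 8.3, 9.1), (3.2, 1.8, 3.1, 3.4)),
    "fam_bc_ge50_1":     ((0.9, 0.7, 1.5, 1.1), (1.1, 0.8, 2.4, 1.3)),
    "fam_bc_ge50_2":     ((0.7, 0.5, 0.6, 0.7), (0.9, 0.8, 1.4, 0.9)),
    "fam_bc_ge50_3plus": ((0.7, 0.7, 2.0, 0.9), (0.7, 1.4, 3.0, 0.4)),
    "fam_oc_lt60_1":     ((3.2, 1.7, 3.4, 1.9), (1.4, 2.1, 1.5, 1.4)),
    "fam_oc_lt60_2plus": ((5.4, 0.4, 4.8, 3.0), (1.4, 0.6, 1.0, 1.0)),
    "fam_oc_ge60_1":     ((1.7, 2.3, 1.8, 1.9), (1.6, 0.7, 1.2, 1.5)),
    "fam_oc_ge60_2plus": ((1.6, 2.7, 5.6, 2.0), (1.9, 1.0, None, 1.6)),
    "fam_panc_1":        ((1.1, 0.9, 0.7, 1.2), (1.3, 1.6, 1.7, 2.1)),
    "fam_panc_2plus":    ((0.7, 2.0, 1.3, 2.6), (1.7, 1.1, 0.6, 0.4)),
    "fam_mbc":           ((1.0, 0.9, None, 0.4), (2.5, 5.4, None, 3.1)),
    "fam_prostate_1":    ((0.9, 0.4, 0.9, 0.8), (1.3, 1.2, 1.8, 1.3)),
    "fam_prostate_2plus": ((0.7, 0.5, 0.5, 0.4), (1.5, 0.9, 1.9, 2.1)),
}

_GENE_IDX = {"BRCA1": 0, "BRCA2": 1}
_RACE_IDX = {
    "european_mixed": 0,
    "african_american": 1,
    "asian": 2,
    "hispanic": 3,
}


def published_odds_ratios(gene: str, race_group: str) -> dict[str, float | None]:
    """Odds ratios for one gene x race-group stratum, keyed by indicator name.

    Inestimable cells are returned as ``None``.
    """
    gi = _GENE_IDX[gene]
    ri = _RACE_IDX[race_group]
    return {name: _OR_GRID[name][gi][ri] for name in _ROWS}
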