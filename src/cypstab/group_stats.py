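"""Nonparametric two-group comparison with family-wise Bonferroni control.

Every feature is compared between the stable and labile classes with a
two-sided Mann–Whitney U test (exact for small tie-free samples, otherwise
a normal approximation with midrank tie correction and optional continuity
correction).  Significance is judged against alpha divided by the declared
family size — the three families mirror the analysis tables: 6 genomic
features (threshold 0.0083 at alpha 0.05), 13 protein properties (0.0038)
and 20 residue frequencies (0.0025).  A Pearson chi-squared test covers
count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_PRODUCT_LIMIT = 400  # exact U distribution when n_x * n_y <= this, tie-free


@dataclass(frozen=True)
class TestResult:
    feature: str
    median_stable: float
    median_labile: float
    u_statistic: float
    p_value: float
    family_size: int
    alpha_corrected: float  # rounded to 4 dp for display
    significant: bool
    n_stable: int
    n_labile: int

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "median_stable": self.median_stable,
            "median_labile": self.median_labile,
            "U": self.u_statistic,
            "p": self.p_value,
            "alpha_corr": self.alpha_corrected,
            "significant": self.significant,
            "n_stable": self.n_stable,
            "n_labile": self.n_labile,
        }


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Display threshold alpha/m rounded to 4 decimal places.

    The unrounded alpha/m is what significance decisions use; e.g. a family
    of 6 at alpha 0.05 prints 0.0083.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return round(alpha / m, 4)


def mann_whitney_u(
    x, y, use_continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns (U of the first sample, two-sided p).  The exact null
    distribution is used for tie-free samples with n_x * n_y <= 400;
    otherwise the normal approximation with midrank tie correction (and a
    continuity correction unless disabled).  A combined sample with a
    single distinct value carries no ordering information: p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        warnings.warn("constant combined sample; p set to 1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and x.size * y.size <= EXACT_PRODUCT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method=method,
        use_continuity=use_continuity,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared(
    table, yates: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence on a counts table.

    Returns (chi2, p, df).  Yates continuity correction is off by default.
    Warns when any expected count is below 5; a zero row/column marginal is
    rejected.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=yates)
    if (expected < 5).any():
        warnings.warn("expected count below 5; chi-squared may be unreliable",
                      stacklevel=2)
    return float(chi2), float(p), int(df)


def compare_groups(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    family: list[str],
    alpha: float = 0.05,
    use_continuity: bool = True,
) -> pd.DataFrame:
    """One Mann–Whitney comparison per feature in a declared family.

    ``features`` is a numeric frame indexed by gene/protein id; ``labels``
    carries a ``label`` column with values ``stable``/``labile``.  The
    Bonferroni family size m is the number of features in ``family``;
    missing values are dropped per-feature.  Returns one row per feature,
    medians to 4 dp.
    """
    m = len(family)
    if m == 0:
        raise ValueError("empty feature family")
    alpha_raw = alpha / m
    alpha_disp = bonferroni_threshold(alpha, m)
    stable_ids = labels.index[labels["label"] == "stable"]
    labile_ids = labels.index[labels["label"] == "labile"]
    rows = []
    for feature in family:
        if feature not in features.columns:
            warnings.warn(f"feature {feature!r} absent; skipped", stacklevel=2)
            continue
        xs = features.loc[features.index.intersection(stable_ids), feature].dropna()
        ys = features.loc[features.index.intersection(labile_ids), feature].dropna()
        if xs.empty or ys.empty:
            warnings.warn(
                f"feature {feature!r}: a group is empty after NA removal; skipped",
                stacklevel=2,
            )
            continue
        u, p = mann_whitney_u(xs, ys, use_continuity=use_continuity)
        rows.append(
            TestResult(
                feature=feature,
                median_stable=round(float(xs.median()), 4),
                median_labile=round(float(ys.median()), 4),
                u_statistic=u,
                p_value=p,
                family_size=m,
                alpha_corrected=alpha_disp,
                significant=bool(p < alpha_raw),
                n_stable=len(xs),
                n_labile=len(ys),
            ).as_row()
        )
    return pd.DataFrame(rows)


GENOMIC_FAMILY = [
    "gene_length",
    "n_exons",
    "exon_length",
    "intron_length",
    "n_transcripts",
    "gc_percent",
]

PROTEIN_FAMILY = [
    "molecular_weight",
    "isoelectric_point",
    "charge",
    "hydrophobicity",
    "Aromatic",
    "Aliphatic",
    "Acidic",
    "Basic",
    "Charged",
    "Polar",
    "Non-polar",
    "Small",
    "Tiny",
]

RESIDUE_FAMILY = [f"f_{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"]
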