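"""Annotation-term proportions and hypergeometric over-representation.

Given a gene -> term annotation table and stable/labile labels, the module
counts annotated genes per term per class (optionally per species),
reports class percentages to 1 decimal place (round-half-up), and tests
over-representation of each term in each class with an upper-tail
hypergeometric test, Benjamini–Hochberg adjusted across terms.

The module is agnostic about where the annotation table comes from
(curated GO terms, predicted terms, anything keyed by gene id).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def percent_1dp(count: int, total: int) -> float:
    """100*count/total displayed to 1 dp with round-half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = Decimal(100 * count) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def proportion_table(
    annotations: pd.DataFrame,
    labels: pd.DataFrame,
    species: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-term, per-class counts and percentages.

    ``annotations`` has columns ``gene_id`` and ``term_id``; ``labels`` is
    indexed by gene id with a ``label`` column.  Annotated genes without a
    label are logged and dropped.  Percentages are of the class total
    (all labelled genes of that class), to 1 dp.  When ``species`` (a gene
    id -> species map) is given, per-species counts are added.
    """
    ann = annotations.drop_duplicates(subset=["gene_id", "term_id"])
    known = ann["gene_id"].isin(labels.index)
    if not known.all():
        unknown = sorted(ann.loc[~known, "gene_id"].unique())
        import warnings

        warnings.warn(
            f"{len(unknown)} annotated gene ids have no label (e.g. {unknown[:3]})",
            stacklevel=2,
        )
        ann = ann[known]
    class_totals = labels["label"].value_counts().to_dict()
    rows = []
    for term, term_genes in ann.groupby("term_id")["gene_id"]:
        genes = set(term_genes)
        for cls in ("stable", "labile"):
            total = class_totals.get(cls, 0)
            if total == 0:
                raise ValueError(f"class {cls!r} has no labelled genes")
            members = set(labels.index[labels["label"] == cls])
            hit = genes & members
            row = {
                "term_id": term,
                "class": cls,
                "count": len(hit),
                "class_total": total,
                "percent": percent_1dp(len(hit), total),
            }
            if species is not None:
                for sp, sp_genes in species.groupby(species):
                    row[f"count_{sp}"] = len(hit & set(sp_genes.index))
            rows.append(row)
    return pd.DataFrame(rows)


def hypergeometric_enrichment(
    term_sets: dict[str, set[str]],
    class_set: set[str],
    background: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of each term in one gene class.

    For a term annotating K of N background genes, and a class of n genes
    overlapping the term in k, p = P[X >= k], X ~ Hypergeom(N, K, n).
    Adjusted p-values are Benjamini–Hochberg across the supplied terms.
    """
    if not background:
        raise ValueError("empty background")
    if not class_set <= background:
        raise ValueError("class set must be a subset of the background")
    n_bg = len(background)
    n_cls = len(class_set)
    rows = []
    for term, genes in term_sets.items():
        if not genes <= background:
            raise ValueError(f"term {term!r} annotates genes outside the background")
        k_term = len(genes)
        k_hit = len(genes & class_set)
        p = float(stats.hypergeom.sf(k_hit - 1, n_bg, k_term, n_cls))
        rows.append(
            {
                "term_id": term,
                "overlap": k_hit,
                "term_size": k_term,
                "class_size": n_cls,
                "background_size": n_bg,
                "p": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame


def term_sets_from_annotations(annotations: pd.DataFrame) -> dict[str, set[str]]:
    return {
        term: set(genes)
        for term, genes in annotations.groupby("term_id")["gene_id"]
    }
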