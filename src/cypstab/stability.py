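"""Stable/labile classification from ortholog-group paralog counts.

A gene's paralog count k is the number of OTHER genes of the same species
inside its ortholog group (per-species scope, the default), or the number of
other genes in the whole group (``scope="group"``).  Genes with k <= 3 are
called "stable" (they descend from evolutionarily conserved clades); genes
with k >= 4 are "labile" (members of lineage-specific expansions, or
"blooms").
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STABLE = "stable"
LABILE = "labile"
UNASSIGNED = "unassigned"

PARALOG_THRESHOLD = 3  # k <= 3 -> stable, k >= 4 -> labile


class OrthologGroupTable:
    """Membership table with rows (group_id, species, gene_id).

    Each gene id must appear in exactly one group.
    """

    COLUMNS = ("group_id", "species", "gene_id")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
        dup = frame["gene_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"gene ids in multiple groups: {sorted(frame.loc[dup, 'gene_id'])[:5]}"
            )
        self.frame = frame.reset_index(drop=True)
        self._by_gene = self.frame.set_index("gene_id")

    @classmethod
    def from_tsv(cls, path) -> "OrthologGroupTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene.index

    def genes(self) -> list[str]:
        return list(self.frame["gene_id"])

    def count_paralogs(self, gene_id: str, scope: str = "species") -> int:
        """Paralog count k for a gene.

        ``scope="species"`` counts same-species genes in the gene's group
        minus one; ``scope="group"`` counts all group members minus one.
        """
        if gene_id not in self._by_gene.index:
            raise KeyError(f"gene {gene_id!r} not in ortholog table")
        row = self._by_gene.loc[gene_id]
        group = self.frame[self.frame["group_id"] == row["group_id"]]
        if scope == "species":
            group = group[group["species"] == row["species"]]
        elif scope != "group":
            raise ValueError(f"unknown scope {scope!r}")
        return len(group) - 1


@dataclass(frozen=True)
class StabilityLabel:
    gene_id: str
    paralog_count: int | None
    label: str  # stable | labile | unassigned


def classify(
    table: OrthologGroupTable,
    genes: list[str] | None = None,
    scope: str = "species",
) -> pd.DataFrame:
    """Label genes stable (k <= 3) or labile (k >= 4).

    ``genes`` defaults to every gene in the table; genes absent from the
    table are labelled "unassigned" with a missing paralog count.  Returns
    a DataFrame indexed by gene_id with columns ``k`` and ``label``.
    """
    if genes is None:
        genes = table.genes()
    # paralog counts for a whole group/species block at once
    counts = table.frame.groupby(
        ["group_id"] if scope == "group" else ["group_id", "species"]
    )["gene_id"].transform("size")
    k_map = dict(zip(table.frame["gene_id"], counts - 1))
    rows = []
    for gene in genes:
        if gene in k_map:
            k = int(k_map[gene])
            label = STABLE if k <= PARALOG_THRESHOLD else LABILE
        else:
            k = None
            label = UNASSIGNED
        rows.append({"gene_id": gene, "k": k, "label": label})
    frame = pd.DataFrame(rows).set_index("gene_id")
    return frame


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
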