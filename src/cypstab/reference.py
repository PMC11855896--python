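"""Published per-species counts of the mosquito/fly CYP dataset.

The comparative study drew on the CYP complements of Drosophila
melanogaster, Anopheles gambiae, Aedes aegypti and Culex quinquefasciatus,
split into stable and labile classes before and after redundancy culling.
The per-species counts ship as package data; totals are always recomputed
by summation, never stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_dataset_counts() -> pd.DataFrame:
    """Per-species gene counts of the reference CYP dataset, indexed by species."""
    with resources.files("cypstab.data").joinpath(
        "mosquito_cyp_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="species")


def dataset_totals() -> dict[str, int]:
    """Column sums over species: total genes and per-class dataset sizes."""
    counts = load_dataset_counts()
    return {col: int(counts[col].sum()) for col in counts.columns}
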