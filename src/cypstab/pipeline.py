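"""End-to-end orchestration: classify -> cull -> features -> stats -> motifs
-> enrichment, with a machine-readable run log.

The pipeline mirrors the comparative workflow: genes are labelled stable or
labile from ortholog-group paralog counts, each class is optionally purged
of >80%-identical sequences, genomic and protein feature tables are built,
every feature family is compared between classes with Bonferroni-corrected
Mann–Whitney tests (on the unculled and, when culling ran, the culled
sets), signature-motif windows are profiled per class, and annotation-term
proportions are summarised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .enrichment import (
    hypergeometric_enrichment,
    proportion_table,
    term_sets_from_annotations,
)
from .genome_features import features_from_gff3
from .group_stats import (
    GENOMIC_FAMILY,
    PROTEIN_FAMILY,
    RESIDUE_FAMILY,
    compare_groups,
)
from .motifs import anchor_motifs, build_pfm, conservation_summary, invariant_columns
from .protein_features import profile_fasta
from .redundancy import cull
from .stability import OrthologGroupTable, classify


@dataclass(frozen=True)
class PipelineConfig:
    proteins: str
    gff3: str
    orthologs: str
    annotations: str | None = None
    genome: str | None = None
    out_dir: str | None = None
    cull_threshold: float | None = 80.0  # None skips culling
    paralog_scope: str = "species"
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for path in (self.proteins, self.gff3, self.orthologs):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if self.cull_threshold is not None and not 0 < self.cull_threshold <= 100:
            raise ValueError("cull threshold must lie in (0, 100]")


@dataclass
class MotifReport:
    motif: str
    label: str
    dataset: str  # unculled | culled
    n_windows: int
    consensus: str
    n_invariant: int
    n_columns: int
    summary: pd.DataFrame = field(repr=False)


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    culled_ids: dict[str, list[str]]  # label -> retained ids (empty if skipped)
    genomic_features: pd.DataFrame
    protein_features: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]  # e.g. "genomic_unculled"
    motif_reports: list[MotifReport]
    enrichment: pd.DataFrame
    ora: pd.DataFrame
    run_log: dict


FAMILIES = {
    "genomic": GENOMIC_FAMILY,
    "protein": PROTEIN_FAMILY,
    "residue": RESIDUE_FAMILY,
}


def _compare_all(
    genomic: pd.DataFrame,
    protein: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float,
    suffix: str,
) -> dict[str, pd.DataFrame]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant null features warn by design
        return {
            f"genomic_{suffix}": compare_groups(genomic, labels, GENOMIC_FAMILY, alpha),
            f"protein_{suffix}": compare_groups(protein, labels, PROTEIN_FAMILY, alpha),
            f"residue_{suffix}": compare_groups(protein, labels, RESIDUE_FAMILY, alpha),
        }


def _motif_stage(
    sequences: dict[str, str], labels: pd.DataFrame, dataset: str
) -> list[MotifReport]:
    windows: dict[tuple[str, str], list[str]] = {}
    for seq_id, seq in sequences.items():
        if seq_id not in labels.index:
            continue
        label = labels.loc[seq_id, "label"]
        if label not in ("stable", "labile"):
            continue
        anchored = anchor_motifs(seq, seq_id)
        for name in ("PERF", "haem"):
            if name in anchored:
                windows.setdefault((name, label), []).append(anchored[name].window)
    reports = []
    for (name, label), wins in sorted(windows.items()):
        pfm = build_pfm(wins, motif=name)
        reports.append(
            MotifReport(
                motif=name,
                label=label,
                dataset=dataset,
                n_windows=pfm.n_windows,
                consensus=pfm.consensus(),
                n_invariant=len(invariant_columns(pfm)),
                n_columns=pfm.n_columns,
                summary=conservation_summary(pfm),
            )
        )
    return reports


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    table = OrthologGroupTable.from_tsv(config.orthologs)
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(config.proteins, "fasta")
    }
    labels = classify(table, list(sequences), scope=config.paralog_scope)
    label_counts = labels["label"].value_counts().to_dict()

    genomic = features_from_gff3(config.gff3, config.genome)
    protein = profile_fasta(config.proteins)

    comparisons = _compare_all(genomic, protein, labels, config.alpha, "unculled")
    motif_reports = _motif_stage(sequences, labels, "unculled")

    culled_ids: dict[str, list[str]] = {}
    if config.cull_threshold is not None:
        for label in ("stable", "labile"):
            members = {
                sid: sequences[sid]
                for sid in labels.index[labels["label"] == label]
                if sid in sequences
            }
            if members:
                culled_ids[label] = list(
                    cull(members, threshold=config.cull_threshold).retained
                )
        kept = [sid for ids in culled_ids.values() for sid in ids]
        labels_culled = labels.loc[labels.index.intersection(kept)]
        comparisons.update(
            _compare_all(
                genomic.loc[genomic.index.intersection(kept)],
                protein.loc[protein.index.intersection(kept)],
                labels_culled,
                config.alpha,
                "culled",
            )
        )
        motif_reports += _motif_stage(
            {sid: sequences[sid] for sid in kept}, labels_culled, "culled"
        )

    enrichment = pd.DataFrame()
    ora = pd.DataFrame()
    if config.annotations is not None:
        annotations = pd.read_csv(config.annotations, sep="\t", dtype=str)
        if len(annotations):
            enrichment = proportion_table(annotations, labels)
            background = set(labels.index)
            term_sets = {
                t: g & background
                for t, g in term_sets_from_annotations(annotations).items()
            }
            stable_set = set(labels.index[labels["label"] == "stable"])
            ora = hypergeometric_enrichment(term_sets, stable_set, background)

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "cull_threshold": config.cull_threshold,
        "paralog_scope": config.paralog_scope,
        "counts": {
            "input_proteins": len(sequences),
            "input_genes": len(genomic),
            "stable": int(label_counts.get("stable", 0)),
            "labile": int(label_counts.get("labile", 0)),
            "unassigned": int(label_counts.get("unassigned", 0)),
            "culled_stable": len(culled_ids.get("stable", [])),
            "culled_labile": len(culled_ids.get("labile", [])),
            "annotation_terms": int(enrichment["term_id"].nunique())
            if len(enrichment)
            else 0,
        },
    }
    result = PipelineResult(
        labels=labels,
        culled_ids=culled_ids,
        genomic_features=genomic,
        protein_features=protein,
        comparisons=comparisons,
        motif_reports=motif_reports,
        enrichment=enrichment,
        ora=ora,
        run_log=run_log,
    )
    if config.out_dir is not None:
        write_report(result, config.out_dir)
    return result


def _format_comparison(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in ("median_stable", "median_labile"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out["alpha_corr"] = out["alpha_corr"].map(lambda v: f"{v:.4f}")
    return out


def write_report(result: PipelineResult, out_dir) -> dict[str, str]:
    """Write the TSV/JSON report bundle with stable column order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=index, lineterminator="\n")
        paths[name] = str(path)

    _save("labels", result.labels, index=True)
    _save("genomic_features", result.genomic_features, index=True)
    _save("protein_features", result.protein_features, index=True)
    for name, frame in result.comparisons.items():
        _save(f"compare_{name}", _format_comparison(frame))
    if result.motif_reports:
        _save(
            "motif_conservation",
            pd.DataFrame(
                [
                    {
                        "motif": r.motif,
                        "label": r.label,
                        "dataset": r.dataset,
                        "n_windows": r.n_windows,
                        "n_columns": r.n_columns,
                        "n_invariant": r.n_invariant,
                        "consensus": r.consensus,
                    }
                    for r in result.motif_reports
                ]
            ),
        )
    if len(result.enrichment):
        formatted = result.enrichment.copy()
        formatted["percent"] = formatted["percent"].map(lambda v: f"{v:.1f}")
        _save("enrichment", formatted)
    else:
        _save("enrichment", pd.DataFrame(columns=["term_id", "class", "count",
                                                  "class_total", "percent"]))
    if len(result.ora):
        _save("ora", result.ora)
    culled_rows = [
        {"label": label, "gene_id": sid}
        for label, ids in result.culled_ids.items()
        for sid in ids
    ]
    _save("culled_retained", pd.DataFrame(culled_rows, columns=["label", "gene_id"]))
    log_path = out / "run_log.json"
    with open(log_path, "w", newline="\n") as fh:
        json.dump(result.run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_log"] = str(log_path)
    return paths
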