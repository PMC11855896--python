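"""Seeded synthetic CYP cohorts for end-to-end testing of the analysis.

The generator emits a file bundle — protein FASTA, gene-model GFF3, genomic
FASTA (one contig per gene), ortholog-group TSV, annotation TSV and a truth
TSV — for two gene classes, "stable" and "labile", with the statistical
contrasts the comparative analysis is designed to detect:

* gene structure: stable genes are longer, with more exons and longer
  introns; per-class medians of gene length, exon count, exon total and
  intron total act as distribution set-points;
* protein composition: per-class residue-frequency set-points (stable
  proteins richer in Cys, Arg, Leu, Trp; labile in Glu, Lys, Met), which
  propagate into the derived hydrophobicity and category contrasts;
* haem-motif variability: every labile protein carries the invariant
  haem-binding consensus PFSAGPRNCIGQRFA, while stable proteins carry
  pattern-sampled variants (fixed pattern positions kept, wildcard
  positions drawn from the composition);
* annotation proportions: per-term stable/labile annotation fractions.

Genomic background sequence is i.i.d. with the class GC target (the
analysed features do not depend on codon structure), and ortholog groups
are built so that paralog-count classification recovers the truth labels
exactly, covering both boundary counts (k = 3 stable, k = 4 labile).

Protein sequences are built by quota sampling: each protein draws a
per-protein target composition (class set-point perturbed residue-wise by a
small lognormal factor), converts it to exact residue counts by largest
remainder, and shuffles.  Within-class composition variance is therefore
set by ``composition_cv`` alone, not inflated by multinomial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motifs import BUILTIN_MOTIFS, HAEM_CONSENSUS_LABILE, MOTIF_ORDER, MotifDefinition
from .scales import STANDARD_RESIDUES

CLASSES = ("stable", "labile")

# residue-frequency set-points (percent, normalised to sum 100): the
# observed per-class median compositions of the mosquito CYP classes
_RAW_STABLE = {
    "A": 6.1100, "C": 1.5238, "D": 5.3465, "E": 6.1151, "F": 6.2000,
    "G": 5.3254, "H": 2.3301, "I": 6.0827, "K": 5.4000, "L": 11.0656,
    "M": 2.9851, "N": 3.9448, "P": 5.1081, "Q": 3.5849, "R": 6.6202,
    "S": 5.4104, "T": 5.2104, "V": 6.2745, "W": 1.1236, "Y": 3.6072,
}
_RAW_LABILE = {
    "A": 5.6711, "C": 1.1811, "D": 5.4409, "E": 6.4338, "F": 6.5476,
    "G": 5.6075, "H": 2.1696, "I": 6.1185, "K": 6.4639, "L": 10.0616,
    "M": 3.3730, "N": 4.0161, "P": 5.0710, "Q": 3.4765, "R": 6.0852,
    "S": 5.3435, "T": 5.4326, "V": 6.5056, "W": 0.9452, "Y": 3.5185,
}


def _normalise(comp: dict[str, float]) -> dict[str, float]:
    total = sum(comp.values())
    return {aa: 100.0 * v / total for aa, v in comp.items()}


STABLE_COMPOSITION = _normalise(_RAW_STABLE)
LABILE_COMPOSITION = _normalise(_RAW_LABILE)

# fixed motif instances planted in every protein (each satisfies its pattern)
FIXED_MOTIF_INSTANCES = {
    "helixC": "WKVR",
    "helixI": "GAETT",
    "helixK": "ETLR",
    "PERF": "PERFNPERE",
    "haem": HAEM_CONSENSUS_LABILE,
}

# relative placement of motif windows along the protein (N->C order)
MOTIF_OFFSET_FRACTIONS = {
    "helixC": 0.22,
    "helixI": 0.42,
    "helixK": 0.55,
    "PERF": 0.72,
    "haem": 0.85,
}

DEFAULT_SPECIES = ("Dmel", "Agam", "Aaeg", "Cqui")

# per-term (stable fraction, labile fraction) annotation set-points
DEFAULT_TERM_PROPORTIONS = {
    "GO:0048856": (0.551, 0.311),
    "GO:0008610": (0.575, 0.099),
    "GO:0006805": (0.098, 0.286),
    "GO:0046680": (0.122, 0.357),
}


class GenerationError(ValueError):
    """Raised for impossible sampling requests (e.g. motifs do not fit)."""


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class ClassGenomicParams:
    """Set-points for one class's gene structure (medians of the targets)."""

    exon_count_mean: float
    exon_length_mean: float  # bp per exon
    intron_length_mean: float  # bp per intron
    gc_target: float  # fraction


DEFAULT_GENOMIC = {
    # stable: 4 exons totalling ~1518 bp, introns totalling ~612 bp
    "stable": ClassGenomicParams(4.0, 379.5, 204.0, 0.4478),
    # labile: 3 exons totalling ~1524 bp, introns totalling ~311 bp
    "labile": ClassGenomicParams(3.0, 508.0, 155.5, 0.4720),
}


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_species: int = 4
    genes_per_class: tuple[int, int] = (50, 50)  # (stable, labile)
    stable_composition: dict[str, float] = field(
        default_factory=lambda: dict(STABLE_COMPOSITION)
    )
    labile_composition: dict[str, float] = field(
        default_factory=lambda: dict(LABILE_COMPOSITION)
    )
    length_mean: float = 510.0  # protein residues
    length_sd: float = 40.0
    composition_cv: float = 0.04  # residue-wise within-class variation
    exon_count_sd: float = 0.35  # counts concentrate at the class mode
    exon_length_cv: float = 0.2
    intron_length_cv: float = 0.3
    genomic: dict[str, ClassGenomicParams] = field(
        default_factory=lambda: dict(DEFAULT_GENOMIC)
    )
    haem_policy: dict[str, str] = field(
        default_factory=lambda: {
            "stable": "pattern_sampled",
            "labile": "fixed_consensus",
        }
    )
    term_proportions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TERM_PROPORTIONS)
    )
    null_features: tuple[str, ...] = ("exon_length", "n_transcripts")
    multi_tx_fraction: float = 0.1
    min_protein_length: int = 150
    min_part_length: int = 30  # bp floor for exons and introns

    def validate(self) -> None:
        for name, comp in (
            ("stable_composition", self.stable_composition),
            ("labile_composition", self.labile_composition),
        ):
            total = sum(comp.values())
            if abs(total - 100.0) > 1e-6:
                raise ConfigurationError(
                    f"{name} sums to {total!r}, expected 100"
                )
            bad = set(comp) - set(STANDARD_RESIDUES)
            if bad:
                raise ConfigurationError(f"{name} has non-standard residues {bad}")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if any(n < 1 for n in self.genes_per_class):
            raise ConfigurationError("genes_per_class entries must be >= 1")
        if self.genes_per_class[1] < 5:
            raise ConfigurationError(
                "need at least 5 labile genes: a labile gene requires 4 or "
                "more same-species paralogs in its ortholog group"
            )
        for cls, policy in self.haem_policy.items():
            if policy not in ("fixed_consensus", "pattern_sampled"):
                raise ConfigurationError(f"unknown haem policy {policy!r} for {cls}")
        for term, (fs, fl) in self.term_proportions.items():
            if not (0 <= fs <= 1 and 0 <= fl <= 1):
                raise ConfigurationError(f"term {term}: fractions must be in [0,1]")


def _quota_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total``, proportional to ``weights``
    (largest-remainder rounding)."""
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _sample_motif_window(
    motif: MotifDefinition,
    policy: str,
    composition: dict[str, float],
    rng: np.random.Generator,
) -> str:
    if policy == "fixed_consensus":
        return FIXED_MOTIF_INSTANCES[motif.name]
    residues = np.array(list(composition))
    probs = np.array([composition[a] for a in residues]) / 100.0
    out = []
    for i in range(motif.window):
        allowed = motif.positions[i] if i < motif.span else None
        if allowed is None or len(allowed) == 20:
            out.append(rng.choice(residues, p=probs))
        elif len(allowed) == 1:
            out.append(next(iter(allowed)))
        else:
            out.append(rng.choice(sorted(allowed)))
    return "".join(out)


def sample_protein(
    composition: dict[str, float],
    length: int,
    motif_windows: list[tuple[MotifDefinition, str]],
    rng: np.random.Generator,
    composition_cv: float = 0.0,
) -> str:
    """One protein sequence with planted motif windows.

    Background residues are quota-sampled from ``composition`` (optionally
    perturbed residue-wise with lognormal CV ``composition_cv``); motif
    windows are written at fixed relative offsets in N->C order, shifted
    right as needed so they never overlap.
    """
    total = sum(m.window for m, _ in motif_windows)
    if length < total + len(motif_windows):
        raise GenerationError(
            f"length {length} too short for {total} residues of motif windows"
        )
    # place windows first (fixed relative offsets, pushed right on overlap)
    placements: list[tuple[int, str]] = []
    prev_end = 0  # 0-based exclusive end of previous window
    for motif, policy in motif_windows:
        frac = MOTIF_OFFSET_FRACTIONS.get(motif.name, 0.5)
        start = max(int(frac * length), prev_end + 1)
        if start + motif.window > length:
            raise GenerationError(
                f"cannot place motif {motif.name} in length {length}"
            )
        placements.append(
            (start, _sample_motif_window(motif, policy, composition, rng))
        )
        prev_end = start + motif.window
    # quota the per-protein target over the FULL length, then charge the
    # window residues against it: the emitted sequence (windows included)
    # then matches the target composition, so the planted class contrast is
    # neither diluted nor biased by the motif content or the haem policy
    residues = np.array(list(composition))
    weights = np.array([composition[a] for a in residues], dtype=float)
    if composition_cv > 0:
        weights = weights * np.exp(
            rng.normal(0.0, composition_cv, size=weights.size)
        )
    counts = _quota_counts(weights, length)
    window_residues = "".join(w for _, w in placements)
    for i, aa in enumerate(residues):
        counts[i] -= window_residues.count(aa)
    if (counts < 0).any():  # window demands more of a residue than the target
        counts = np.maximum(counts, 0)
        counts = _quota_counts(counts.astype(float) + 1e-9, length - total)
    background = np.repeat(residues, counts)
    rng.shuffle(background)
    seq: list[str] = []
    bg = iter(background)
    pos = 0
    for start, window in placements:
        while pos < start:
            seq.append(next(bg))
            pos += 1
        seq.extend(window)
        pos += len(window)
    seq.extend(bg)
    return "".join(seq)


def sample_gene_model(
    exon_count: int,
    exon_lengths: list[int],
    intron_lengths: list[int],
    gc: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], str]:
    """Exon spans (1-based inclusive) and the gene-span nucleotide sequence.

    The gene length is the sum of all exon and intron lengths, so the
    features derived downstream (gene length, exon total, intron total by
    subtraction) round-trip exactly.
    """
    if exon_count < 1:
        raise GenerationError("exon_count must be >= 1")
    if len(exon_lengths) != exon_count or len(intron_lengths) != exon_count - 1:
        raise GenerationError("part list lengths inconsistent with exon_count")
    if any(v <= 0 for v in exon_lengths) or any(v <= 0 for v in intron_lengths):
        raise GenerationError("exon and intron lengths must be positive")
    spans = []
    pos = 1
    for i, exon_len in enumerate(exon_lengths):
        spans.append((pos, pos + exon_len - 1))
        pos += exon_len
        if i < exon_count - 1:
            pos += intron_lengths[i]
    gene_length = pos - 1
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequence = "".join(rng.choice(bases, size=gene_length, p=probs))
    return spans, sequence


@dataclass
class SyntheticGene:
    gene_id: str
    species: str
    label: str
    protein: str
    exon_spans: list[tuple[int, int]]
    transcripts: list[list[tuple[int, int]]]
    genome_sequence: str

    @property
    def gene_length(self) -> int:
        return len(self.genome_sequence)


@dataclass
class Cohort:
    config: CohortConfig
    genes: list[SyntheticGene]
    ortholog_frame: pd.DataFrame
    annotation_frame: pd.DataFrame

    @property
    def truth_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {"gene_id": g.gene_id, "class": g.label, "species": g.species}
                for g in self.genes
            ]
        )
        return frame.set_index("gene_id")

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def write(self, out_dir) -> dict[str, str]:
        """Write the bundle; returns a name -> path map.  Deterministic."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": out / "proteins.fasta",
            "gff3": out / "genes.gff3",
            "genome": out / "genome.fasta",
            "orthologs": out / "orthologs.tsv",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.tsv",
        }
        with open(paths["proteins"], "w", newline="\n") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n")
                for i in range(0, len(g.protein), 60):
                    fh.write(g.protein[i : i + 60] + "\n")
        with open(paths["genome"], "w", newline="\n") as fh:
            for g in self.genes:
                fh.write(f">ctg_{g.gene_id}\n")
                for i in range(0, len(g.genome_sequence), 60):
                    fh.write(g.genome_sequence[i : i + 60] + "\n")
        with open(paths["gff3"], "w", newline="\n") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"##sequence-region ctg_{g.gene_id} 1 {g.gene_length}\n"
                )
            for g in self.genes:
                seqid = f"ctg_{g.gene_id}"
                fh.write(
                    f"{seqid}\tcypstab\tgene\t1\t{g.gene_length}\t.\t+\t.\t"
                    f"ID={g.gene_id}\n"
                )
                for t, exons in enumerate(g.transcripts, start=1):
                    tx_id = f"{g.gene_id}.t{t}"
                    tx_end = max(e for _, e in exons)
                    tx_start = min(s for s, _ in exons)
                    fh.write(
                        f"{seqid}\tcypstab\tmRNA\t{tx_start}\t{tx_end}\t.\t+\t.\t"
                        f"ID={tx_id};Parent={g.gene_id}\n"
                    )
                    for e, (s, end) in enumerate(exons, start=1):
                        fh.write(
                            f"{seqid}\tcypstab\texon\t{s}\t{end}\t.\t+\t.\t"
                            f"ID={tx_id}.e{e};Parent={tx_id}\n"
                        )
        self.ortholog_frame.to_csv(
            paths["orthologs"], sep="\t", index=False, lineterminator="\n"
        )
        self.annotation_frame.to_csv(
            paths["annotations"], sep="\t", index=False, lineterminator="\n"
        )
        self.truth_frame.to_csv(paths["truth"], sep="\t", lineterminator="\n")
        return {k: str(v) for k, v in paths.items()}


def _labile_chunks(n: int) -> list[int]:
    """Partition n labile genes into expansion-family sizes of 5-8.

    Sizes cycle 5, 6, 7, 8 (k = 4..7, covering the k = 4 boundary); a
    remainder smaller than 5 is merged into the last chunk so every family
    keeps at least five same-species members.
    """
    sizes: list[int] = []
    cycle = (5, 6, 7, 8)
    remaining = n
    while remaining > 0:
        size = cycle[len(sizes) % len(cycle)]
        if remaining < size:
            if remaining < 5 and sizes:
                sizes[-1] += remaining
            else:
                sizes.append(remaining)
            break
        sizes.append(size)
        remaining -= size
    return sizes


def _build_ortholog_frame(genes: list[SyntheticGene]) -> pd.DataFrame:
    """Ortholog groups whose per-species paralog counts reproduce the labels.

    Stable genes of each species are chunked into blocks of 1-4 members
    (k = 0..3, covering the k = 3 boundary); chunks with the same index are
    merged across species into one cross-species group.  Labile genes are
    already assigned to species in whole expansion families of >= 5 (see
    :func:`_labile_chunks`); consecutive same-species runs become one
    species-specific group each.
    """
    rows = []
    stable_sizes = (1, 2, 3, 4)
    by_species: dict[str, list[SyntheticGene]] = {}
    for g in genes:
        if g.label == "stable":
            by_species.setdefault(g.species, []).append(g)
    for species in sorted(by_species):
        members = by_species[species]
        i = chunk = 0
        while i < len(members):
            size = stable_sizes[chunk % len(stable_sizes)]
            for g in members[i : i + size]:
                rows.append(
                    {
                        "group_id": f"OG_S{chunk:04d}",
                        "species": species,
                        "gene_id": g.gene_id,
                    }
                )
            i += size
            chunk += 1
    labile = [g for g in genes if g.label == "labile"]
    sizes = _labile_chunks(len(labile))
    i = 0
    for chunk, size in enumerate(sizes):
        for g in labile[i : i + size]:
            rows.append(
                {
                    "group_id": f"OG_L{chunk:04d}",
                    "species": g.species,
                    "gene_id": g.gene_id,
                }
            )
        i += size
    return pd.DataFrame(rows, columns=["group_id", "species", "gene_id"])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort.  Same config => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species_list = list(DEFAULT_SPECIES[: config.n_species])
    while len(species_list) < config.n_species:
        species_list.append(f"sp{len(species_list) + 1}")
    # stable genes rotate species; labile genes take species in whole
    # expansion families so every family has >= 5 same-species members
    n_stable, n_labile = config.genes_per_class
    stable_species = [
        species_list[i % len(species_list)] for i in range(n_stable)
    ]
    labile_species: list[str] = []
    for chunk, size in enumerate(_labile_chunks(n_labile)):
        labile_species.extend([species_list[chunk % len(species_list)]] * size)
    species_plan = {"stable": stable_species, "labile": labile_species}

    genes: list[SyntheticGene] = []
    serial = 0
    for label, n_genes, composition in (
        ("stable", n_stable, config.stable_composition),
        ("labile", n_labile, config.labile_composition),
    ):
        params = config.genomic[label]
        motif_windows = [
            (
                BUILTIN_MOTIFS[name],
                config.haem_policy[label] if name == "haem" else "fixed_consensus",
            )
            for name in MOTIF_ORDER
        ]
        for i in range(n_genes):
            species = species_plan[label][i]
            gene_id = f"{species}_g{serial:04d}"
            serial += 1
            length = max(
                config.min_protein_length,
                int(round(rng.normal(config.length_mean, config.length_sd))),
            )
            protein = sample_protein(
                composition, length, motif_windows, rng, config.composition_cv
            )
            n_exons = max(
                1,
                int(round(rng.normal(params.exon_count_mean, config.exon_count_sd))),
            )
            exon_lengths = [
                max(
                    config.min_part_length,
                    int(
                        round(
                            rng.normal(
                                params.exon_length_mean,
                                config.exon_length_cv * params.exon_length_mean,
                            )
                        )
                    ),
                )
                for _ in range(n_exons)
            ]
            intron_lengths = [
                max(
                    config.min_part_length,
                    int(
                        round(
                            rng.normal(
                                params.intron_length_mean,
                                config.intron_length_cv * params.intron_length_mean,
                            )
                        )
                    ),
                )
                for _ in range(n_exons - 1)
            ]
            spans, genome_seq = sample_gene_model(
                n_exons, exon_lengths, intron_lengths, params.gc_target, rng
            )
            transcripts = [spans]
            if n_exons >= 2 and rng.random() < config.multi_tx_fraction:
                transcripts.append(spans[:-1])  # shorter secondary isoform
            genes.append(
                SyntheticGene(
                    gene_id=gene_id,
                    species=species,
                    label=label,
                    protein=protein,
                    exon_spans=spans,
                    transcripts=transcripts,
                    genome_sequence=genome_seq,
                )
            )
    ortholog_frame = _build_ortholog_frame(genes)
    ann_rows = []
    stable_ids = [g.gene_id for g in genes if g.label == "stable"]
    labile_ids = [g.gene_id for g in genes if g.label == "labile"]
    for term in sorted(config.term_proportions):
        f_stable, f_labile = config.term_proportions[term]
        for ids, frac in ((stable_ids, f_stable), (labile_ids, f_labile)):
            k = int(round(frac * len(ids)))
            if k:
                chosen = rng.choice(np.array(ids), size=k, replace=False)
                for gid in sorted(chosen):
                    ann_rows.append({"gene_id": gid, "term_id": term})
    annotation_frame = pd.DataFrame(ann_rows, columns=["gene_id", "term_id"])
    return Cohort(
        config=config,
        genes=genes,
        ortholog_frame=ortholog_frame,
        annotation_frame=annotation_frame,
    )


def null_config(config: CohortConfig | None = None, seed: int = 0) -> CohortConfig:
    """A cohort config with no planted class differences (both classes use
    the stable set-points); used for type-I error studies."""
    base = config or CohortConfig()
    return replace(
        base,
        seed=seed,
        labile_composition=dict(base.stable_composition),
        genomic={
            "stable": base.genomic["stable"],
            "labile": base.genomic["stable"],
        },
        haem_policy={"stable": "fixed_consensus", "labile": "fixed_consensus"},
        term_proportions={
            t: (fs, fs) for t, (fs, _) in base.term_proportions.items()
        },
    )
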