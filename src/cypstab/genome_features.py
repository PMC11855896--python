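"""Gene-structure features from GFF3 gene models.

Derives, per gene: gene length, exon count, total exon length, total intron
length, transcript count, and GC content.  Exon count and exon length come
from a single representative transcript — the one with the greatest total
exon length (ties broken by lexicographically smallest transcript id) — and
intron length is derived by subtraction:

    L_intron = L_gene − L_exon

floored at zero with a warning if a representative transcript does not span
the whole gene.  Coordinates are 1-based inclusive per the GFF3 standard;
all lengths are end − start + 1.  Strand is ignored (every feature here is
strand-symmetric).  GC content is computed over the full gene span, introns
included, with ambiguity codes excluded from numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd


class GffFormatError(ValueError):
    """Raised for structurally invalid gene models (e.g. orphan exons)."""


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # (start, end), 1-based inclusive

    def __post_init__(self):
        if not self.exons:
            raise GffFormatError(f"transcript {self.transcript_id} has no exons")
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))

    @property
    def total_exon_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str = "+"
    transcripts: tuple[TranscriptModel, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.transcripts:
            raise GffFormatError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            for s, e in tx.exons:
                if s < self.start or e > self.end:
                    raise GffFormatError(
                        f"exon {s}-{e} of {tx.transcript_id} outside gene span "
                        f"{self.start}-{self.end} of {self.gene_id}"
                    )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicFeatureVector:
    gene_id: str
    gene_length: int
    n_exons: int
    exon_length: int
    intron_length: int
    n_transcripts: int
    gc_percent: float | None

    def as_row(self) -> dict:
        return {
            "gene_length": self.gene_length,
            "n_exons": self.n_exons,
            "exon_length": self.exon_length,
            "intron_length": self.intron_length,
            "n_transcripts": self.n_transcripts,
            "gc_percent": self.gc_percent,
        }


def parse_gene_models(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModel objects.

    Uses an in-memory gffutils database, so unsorted files are handled.
    mRNA features must carry a Parent gene; exons must carry a Parent
    transcript, otherwise a format error names the offending feature.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneModel] = []
    known_tx_parents = {g.id for g in db.features_of_type("gene")}
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise GffFormatError(
                f"orphan exon at {exon.seqid}:{exon.start}-{exon.end} (no Parent)"
            )
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            parents = mrna.attributes.get("Parent", [])
            if gene.id not in parents:
                continue
            exons = tuple(
                (e.start, e.end)
                for e in db.children(mrna, featuretype="exon", order_by="start")
            )
            if not exons:
                raise GffFormatError(f"transcript {mrna.id} has no exons")
            transcripts.append(TranscriptModel(mrna.id, exons))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seqid=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand or "+",
                transcripts=tuple(transcripts),
            )
        )
    # orphan transcript check: every mRNA must name a known gene
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or not any(p in known_tx_parents for p in parents):
            raise GffFormatError(f"transcript {mrna.id} has no parent gene")
    return genes


def select_representative(gene: GeneModel) -> TranscriptModel:
    """The transcript with maximal total exon length.

    Ties break to the lexicographically smallest transcript id, so the
    choice is deterministic.
    """
    return min(
        gene.transcripts, key=lambda tx: (-tx.total_exon_length, tx.transcript_id)
    )


def gc_content(sequence: str) -> float | None:
    """GC percent over unambiguous bases; None if no A/C/G/T present."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def compute_genomic_features(
    gene: GeneModel, genomic_sequence: str | None = None
) -> GenomicFeatureVector:
    """Feature vector for one gene.

    ``genomic_sequence`` is the nucleotide sequence of the gene span itself
    (length equal to the gene length); when absent, GC is reported missing.
    """
    rep = select_representative(gene)
    exon_length = rep.total_exon_length
    intron_length = gene.length - exon_length
    if intron_length < 0:
        warnings.warn(
            f"gene {gene.gene_id}: exon total {exon_length} exceeds gene length "
            f"{gene.length}; intron length floored at 0",
            stacklevel=2,
        )
        intron_length = 0
    gc = gc_content(genomic_sequence) if genomic_sequence is not None else None
    return GenomicFeatureVector(
        gene_id=gene.gene_id,
        gene_length=gene.length,
        n_exons=rep.n_exons,
        exon_length=exon_length,
        intron_length=intron_length,
        n_transcripts=len(gene.transcripts),
        gc_percent=gc,
    )


def features_from_gff3(
    gff3_path, genome_fasta: str | None = None
) -> pd.DataFrame:
    """Feature table for every gene in a GFF3 file.

    ``genome_fasta`` optionally supplies contig sequences so GC can be
    computed over each gene span.
    """
    contigs: dict[str, str] = {}
    if genome_fasta is not None:
        from Bio import SeqIO

        contigs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")
        }
    rows = {}
    for gene in parse_gene_models(gff3_path):
        span = None
        if gene.seqid in contigs:
            span = contigs[gene.seqid][gene.start - 1 : gene.end]
        rows[gene.gene_id] = compute_genomic_features(gene, span).as_row()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gene_id"
    return frame
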