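"""Gene models (exon/intron structure) and FASTA/GFF3 round-tripping.

Coordinates are 0-based half-open on the forward strand internally; GFF3
I/O converts to/from the format's 1-based inclusive convention.  Genes on
the minus strand keep forward-strand exon intervals; traversal in CDS
order reverses the exon list.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ValidationError(ValueError):
    """An input violated a structural invariant."""


@dataclass
class GeneModel:
    """Exon/intron structure of a single gene.

    Parameters
    ----------
    gene_id:
        Gene identifier (e.g. ``"BflGb6"``).
    seq_id:
        Identifier of the genomic sequence the coordinates refer to.
    strand:
        ``"+"`` or ``"-"``.
    exons:
        Ordered, non-overlapping ``(start, end)`` intervals, 0-based
        half-open, on the forward strand.
    cds_start_offset:
        Bases of the first exon (in CDS order) upstream of the start codon.
    cds_end_offset:
        Bases of the last exon (in CDS order) downstream of the stop codon.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start_offset: int = 0
    cds_end_offset: int = 0

    def __post_init__(self) -> None:
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene model has no exons")
        prev_end = None
        for i, (a, b) in enumerate(self.exons):
            if b <= a:
                raise ValidationError(f"{self.gene_id}: exon {i} has non-positive length")
            if prev_end is not None:
                if a < prev_end:
                    raise ValidationError(f"{self.gene_id}: exons {i - 1} and {i} overlap or are unsorted")
                if a == prev_end:
                    raise ValidationError(f"{self.gene_id}: intron {i - 1} has zero length")
            prev_end = b
        if self.cds_start_offset < 0 or self.cds_end_offset < 0:
            raise ValidationError(f"{self.gene_id}: negative CDS offset")

    # -- derived geometry ---------------------------------------------------

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (forward-strand order)."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def exons_cds_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def cds_length(self) -> int:
        total = sum(b - a for a, b in self.exons)
        return total - self.cds_start_offset - self.cds_end_offset

    def intron_cds_offset(self, intron_index: int) -> int:
        """Number of CDS bases 5' of intron ``intron_index`` (CDS order)."""
        exons = self.exons_cds_order()
        n_introns = len(exons) - 1
        if not 0 <= intron_index < n_introns:
            raise IndexError(f"intron index {intron_index} out of range (gene has {n_introns} introns)")
        upstream = sum(b - a for a, b in exons[: intron_index + 1])
        offset = upstream - self.cds_start_offset
        if offset <= 0 or offset >= self.cds_length:
            raise ValidationError(f"{self.gene_id}: intron {intron_index} lies outside the CDS (UTR intron, unmappable)")
        return offset

    def spliced_sequence(self, genomic: str) -> str:
        """mRNA-sense spliced sequence (reverse-complemented on '-')."""
        s = "".join(genomic[a:b] for a, b in self.exons)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# -- GFF3 -------------------------------------------------------------------


def write_gene_models_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for m in models:
        g0, g1 = m.span
        attrs = f"ID={m.gene_id}"
        lines.append("\t".join([m.seq_id, "globkit", "gene", str(g0 + 1), str(g1), ".", m.strand, ".", attrs]))
        mrna_id = f"{m.gene_id}.t1"
        lines.append(
            "\t".join([m.seq_id, "globkit", "mRNA", str(g0 + 1), str(g1), ".", m.strand, ".", f"ID={mrna_id};Parent={m.gene_id}"])
        )
        exons_cds = m.exons_cds_order()
        for k, (a, b) in enumerate(m.exons):
            lines.append(
                "\t".join(
                    [m.seq_id, "globkit", "exon", str(a + 1), str(b), ".", m.strand, ".", f"ID={mrna_id}.exon{k + 1};Parent={mrna_id}"]
                )
            )
        # CDS rows: trim the start/end offsets off the terminal exons in CDS order
        cds = list(exons_cds)
        a0, b0 = cds[0]
        if m.strand == "+":
            cds[0] = (a0 + m.cds_start_offset, b0)
        else:
            cds[0] = (a0, b0 - m.cds_start_offset)
        a1, b1 = cds[-1]
        if m.strand == "+":
            cds[-1] = (a1, b1 - m.cds_end_offset)
        else:
            cds[-1] = (a1 + m.cds_end_offset, b1)
        phase = 0
        for a, b in cds:
            lines.append(
                "\t".join([m.seq_id, "globkit", "CDS", str(a + 1), str(b), ".", m.strand, str(phase), f"ID={mrna_id}.cds;Parent={mrna_id}"])
            )
            phase = (3 - ((b - a) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models back from GFF3 (gene + exon features, via gffutils)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        cds_ivs = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            cds_ivs = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
            break
        if not exons:
            exons = sorted((f.start - 1, f.end) for f in db.children(gene, featuretype="exon"))
        start_off = end_off = 0
        if cds_ivs and exons:
            if gene.strand == "+":
                start_off = cds_ivs[0][0] - exons[0][0]
                end_off = exons[-1][1] - cds_ivs[-1][1]
            else:
                start_off = exons[-1][1] - cds_ivs[-1][1]
                end_off = cds_ivs[0][0] - exons[0][0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_start_offset=max(start_off, 0),
                cds_end_offset=max(end_off, 0),
            )
        )
    return models
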