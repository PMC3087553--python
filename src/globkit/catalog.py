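"""Globin gene catalog: loading, validation, round-trip writing, summaries.

The catalog dialect is a tab-separated table, one row per gene, with EST
accessions semicolon-joined in a single column and a mandatory header row.
Leading ``#`` comment lines are preserved so that ``write_catalog``
round-trips the packaged fixture byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .genemodels import GeneModel, ValidationError

_COLUMNS = [
    "gene_id",
    "scaffold_id",
    "alt_haplotype_id",
    "haplotype_identity_pct",
    "haplotype_similarity_pct",
    "est_accessions",
    "cds_accession",
    "cds_coverage",
]


@dataclass
class GeneRecord:
    gene_id: str
    scaffold_id: str
    alt_haplotype_id: str | None = None
    haplotype_identity_pct: float | None = None
    haplotype_similarity_pct: float | None = None
    est_accessions: list[str] = field(default_factory=list)
    cds_accession: str = ""
    cds_coverage: str = "complete"
    gene_model_ref: GeneModel | None = None

    def validate(self) -> None:
        if self.cds_coverage not in ("complete", "partial"):
            raise ValidationError(f"{self.gene_id}: cds_coverage must be 'complete' or 'partial'")
        if len(set(self.est_accessions)) != len(self.est_accessions):
            raise ValidationError(f"{self.gene_id}: duplicate EST accessions")
        ident, sim = self.haplotype_identity_pct, self.haplotype_similarity_pct
        for name, v in (("identity", ident), ("similarity", sim)):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{self.gene_id}: haplotype {name} {v} outside [0, 100]")
        if ident is not None and sim is not None and sim < ident:
            raise ValidationError(f"{self.gene_id}: haplotype similarity {sim} < identity {ident}")


@dataclass
class GlobinCatalog:
    records: list[GeneRecord]
    comments: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            rec.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)


@dataclass
class CatalogSummary:
    n_genes: int
    est_counts: dict[str, int]
    n_with_alt_haplotype: int
    coverage: dict[str, str]


def packaged_fixture_path(name: str = "table1.tsv") -> Path:
    """Path to a data file shipped inside the package."""
    return Path(str(resources.files("globkit").joinpath("data", name)))


def load_catalog(path: str | Path) -> GlobinCatalog:
    """Load and validate a catalog TSV.

    Raises
    ------
    ValidationError
        On a malformed row (with its line number), a duplicate gene id,
        or an empty file.
    """
    text = Path(path).read_text()
    comments: list[str] = []
    rows: list[tuple[int, str]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if header is None:
                comments.append(line)
            continue
        if not line.strip():
            continue
        if header is None:
            header = line.split("\t")
            if header != _COLUMNS:
                raise ValidationError(f"line {lineno}: unexpected header columns {header}")
            continue
        rows.append((lineno, line))
    if header is None or not rows:
        raise ValidationError("no records in catalog file")
    records = []
    for lineno, line in rows:
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValidationError(f"line {lineno}: expected {len(_COLUMNS)} columns, found {len(parts)}")
        d = dict(zip(_COLUMNS, parts))
        try:
            records.append(
                GeneRecord(
                    gene_id=d["gene_id"],
                    scaffold_id=d["scaffold_id"],
                    alt_haplotype_id=d["alt_haplotype_id"] or None,
                    haplotype_identity_pct=float(d["haplotype_identity_pct"]) if d["haplotype_identity_pct"] else None,
                    haplotype_similarity_pct=float(d["haplotype_similarity_pct"]) if d["haplotype_similarity_pct"] else None,
                    est_accessions=[a for a in d["est_accessions"].split(";") if a],
                    cds_accession=d["cds_accession"],
                    cds_coverage=d["cds_coverage"],
                )
            )
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
    catalog = GlobinCatalog(records=records, comments=comments)
    catalog.validate()
    return catalog


def _fmt_pct(v: float | None) -> str:
    return "" if v is None else f"{v:.1f}"


def write_catalog(catalog: GlobinCatalog, path: str | Path) -> None:
    lines = list(catalog.comments)
    lines.append("\t".join(_COLUMNS))
    for r in catalog.records:
        lines.append(
            "\t".join(
                [
                    r.gene_id,
                    r.scaffold_id,
                    r.alt_haplotype_id or "",
                    _fmt_pct(r.haplotype_identity_pct),
                    _fmt_pct(r.haplotype_similarity_pct),
                    ";".join(r.est_accessions),
                    r.cds_accession,
                    r.cds_coverage,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def catalog_stats(catalog: GlobinCatalog) -> CatalogSummary:
    """Exact tallies over catalog records (empty catalog -> zero counts)."""
    return CatalogSummary(
        n_genes=len(catalog.records),
        est_counts={r.gene_id: len(r.est_accessions) for r in catalog.records},
        n_with_alt_haplotype=sum(1 for r in catalog.records if r.alt_haplotype_id),
        coverage={r.gene_id: r.cds_coverage for r in catalog.records},
    )


def load_packaged_catalog() -> GlobinCatalog:
    return load_catalog(packaged_fixture_path("table1.tsv"))
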