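"""Micro-synteny: shared flanking-gene evidence between two genomic regions.

Orthology of a focal gene (e.g. an amphioxus neuroglobin candidate vs the
vertebrate NGB locus) is corroborated when ortholog families flanking it
in one genome also flank it in the other.  Family assignments are inputs
(pre-computed orthology); distance is measured in genes, not bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .genemodels import ValidationError


@dataclass
class SyntenyMap:
    region: str
    genes: list[tuple[str, str, str]]  # (gene_label, family_id, strand) in physical order

    def __post_init__(self) -> None:
        labels = [g for g, _, _ in self.genes]
        if len(labels) != len(set(labels)):
            raise ValidationError(f"{self.region}: duplicate gene labels")

    def families(self) -> list[str]:
        return [f for _, f, _ in self.genes]

    def index_of_family(self, family: str) -> int:
        hits = [i for i, (_, f, _) in enumerate(self.genes) if f == family]
        if len(hits) != 1:
            raise ValidationError(f"{self.region}: family {family!r} present {len(hits)} times (need exactly 1)")
        return hits[0]


def load_synteny_map(path: str | Path) -> SyntenyMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("position_index")
    region = str(df["region"].iloc[0])
    genes = [(str(r.gene_label), str(r.family_id), str(r.strand)) for r in df.itertuples()]
    return SyntenyMap(region, genes)


def packaged_synteny_map(name: str) -> SyntenyMap:
    path = Path(str(resources.files("globkit").joinpath("data", name)))
    return load_synteny_map(path)


@dataclass
class SyntenyReport:
    focal_family: str
    shared_families: set[str]
    offsets_a: dict[str, int]
    offsets_b: dict[str, int]
    order_conserved: bool


def shared_neighbors(map_a: SyntenyMap, map_b: SyntenyMap, focal_family: str, window: int = 10) -> SyntenyReport:
    """Ortholog families found within +-window genes of the focal gene in both maps.

    The order-conservation flag is true when the shared families appear in
    the same relative order on both maps, allowing a global strand flip
    (one map reversed).
    """
    ia = map_a.index_of_family(focal_family)
    ib = map_b.index_of_family(focal_family)

    def neighborhood(m: SyntenyMap, i: int) -> dict[str, int]:
        out = {}
        for j in range(max(0, i - window), min(len(m.genes), i + window + 1)):
            fam = m.genes[j][1]
            if fam != focal_family and fam not in out:
                out[fam] = j - i
        return out

    na, nb = neighborhood(map_a, ia), neighborhood(map_b, ib)
    shared = set(na) & set(nb)
    order = True
    if len(shared) >= 2:
        fams = sorted(shared, key=lambda f: na[f])
        off_b = [nb[f] for f in fams]
        increasing = all(x < y for x, y in zip(off_b, off_b[1:]))
        decreasing = all(x > y for x, y in zip(off_b, off_b[1:]))
        order = increasing or decreasing
    return SyntenyReport(
        focal_family=focal_family,
        shared_families=shared,
        offsets_a={f: na[f] for f in shared},
        offsets_b={f: nb[f] for f in shared},
        order_conserved=order,
    )
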