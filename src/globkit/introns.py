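"""Intron positions in globin-fold helix notation, and gain/loss parsimony.

An intron position is written ``<segment><residue>.<phase>`` (e.g.
``B12.2``): the helix (or inter-helix) segment of the canonical globin
fold, the 1-based residue number within that segment, and the phase p in
{0, 1, 2} = number of bases of that residue's codon lying 5' of the
intron.  ``E8.1`` therefore sits between codon positions 1 and 2 of the
8th residue of helix E; ``G7.0`` immediately precedes the codon of G7.

Parsimony modes for a binary presence/absence character on a tree:

* ``fitch``      unordered binary small parsimony (root-invariant);
* ``gain_only``  Dollo: at most one gain, losses counted;
* ``loss_only``  character ancestrally present, only losses allowed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .genemodels import GeneModel, ValidationError

#: canonical order of helix and inter-helix segments of the globin fold
CANONICAL_SEGMENTS = [
    "NA", "A", "AB", "B", "BC", "C", "CD", "D", "DE", "E",
    "EF", "F", "FG", "G", "GH", "H", "HC",
]

_NOTATION_RE = re.compile(r"^([A-Z]{1,2})(\d+)\.([012])$")


@dataclass
class FoldMap:
    """Residue index (1-based) -> (segment label, position within segment)."""

    assignments: dict[int, tuple[str, int]]

    @property
    def protein_length(self) -> int:
        return len(self.assignments)

    def segment_of(self, residue: int) -> tuple[str, int]:
        try:
            return self.assignments[residue]
        except KeyError:
            raise ValidationError(f"residue {residue} outside fold map (length {self.protein_length})") from None


@dataclass(frozen=True)
class IntronPosition:
    segment: str
    residue_number: int
    phase: int

    @property
    def notation(self) -> str:
        return f"{self.segment}{self.residue_number}.{self.phase}"

    @classmethod
    def parse(cls, notation: str) -> "IntronPosition":
        m = _NOTATION_RE.match(notation)
        if not m:
            raise ValidationError(f"invalid intron notation {notation!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


def build_fold_map(protein_length: int, segments: list[tuple[str, int, int]]) -> FoldMap:
    """Build a fold map from contiguous (label, start_residue, end_residue) spans.

    Segments must appear in canonical fold order, be contiguous, and cover
    residues 1..protein_length exactly.
    """
    assignments: dict[int, tuple[str, int]] = {}
    expected_start = 1
    last_order = -1
    for label, start, end in segments:
        if label not in CANONICAL_SEGMENTS:
            raise ValidationError(f"unknown segment label {label!r}")
        order = CANONICAL_SEGMENTS.index(label)
        if order <= last_order:
            raise ValidationError(f"segment {label} out of canonical order")
        last_order = order
        if start != expected_start:
            kind = "gap" if start > expected_start else "overlap"
            raise ValidationError(f"{kind} at residue {min(start, expected_start)} (segment {label})")
        if end < start:
            raise ValidationError(f"segment {label} has negative length")
        for r in range(start, end + 1):
            assignments[r] = (label, r - start + 1)
        expected_start = end + 1
    if expected_start != protein_length + 1:
        raise ValidationError(f"segments cover 1..{expected_start - 1}, expected 1..{protein_length}")
    return FoldMap(assignments)


def load_fold_map_tsv(path: str | Path) -> FoldMap:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, start, end = line.split("\t")
        if label == "segment":
            continue
        rows.append((label, int(start), int(end)))
    length = max(end for _, _, end in rows)
    return build_fold_map(length, rows)


def map_intron(gene_model: GeneModel, fold_map: FoldMap, intron_index: int) -> IntronPosition:
    """Locate an intron in helix notation from its CDS offset."""
    offset = gene_model.intron_cds_offset(intron_index)
    cds_len = gene_model.cds_length
    if cds_len // 3 > fold_map.protein_length + 1:
        raise ValidationError(
            f"{gene_model.gene_id}: CDS implies {cds_len // 3} residues but fold map covers {fold_map.protein_length}"
        )
    phase = offset % 3
    residue = offset // 3 + 1
    segment, pos = fold_map.segment_of(residue)
    return IntronPosition(segment, pos, phase)


def locate_intron_offset(position: IntronPosition, fold_map: FoldMap) -> int:
    """Inverse of :func:`map_intron`: CDS offset (bases 5' of the intron)."""
    matches = [r for r, (seg, p) in fold_map.assignments.items() if seg == position.segment and p == position.residue_number]
    if not matches:
        raise ValidationError(f"{position.notation}: no residue {position.residue_number} in segment {position.segment}")
    residue = matches[0]
    return (residue - 1) * 3 + position.phase


# -- presence matrix --------------------------------------------------------


def load_presence_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    validate_presence_matrix(df)
    return df


def validate_presence_matrix(matrix: pd.DataFrame) -> None:
    for col in matrix.columns:
        IntronPosition.parse(col)
    vals = set(matrix.to_numpy().ravel().tolist())
    if not vals <= {0, 1}:
        raise ValidationError(f"presence matrix must be binary, found {sorted(vals - {0, 1})}")


def packaged_presence_matrix() -> pd.DataFrame:
    path = Path(str(resources.files("globkit").joinpath("data", "intron_presence.tsv")))
    return load_presence_matrix(path)


@dataclass
class IntronSummary:
    conservation: dict[str, int]
    positions_per_segment: dict[str, list[str]]
    b12_2_count: int
    g7_0_count: int


def summarize_introns(matrix: pd.DataFrame) -> IntronSummary:
    """Per-position conservation counts and distinct positions per segment."""
    if matrix.empty:
        return IntronSummary({}, {}, 0, 0)
    validate_presence_matrix(matrix)
    conservation = {col: int(matrix[col].sum()) for col in matrix.columns}
    per_seg: dict[str, list[str]] = {}
    for col in matrix.columns:
        if conservation[col] == 0:
            continue
        seg = IntronPosition.parse(col).segment
        per_seg.setdefault(seg, []).append(col)
    return IntronSummary(
        conservation=conservation,
        positions_per_segment=per_seg,
        b12_2_count=conservation.get("B12.2", 0),
        g7_0_count=conservation.get("G7.0", 0),
    )


# -- parsimony --------------------------------------------------------------


def _check_taxa(tree: dendropy.Tree, matrix: pd.DataFrame) -> None:
    tree.is_rooted = True  # Dollo/loss modes interpret the seed node as the root
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    mat_taxa = set(matrix.index)
    if tree_taxa != mat_taxa:
        only_tree = sorted(tree_taxa - mat_taxa)
        only_mat = sorted(mat_taxa - tree_taxa)
        raise ValidationError(f"taxon mismatch: only in tree {only_tree}, only in matrix {only_mat}")


def _fitch_changes(tree: dendropy.Tree, states: dict[str, int]) -> int:
    changes = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset({states[node.taxon.label]})
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = frozenset.union(*child_sets)
                changes += len(child_sets) - 1
    return changes


def _all_absent_flags(tree: dendropy.Tree, states: dict[str, int]) -> dict[int, bool]:
    absent: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            absent[id(node)] = states[node.taxon.label] == 0
        else:
            absent[id(node)] = all(absent[id(c)] for c in node.child_nodes())
    return absent


def _count_maximal_absent_clades(root: dendropy.Node, absent: dict[int, bool]) -> int:
    """Losses = maximal all-absent subtrees below (and including) ``root``."""
    if absent[id(root)]:
        return 1
    count = 0
    stack = list(root.child_nodes())
    while stack:
        node = stack.pop()
        if absent[id(node)]:
            count += 1
        else:
            stack.extend(node.child_nodes())
    return count


def parsimony_events(tree: dendropy.Tree, matrix: pd.DataFrame, mode: str = "fitch") -> pd.DataFrame:
    """Minimal event counts per character under the chosen scenario.

    Returns a DataFrame indexed by character with columns ``gains``,
    ``losses`` and ``events`` (their sum; for ``fitch`` the unpolarized
    change count appears in ``events`` alone).
    """
    if mode not in ("fitch", "gain_only", "loss_only"):
        raise ValidationError(f"unknown parsimony mode {mode!r}")
    # characters need not carry helix notations (simulated matrices do not)
    vals = set(matrix.to_numpy().ravel().tolist())
    if not vals <= {0, 1}:
        raise ValidationError(f"presence matrix must be binary, found {sorted(vals - {0, 1})}")
    _check_taxa(tree, matrix)
    rows = []
    for col in matrix.columns:
        states = {t: int(matrix.loc[t, col]) for t in matrix.index}
        if mode == "fitch":
            events = _fitch_changes(tree, states)
            rows.append({"character": col, "gains": None, "losses": None, "events": events})
        elif mode == "gain_only":
            present = [t for t, s in states.items() if s == 1]
            if not present:
                rows.append({"character": col, "gains": 0, "losses": 0, "events": 0})
                continue
            mrca = tree.mrca(taxon_labels=present) if len(present) > 1 else next(
                leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == present[0]
            )
            absent = _all_absent_flags(tree, states)
            losses = _count_maximal_absent_clades(mrca, absent) if not mrca.is_leaf() else 0
            rows.append({"character": col, "gains": 1, "losses": losses, "events": 1 + losses})
        else:  # loss_only: ancestrally present at the root, no gains
            absent = _all_absent_flags(tree, states)
            losses = _count_maximal_absent_clades(tree.seed_node, absent)
            rows.append({"character": col, "gains": 0, "losses": losses, "events": losses})
    return pd.DataFrame(rows).set_index("character")
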