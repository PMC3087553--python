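"""Global protein alignment and percent identity/similarity matrices.

Needleman-Wunsch with affine gaps (Gotoh), end gaps penalized, PAM250 by
default — the scoring class of MatGAT-style identity/similarity tables.
The traceback tie-break is fixed (diagonal, then up, then left) so output
is deterministic.  Percentages use the length of the shorter ungapped
sequence as denominator; a substitution score > 0 counts as "similar".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .genemodels import ValidationError

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX")

NEG_INF = float("-inf")
_EPS = 1e-9


def _load_matrix(name: str) -> dict[tuple[str, str], float]:
    m = substitution_matrices.load(name)
    out: dict[tuple[str, str], float] = {}
    for x in m.alphabet:
        for y in m.alphabet:
            out[(x, y)] = float(m[x, y])
    # X scores 0 against everything (unknown residue)
    for x in set(m.alphabet) | {"X"}:
        out[(x, "X")] = 0.0
        out[("X", x)] = 0.0
    return out


@dataclass
class ScoringScheme:
    """Substitution matrix plus positive affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``; terminal gaps
    are charged like internal ones.
    """

    matrix_name: str = "PAM250"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if not self.values:
            self.values = _load_matrix(self.matrix_name)

    def score(self, x: str, y: str) -> float:
        return self.values[(x, y)]


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValidationError("gap-gap column in alignment")


def _validate_seq(s: str, name: str) -> None:
    if not s:
        raise ValidationError(f"sequence {name} is empty")
    for i, c in enumerate(s):
        if c not in _VALID_AA:
            raise ValidationError(f"sequence {name}: illegal character {c!r} at position {i + 1}")


# DP states: 0 = M (diagonal), 1 = X (gap in b, consumes a), 2 = Y (gap in a)


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment (affine gaps, end gaps penalized).

    Ties prefer the diagonal move, then the up move (gap in ``b``), then
    the left move (gap in ``a``).
    """
    scheme = scheme or ScoringScheme()
    a, b = a.upper(), b.upper()
    _validate_seq(a, "A")
    _validate_seq(b, "B")
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend

    S = np.full((3, n + 1, m + 1), NEG_INF)
    S[0, 0, 0] = 0.0
    for i in range(1, n + 1):
        S[1, i, 0] = -(go + ge * i)
    for j in range(1, m + 1):
        S[2, 0, j] = -(go + ge * j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = scheme.score(ai, b[j - 1])
            S[0, i, j] = max(S[0, i - 1, j - 1], S[1, i - 1, j - 1], S[2, i - 1, j - 1]) + sub
            S[1, i, j] = max(S[0, i - 1, j] - go - ge, S[1, i - 1, j] - ge, S[2, i - 1, j] - go - ge)
            S[2, i, j] = max(S[0, i, j - 1] - go - ge, S[1, i, j - 1] - go - ge, S[2, i, j - 1] - ge)

    final = [S[k, n, m] for k in range(3)]
    best = max(final)
    state = next(k for k in range(3) if final[k] >= best - _EPS)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = S[0, i, j] - scheme.score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            cands = [(0, S[0, i, j]), (1, S[1, i, j]), (2, S[2, i, j])]
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = S[1, i, j]
            i -= 1
            cands = [(0, S[0, i, j] - go - ge), (1, S[1, i, j] - ge), (2, S[2, i, j] - go - ge)]
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = S[2, i, j]
            j -= 1
            cands = [(0, S[0, i, j] - go - ge), (1, S[1, i, j] - go - ge), (2, S[2, i, j] - ge)]
        if i == 0 and j == 0:
            break
        if state != 0:
            # the gap-state value equals the best of its sources
            target = max(v for _, v in cands)
        state = next(k for k, v in cands if abs(v - target) < _EPS)

    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(best))


def identity_similarity(aln: PairwiseAlignment, scheme: ScoringScheme | None = None) -> tuple[float, float]:
    """Percent identity and similarity over the shorter ungapped sequence."""
    scheme = scheme or ScoringScheme()
    a_res = aln.aligned_a.replace("-", "")
    b_res = aln.aligned_b.replace("-", "")
    denom = min(len(a_res), len(b_res))
    ident = sim = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if scheme.score(x, y) > 0:
            sim += 1
    return 100.0 * ident / denom, 100.0 * sim / denom


@dataclass
class SimilarityMatrix:
    identity: pd.DataFrame
    similarity: pd.DataFrame


def all_pairs_matrix(seqs: dict[str, str], scheme: ScoringScheme | None = None) -> SimilarityMatrix:
    """Symmetric percent identity and similarity matrices, diagonal 100."""
    scheme = scheme or ScoringScheme()
    labels = list(seqs)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate sequence labels")
    if len(labels) < 2:
        raise ValidationError("need at least 2 sequences")
    ident = pd.DataFrame(100.0, index=labels, columns=labels)
    sim = pd.DataFrame(100.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            aln = global_align(seqs[la], seqs[lb], scheme)
            pi, ps = identity_similarity(aln, scheme)
            ident.loc[la, lb] = ident.loc[lb, la] = pi
            sim.loc[la, lb] = sim.loc[lb, la] = ps
    return SimilarityMatrix(identity=ident, similarity=sim)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.round(1).to_csv(path, sep="\t", float_format="%.1f")
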