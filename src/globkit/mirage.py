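"""Detection of mirage minisatellites at exon-intron boundaries.

A "mirage" is a tandem duplication whose repeat unit spans a splice
junction: copies of the 3' end of an intron plus the 5' start of the next
exon (acceptor side), or of the 3' end of an exon plus the 5' start of
the following intron (donor side).  Detection replaces dot-plot
inspection with a deterministic operator:

1. window of +-2 x max_unit_length around each annotated splice junction;
2. exact k-mer self-comparison inside the window; the tandem period is a
   modal spacing between repeated k-mers (smallest passing candidate);
3. repeat extent refined from the lag-period per-base match profile;
4. units tiled at the period from the refined extent start; clusters
   failing the parameter thresholds (min units, identity, boundary
   overlap) are discarded.

Units within a cluster are compared by global nucleotide alignment
(match +1 / mismatch -1, gap open 2 / extend 1), and related by a
neighbor-joining tree of (100 - identity) distances, the standard readout
for concerted evolution within a repeat cluster.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genemodels import GeneModel, ValidationError
from .simulate import MirageSpec, make_mirage_gene


@dataclass
class DetectorParams:
    seed_kmer: int = 10
    min_unit_length: int = 50
    max_unit_length: int = 500
    min_mean_identity: float = 70.0
    min_units: int = 2
    boundary_overlap: int = 10  # bp required on each side of the junction
    # per-base score offset for the maximal-scoring repeat segment: random
    # sequence matches at ~0.25 per base under any lag, tandem copies at
    # >= ~0.7 even at 15% per-unit divergence, so 0.45 separates the two
    segment_baseline: float = 0.45
    min_segment_score: float = 5.0

    def __post_init__(self) -> None:
        if self.min_unit_length >= self.max_unit_length:
            raise ValidationError("min_unit_length must be < max_unit_length")
        if not 50.0 < self.min_mean_identity <= 100.0:
            raise ValidationError("identity threshold must lie in (50, 100]")


@dataclass
class MirageCluster:
    gene_id: str
    intron_index: int
    side: str  # "acceptor" | "donor"
    junction: int  # genomic coordinate of the junction (0-based)
    unit_intervals: list[tuple[int, int]]
    consensus_length: int
    partial_units: list[tuple[int, int]] = field(default_factory=list)
    has_AG_at_acceptor_offset: list[bool] = field(default_factory=list)
    has_GT_at_donor_offset: list[bool] = field(default_factory=list)
    identity_matrix: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return len(self.unit_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.unit_intervals[0][0], self.unit_intervals[-1][1])


# -- nucleotide global alignment (match +1 / mismatch -1, gap 2 + 1k) -------

_nuc_aligner = None


def _get_nuc_aligner():
    global _nuc_aligner
    if _nuc_aligner is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -3.0  # gap of length k costs 2 + k
        a.extend_gap_score = -1.0
        _nuc_aligner = a
    return _nuc_aligner


def _nuc_identity_pct(a: str, b: str) -> float:
    """Percent identity from a global alignment, shorter sequence as denominator."""
    aln = _get_nuc_aligner().align(a, b)[0]
    return 100.0 * aln.counts().identities / min(len(a), len(b))


# -- period estimation ------------------------------------------------------


def _period_candidates(window: str, params: DetectorParams) -> list[int]:
    """Spacings between repeated k-mers, most supported first."""
    k = params.seed_kmer
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(window) - k + 1):
        pos[window[i : i + k]].append(i)
    spacing_support: Counter = Counter()
    for plist in pos.values():
        if len(plist) < 2:
            continue
        for x, y in zip(plist, plist[1:]):
            d = y - x
            if params.min_unit_length <= d <= params.max_unit_length:
                spacing_support[d] += 1
    cands = [d for d, c in spacing_support.items() if c >= 1]
    cands.sort(key=lambda d: (-spacing_support[d], d))
    return cands[:10]


def _lag_match_extent(window: str, lag: int, params: DetectorParams):
    """Footprint of the tandem repeat at a candidate period within the window.

    Scores each position x by ``match(x, x + lag) - baseline`` and takes
    the maximal-scoring contiguous segment (Kadane): random sequence
    drifts negative (~0.25 match rate), true tandem copies positive, so
    interior mutation dips cannot fragment the segment.  Returns the
    (start, end) of the full repeated footprint or None.
    """
    n = len(window)
    if lag >= n:
        return None
    m = np.frombuffer(window.encode(), dtype=np.uint8)
    f = (m[:-lag] == m[lag:]).astype(np.float64) - params.segment_baseline
    best = run = 0.0
    best_bounds = None
    run_start = 0
    for i, v in enumerate(f):
        if run <= 0.0:
            run, run_start = v, i
        else:
            run += v
        if run > best:
            best = run
            best_bounds = (run_start, i + 1)
    if best_bounds is None or best < params.min_segment_score:
        return None
    s, e = best_bounds
    return s, e + lag  # positions x and x+lag both belong to the repeat


def _junctions(model: GeneModel):
    """(intron_index, side, junction coordinate) for every splice boundary."""
    out = []
    for idx, (a, b) in enumerate(model.introns):
        out.append((idx, "donor", a))  # first intronic base
        out.append((idx, "acceptor", b))  # first exonic base of next exon
    return out


def detect_mirage(genomic_seq: str, gene_model: GeneModel, params: DetectorParams | None = None) -> list[MirageCluster]:
    """Scan every splice junction of a gene model for tandem repeat clusters."""
    params = params or DetectorParams()
    seq = genomic_seq.upper()
    g0, g1 = gene_model.span
    if g1 > len(seq):
        raise ValidationError(f"{gene_model.gene_id}: gene model exceeds sequence bounds")
    clusters = []
    for intron_index, side, junction in _junctions(gene_model):
        reach = 2 * params.max_unit_length
        w0, w1 = max(0, junction - reach), min(len(seq), junction + reach)
        window = seq[w0:w1]
        anchor = junction - w0
        best = None
        for period in sorted(_period_candidates(window, params)):
            # grow the window while the repeat footprint touches its edge,
            # so clusters larger than the initial reach are not truncated
            ww0, ww1 = w0, w1
            for _ in range(8):
                wwindow = seq[ww0:ww1]
                extent = _lag_match_extent(wwindow, period, params)
                if extent is None:
                    break
                touches_left = extent[0] <= 2 and ww0 > 0
                touches_right = extent[1] >= len(wwindow) - 2 and ww1 < len(seq)
                if not (touches_left or touches_right):
                    break
                ww0 = max(0, ww0 - 4 * period) if touches_left else ww0
                ww1 = min(len(seq), ww1 + 4 * period) if touches_right else ww1
            if extent is None:
                continue
            anchor = junction - ww0
            ext0, ext1 = extent
            # cluster must straddle the junction
            if not (ext0 + params.boundary_overlap <= anchor <= ext1 - params.boundary_overlap):
                continue
            n_full = int((ext1 - ext0) // period)
            rem = (ext1 - ext0) - n_full * period
            if rem >= 0.5 * period:
                n_full += 1
            if n_full < params.min_units:
                continue
            intervals = [(ww0 + ext0 + i * period, ww0 + ext0 + (i + 1) * period) for i in range(n_full)]
            intervals = [(a, min(b, len(seq))) for a, b in intervals]
            units = [seq[a:b] for a, b in intervals]
            if any(len(u) < 0.5 * period for u in units):
                continue
            idm = np.full((n_full, n_full), 100.0)
            for i in range(n_full):
                for j in range(i + 1, n_full):
                    idm[i, j] = idm[j, i] = _nuc_identity_pct(units[i], units[j])
            off = np.triu_indices(n_full, k=1)
            if idm[off].mean() < params.min_mean_identity:
                continue
            cluster = MirageCluster(
                gene_id=gene_model.gene_id,
                intron_index=intron_index,
                side=side,
                junction=junction,
                unit_intervals=intervals,
                consensus_length=period,
                identity_matrix=idm,
            )
            _fill_signals(cluster, seq)
            best = cluster
            break  # smallest passing period wins
        if best is not None:
            clusters.append(best)
    # deduplicate identical spans reported from two junctions of one intron
    seen: set[tuple] = set()
    unique = []
    for c in clusters:
        key = (c.span, c.consensus_length)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def _fill_signals(cluster: MirageCluster, seq: str, tolerance: int = 2) -> None:
    """Flag AG (acceptor) / GT (donor) at the homologous offset in each unit."""
    L = cluster.consensus_length
    start = cluster.unit_intervals[0][0]
    if cluster.side == "acceptor":
        offset = (cluster.junction - start) % L - 2  # AG ends right before the junction
        target = "AG"
    else:
        offset = (cluster.junction - start) % L  # GT begins at the junction
        target = "GT"
    ag_flags, gt_flags = [], []
    for a, _ in cluster.unit_intervals:
        found = False
        for d in range(-tolerance, tolerance + 1):
            p = a + offset + d
            if 0 <= p <= len(seq) - 2 and seq[p : p + 2] == target:
                found = True
                break
        (ag_flags if target == "AG" else gt_flags).append(found)
    cluster.has_AG_at_acceptor_offset = ag_flags
    cluster.has_GT_at_donor_offset = gt_flags


def unit_identity_matrix(cluster: MirageCluster, genomic_seq: str) -> np.ndarray:
    """Pairwise percent identity of cluster units by global alignment."""
    units = [genomic_seq[a:b] for a, b in cluster.unit_intervals]
    n = len(units)
    idm = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            idm[i, j] = idm[j, i] = _nuc_identity_pct(units[i], units[j])
    return idm


def scan_splice_signals(cluster: MirageCluster, genomic_seq: str, tolerance: int = 2):
    """Per-unit table of cryptic splice-signal presence at the homologous offset."""
    _fill_signals(cluster, genomic_seq.upper(), tolerance)
    flags = cluster.has_AG_at_acceptor_offset if cluster.side == "acceptor" else cluster.has_GT_at_donor_offset
    return [
        {"unit": f"D{i + 1}", "interval": iv, "signal": "AG" if cluster.side == "acceptor" else "GT", "present": f}
        for i, (iv, f) in enumerate(zip(cluster.unit_intervals, flags))
    ]


# -- neighbor joining -------------------------------------------------------


def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Deterministic tie-break: among minimal-Q pairs, the lexicographically
    lowest (sorted) label pair is joined.  Negative branch lengths are
    clamped to zero.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be square and symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0):
        raise ValidationError("distance matrix must be non-negative with zero diagonal")
    if n < 3:
        raise ValidationError("need at least 3 taxa")
    if len(labels) != n or len(set(labels)) != n:
        raise ValidationError("labels must be unique and match the matrix")

    nodes = list(labels)  # newick fragment per active node
    names = list(labels)  # tie-break key per active node (lowest leaf label)
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        tot = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - tot[i] - tot[j]
                key = tuple(sorted((names[i], names[j])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (tot[i] - tot[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})"
        new_name = min(names[i], names[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                D2[a, b] = D[ka, kb]
            D2[a, -1] = D2[-1, a] = max(dnew[ka], 0.0)
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]
    # final star: three-point formulas give the exact branch lengths
    la = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lb = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lc = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    return f"({nodes[0]}:{la:.6f},{nodes[1]}:{lb:.6f},{nodes[2]}:{lc:.6f});"


# -- forward model: intron gain from a mirage cluster -----------------------


def simulate_intron_gain(cluster_spec: MirageSpec, recruit_unit_index: int, seed: int | None = None):
    """Forward model of intron gain: one repeat unit's exonic part becomes a new exon.

    The recruited unit's cryptic AG acceptor and the GT at the start of
    the following unit become the splice signals of the new exon; the
    repeats in between turn intronic.  Returns ``(seq, pre_model,
    post_model)``; the spliced exon sequence outside the recruited
    segment is unchanged.
    """
    if cluster_spec.boundary_kind != "acceptor_side":
        raise ValidationError("intron-gain model is defined for acceptor-side clusters")
    spec = cluster_spec if seed is None else MirageSpec(**{**_spec_dict(cluster_spec), "seed": seed})
    seq, pre_model, truth = make_mirage_gene(spec)
    n = truth.n_units
    r = recruit_unit_index
    if not 1 <= r <= n - 1:
        raise ValidationError(f"recruit_unit_index must be interior to the cluster (1..{n - 1})")
    L = spec.unit_length
    ip = spec.intron_part_length
    u_start, u_end = truth.unit_intervals[r - 1]
    new_exon = (u_start + ip, u_end)
    if seq[new_exon[0] - 2 : new_exon[0]] != "AG":
        raise ValidationError("no cryptic site: recruited unit lacks its AG acceptor")
    if seq[new_exon[1] : new_exon[1] + 2] != "GT":
        raise ValidationError("no cryptic site: no GT donor follows the recruited unit")
    exons = [pre_model.exons[0], new_exon] + pre_model.exons[1:]
    post_model = GeneModel(
        gene_id=pre_model.gene_id + "_postgain",
        seq_id=pre_model.seq_id,
        strand="+",
        exons=exons,
    )
    return seq, pre_model, post_model


def _spec_dict(spec: MirageSpec) -> dict:
    from dataclasses import asdict

    return asdict(spec)
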