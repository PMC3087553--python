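"""Seeded synthetic fixtures for every pipeline stage.

Generators here are pure functions of (spec, seed): identical inputs give
bit-identical outputs.  Each emits a truth record alongside the data so
detectors and counters can be scored against planted ground truth.

The mirage generator emulates minisatellite-like tandem duplications of an
exon-intron boundary: every repeat unit is a copy of either the 3' end of
an intron plus the 5' start of the following exon (acceptor side) or the
3' end of an exon plus the 5' start of the following intron (donor side).
The unit template carries the canonical splice dinucleotides (AG before
the exonic segment, GT at the intronic segment start), so duplicated units
contain cryptic splice signals unless mutated away.  Mutations are
substitutions only; truth identities therefore stay analytic.  Unit split
point is 60% intronic / 40% exonic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import dendropy
import numpy as np

from .genemodels import GeneModel, ValidationError

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MirageSpec:
    """Parameters of a planted mirage cluster and its host gene."""

    unit_length: int
    n_units: int
    per_unit_divergence: float
    boundary_kind: str  # "acceptor_side" | "donor_side"
    intron_core_length: int = 400
    exon_lengths: tuple[int, ...] = (120, 280)
    seed: int = 0
    knockout_signal_units: tuple[int, ...] = ()  # 1-based unit indices whose splice signal is destroyed

    def __post_init__(self) -> None:
        if self.unit_length <= 0 or self.n_units < 1:
            raise ValidationError("n_units and unit_length must be positive")
        if not 0.0 <= self.per_unit_divergence <= 0.5:
            raise ValidationError(f"per_unit_divergence {self.per_unit_divergence} outside [0, 0.5]")
        if self.boundary_kind not in ("acceptor_side", "donor_side"):
            raise ValidationError(f"unknown boundary_kind {self.boundary_kind!r}")
        if len(self.exon_lengths) < 2:
            raise ValidationError("gene needs at least 2 exons")

    @property
    def intron_part_length(self) -> int:
        return int(round(self.unit_length * 0.6))

    @property
    def exon_part_length(self) -> int:
        return self.unit_length - self.intron_part_length


@dataclass
class TruthRecord:
    """Planted ground truth emitted with every mirage fixture."""

    spec: dict
    unit_intervals: list[tuple[int, int]]
    n_units: int
    identities_pct: dict[str, float]
    signal_states: list[bool]
    junction: int
    intron_index: int
    side: str
    seed: int


PRESETS: dict[str, MirageSpec] = {
    # BflGb6 haplotype 1: 6 acceptor-side units of ~155 bp, one cryptic
    # signal mutated away ("many, but not all" units carry AG/GT).
    "bflgb6_h1": MirageSpec(
        unit_length=155, n_units=6, per_unit_divergence=0.08, boundary_kind="acceptor_side",
        intron_core_length=400, exon_lengths=(120, 280), seed=101, knockout_signal_units=(3,),
    ),
    # BflGb6 haplotype 2: 3 units of the same structure.
    "bflgb6_h2": MirageSpec(
        unit_length=155, n_units=3, per_unit_divergence=0.08, boundary_kind="acceptor_side",
        intron_core_length=400, exon_lengths=(120, 280), seed=102,
    ),
    # BflGb9: donor-side duplication, 157 bp units.
    "bflgb9": MirageSpec(
        unit_length=157, n_units=2, per_unit_divergence=0.05, boundary_kind="donor_side",
        intron_core_length=400, exon_lengths=(200, 260), seed=202,
    ),
}


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, unit: np.ndarray, divergence: float) -> np.ndarray:
    out = unit.copy()
    hits = np.flatnonzero(rng.random(len(unit)) < divergence)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _ungapped_identity_pct(a: str, b: str) -> float:
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * same / n


def make_mirage_gene(spec: MirageSpec, gene_id: str = "synthetic_mirage") -> tuple[str, GeneModel, TruthRecord]:
    """Build a two-exon gene whose splice boundary carries a planted mirage cluster.

    Returns the genomic sequence, the gene model (forward strand), and the
    truth record with planted unit intervals, identities and signal states.
    """
    rng = np.random.default_rng(spec.seed)
    L, n = spec.unit_length, spec.n_units
    ip, ep = spec.intron_part_length, spec.exon_part_length
    e_lens = spec.exon_lengths

    template = _random_dna(rng, L)
    if spec.boundary_kind == "acceptor_side":
        # unit = [GT ... intron tail ... AG | exon head]
        template[0:2] = list("GT")
        template[ip - 2 : ip] = list("AG")
        sig_at = ip - 2  # AG offset within the unit
        sig = "AG"
    else:
        # unit = [exon tail | GT ... intron head ...]
        template[ep : ep + 2] = list("GT")
        sig_at = ep
        sig = "GT"

    units = [_mutate(rng, template, spec.per_unit_divergence) for _ in range(n)]
    real_unit = n - 1 if spec.boundary_kind == "acceptor_side" else 0
    # the authentic junction must keep its splice dinucleotide intact
    units[real_unit][sig_at : sig_at + 2] = list(sig)
    for k in spec.knockout_signal_units:
        if not 1 <= k <= n:
            raise ValidationError(f"knockout unit index {k} out of range")
        if k - 1 == real_unit:
            raise ValidationError("cannot knock out the authentic splice signal")
        units[k - 1][sig_at : sig_at + 2] = list("CC")

    core = _random_dna(rng, spec.intron_core_length)
    if spec.boundary_kind == "acceptor_side":
        if e_lens[1] <= ep:
            raise ValidationError("exon 2 shorter than the unit's exonic part")
        exon1 = _random_dna(rng, e_lens[0])
        exon2_rest = _random_dna(rng, e_lens[1] - ep)
        core[0:2] = list("GT")  # authentic donor of the intron
        parts = [exon1, core] + units + [exon2_rest]
        seq = "".join("".join(p) for p in parts)
        cluster_start = e_lens[0] + spec.intron_core_length
        junction = cluster_start + (n - 1) * L + ip  # first base of exon 2
        exons = [(0, e_lens[0]), (junction, junction + e_lens[1])]
        intron_index = 0
    else:
        if e_lens[0] <= ep:
            raise ValidationError("exon 1 shorter than the unit's exonic part")
        exon1_rest = _random_dna(rng, e_lens[0] - ep)
        exon2 = _random_dna(rng, e_lens[1])
        tail = _random_dna(rng, 20)
        tail[-2:] = list("AG")  # authentic acceptor of the intron
        parts = [exon1_rest] + units + [core, tail, exon2]
        seq = "".join("".join(p) for p in parts)
        cluster_start = e_lens[0] - ep
        junction = e_lens[0]  # first intronic base
        exon2_start = cluster_start + n * L + spec.intron_core_length + 20
        exons = [(0, e_lens[0]), (exon2_start, exon2_start + e_lens[1])]
        intron_index = 0

    model = GeneModel(gene_id=gene_id, seq_id=f"{gene_id}_region", strand="+", exons=exons)
    unit_strs = ["".join(u) for u in units]
    identities = {
        f"D{i + 1}|D{j + 1}": _ungapped_identity_pct(unit_strs[i], unit_strs[j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    signal_states = ["".join(u[sig_at : sig_at + 2]) == sig for u in units]
    truth = TruthRecord(
        spec=asdict(spec),
        unit_intervals=[(cluster_start + i * L, cluster_start + (i + 1) * L) for i in range(n)],
        n_units=n,
        identities_pct=identities,
        signal_states=signal_states,
        junction=junction,
        intron_index=intron_index,
        side="acceptor" if spec.boundary_kind == "acceptor_side" else "donor",
        seed=spec.seed,
    )
    return seq, model, truth


# -- haplotype pairs --------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_haplotype_pair(protein: str, target_protein_divergence: float, seed: int) -> tuple[str, str, float]:
    """Derive an allelic partner by PAM-favoring substitutions.

    Substituted positions are drawn uniformly without replacement; the
    replacement residue at each position is drawn with probability
    proportional to 2**PAM250(x, y) over y != x, so conservative exchanges
    dominate, as between real haplotypes.  Returns (A, B, identity_pct)
    with the identity computed by direct string comparison.
    """
    if not 0.0 <= target_protein_divergence <= 0.1:
        raise ValidationError("target divergence must lie in [0, 0.1]")
    from Bio.Align import substitution_matrices

    pam = substitution_matrices.load("PAM250")
    rng = np.random.default_rng(seed)
    b = list(protein)
    n_sub = int(round(target_protein_divergence * len(protein)))
    positions = rng.choice(len(protein), size=min(n_sub, len(protein)), replace=False)
    for pos in positions:
        x = b[pos]
        if x not in _AA:
            continue
        cands = [y for y in _AA if y != x]
        w = np.array([2.0 ** pam[x, y] for y in cands])
        b[pos] = cands[rng.choice(len(cands), p=w / w.sum())]
    bs = "".join(b)
    same = sum(1 for x, y in zip(protein, bs) if x == y)
    return protein, bs, 100.0 * same / len(protein)


# -- intron presence/absence characters on a tree ---------------------------


def _check_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if len(node.child_nodes()) != 2:
            raise ValidationError("tree must be binary (every internal node with exactly 2 children)")


def make_intron_characters(
    tree: dendropy.Tree,
    n_characters: int,
    gain_rate: float,
    loss_rate: float,
    seed: int,
    root_state: int = 0,
    plant_gain_clade: set[str] | None = None,
):
    """Evolve binary presence/absence characters along a rooted binary tree.

    A two-state Markov process (0 -> 1 at ``gain_rate``, 1 -> 0 at
    ``loss_rate`` per unit branch length) runs down every branch; every
    realized event is logged per branch.  Returns ``(matrix, events)``
    where ``matrix`` is a pandas DataFrame (taxa x characters, 0/1) and
    ``events`` a list of per-character dicts with gain/loss counts and the
    branch-by-branch event log.

    With ``plant_gain_clade`` given, a single deterministic character is
    produced instead: one gain on the branch subtending that clade.
    """
    import pandas as pd

    if gain_rate < 0 or loss_rate < 0:
        raise ValidationError("rates must be non-negative")
    _check_binary(tree)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    if plant_gain_clade is not None:
        tree.is_rooted = True
        mrca = tree.mrca(taxon_labels=sorted(plant_gain_clade))
        below = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if below != set(plant_gain_clade):
            raise ValidationError("plant_gain_clade is not a clade of the tree")
        states = {t: int(t in below) for t in taxa}
        matrix = pd.DataFrame({"planted_gain": [states[t] for t in taxa]}, index=taxa)
        events = [{"character": "planted_gain", "gains": 1, "losses": 0, "log": [("mrca_edge", "gain")]}]
        return matrix, events

    rng = np.random.default_rng(seed)
    columns = {}
    events = []
    for c in range(n_characters):
        state_at: dict[int, int] = {id(tree.seed_node): int(root_state)}
        log: list[tuple[str, str]] = []
        gains = losses = 0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            s = state_at[id(node.parent_node)]
            t_remaining = node.edge.length if node.edge.length is not None else 1.0
            while True:
                rate = gain_rate if s == 0 else loss_rate
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= t_remaining:
                    break
                t_remaining -= wait
                if s == 0:
                    s, gains = 1, gains + 1
                    log.append((_edge_label(node), "gain"))
                else:
                    s, losses = 0, losses + 1
                    log.append((_edge_label(node), "loss"))
            state_at[id(node)] = s
        columns[f"char{c}"] = [state_at[id(leaf)] for leaf in tree.leaf_node_iter()]
        events.append({"character": f"char{c}", "gains": gains, "losses": losses, "log": log})
    matrix = pd.DataFrame(columns, index=taxa)
    return matrix, events


def _edge_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return f"edge_to_{node.taxon.label}"
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "edge_to_clade_" + "+".join(tips)


# -- noisy biexponential rebinding traces (thin wrapper) --------------------


def make_rebinding_trace(params, co_conc: float, time_grid, noise_sigma: float, seed: int):
    """Noisy rebinding trace; delegates to the kinetics simulator."""
    from .kinetics import simulate_rebinding

    return simulate_rebinding(params, co_conc, time_grid, noise_sigma=noise_sigma, seed=seed)
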