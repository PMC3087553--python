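# Methods

## Rebinding kinetics

**Model.** Three states after full photolysis: pentacoordinate heme P,
internally hexacoordinate His-bound H, and CO-bound C. With CO in excess
the scheme is linear:

    dP/dt = −(a + k_on_His)·P + k_off_His·H + k_off_CO·C
    dH/dt =  k_on_His·P − k_off_His·H
    dC/dt =  a·P − k_off_CO·C,      a = k_on_CO·[CO]

The observable is deltaA_N = P + H (fraction of hemes not CO-bound),
normalized to 1 at t = 0. `simulate_rebinding` integrates this with Radau
(atol 1e-10, rtol 1e-8, analytic Jacobian). For k_off_CO = 0 the C state
is absorbing and `closed_form_rebinding` evaluates the exact
biexponential from the eigen-decomposition of the 2×2 (P, H) subsystem;
the ODE path agrees with it to ≤1e-6 absolute (property-tested over 100
random rate sets on [0, 5 s]).

**Assumptions.** Pseudo-first-order CO (ligand in excess); full
photolysis (P(0) = 1); CO dissociation negligible on the observed
timescale (k_off_CO = 0 by default, toggleable); no additional
conformational states, no redox/disulfide modulation, no oxygen-pulse
competition, no temperature dependence beyond the labeled solubility
constant.

**Defaults** (`default_bflgb4_params`): k_on_His = 4000 s⁻¹ and
k_off_His = 2 s⁻¹ (the measured internal-ligand rates this package is
built to recover); k_on_CO = 50 µM⁻¹s⁻¹ and k_on_O2 = 200 µM⁻¹s⁻¹,
plausible neuroglobin-class values chosen once (at 100 µM CO this puts
a = 5000 s⁻¹ next to k_on_His = 4000 s⁻¹, i.e. visibly biphasic
competition); k_off_O2 is pinned so that the equilibrium half-saturation
pressure is exactly 3 Torr at 25 °C:
k_off_O2 = P50·s·k_on_O2/(1 + K_His) with K_His = k_on_His/k_off_His =
2000 and s = 1.82 µM/Torr (O2 solubility in water at 25 °C, a named,
overridable constant). The oxygen rates are pinned defaults, not
measured values.

**Fitting.** `fit_biphasic` does trust-region least squares of
A_f·e^(−r_f t) + A_s·e^(−r_s t) + b with multi-start initialization over
a log-spaced rate grid (8 per rate), best residual kept. `fit_mechanism`
fits (k_on_CO, k_on_His, k_off_His) in log space, Levenberg–Marquardt,
globally across all traces against the closed-form model; the His rates
are flagged unidentifiable when no eigenmode pair carries > 1e-3
amplitude at any concentration (effectively monoexponential data). The
slow phase only constrains k_off_His when the grid extends to seconds;
the fast phase alone (10 ms grids) suffices for k_on_His and k_on_CO.

## Intron helix notation and parsimony

An intron position is `<segment><residue>.<phase>` where phase p ∈
{0, 1, 2} is the number of bases of that residue's codon lying 5' of the
intron; p = 0 means the intron immediately precedes the codon (so G7.0
precedes the codon of G-helix residue 7, and E8.1 sits between codon
positions 1 and 2 of E-helix residue 8). Inter-segment regions (NA, CD,
EF, HC, …) number residues from the start of the region. The fold-map
annotation is an input (packaged as a transcription-style fixture), never
derived from structure.

Parsimony modes per binary character: `fitch` (unordered small
parsimony, root-invariant; verified against exhaustive enumeration over
all internal-state assignments for every 4-taxon topology and leaf
pattern), `gain_only` (Dollo: exactly one gain at the MRCA of the present
taxa, plus the minimal number of losses = maximal all-absent clades
inside that subtree), and `loss_only` (ancestrally present, losses =
maximal all-absent clades in the whole rooted tree). These are the three
scenarios weighed when arguing that scattered E-helix ("central") intron
positions are convergent gains rather than repeated losses: a character
confined to one clade costs one gain versus one loss per complementary
lineage.

## Mirage detection

Detection replaces dot-plot inspection with a deterministic operator per
annotated splice junction:

1. window of ±2×max_unit_length (default 500 bp) around the junction;
2. candidate tandem periods = spacings between repeated exact k-mers
   (k = 10) within the window, most-supported first;
3. for each candidate period L, the repeat footprint is the
   maximal-scoring contiguous segment of the per-base profile
   match(x, x+L) − 0.45 (Kadane). Random sequence matches at ~0.25/base
   and drifts negative; tandem copies match at ≥ ~0.7 even at 15%
   per-unit divergence, so interior mutation dips cannot fragment the
   segment. The window grows while the footprint touches its edge, so
   clusters larger than the initial reach are not truncated;
4. units are tiled at the period from the footprint start; the smallest
   period whose cluster passes all filters wins (larger multiples of the
   true period also score, sub-multiples fail the identity filter);
5. filters (defaults): ≥2 full units, ≥50 bp and ≤500 bp period, mean
   pairwise unit identity ≥ 70%, cluster straddling the junction by
   ≥10 bp on each side. Terminal partials < 50% of the period are not
   counted as units.

k = 10 rather than a longer seed: with 12-mers the expected number of
intact seed pairs in a 60-bp unit at 15% per-unit divergence drops to ~1,
which forfeits the recall target; 10-mers keep seed discovery reliable
while the footprint/identity filters (not the seeds) control false
positives — zero clusters across 50 shuffled-sequence seeds.

Unit identities use global nucleotide alignment (match +1, mismatch −1,
gap open 2, extend 1; shorter unit as denominator). Cryptic splice
signals are scored as AG (acceptor side) or GT (donor side) within ±2 bp
of the homologous offset defined by the authentic junction. Repeat-unit
relationships use Saitou–Nei neighbor joining on (100 − identity)
distances with a fixed lexicographic tie-break and non-negativity-clamped
branch lengths; 3-taxon stars use the exact three-point formulas.

**Intron-gain forward model.** In an acceptor-side cluster, a recruited
interior unit's exonic segment becomes a new exon if its cryptic AG and
the GT at the start of the following unit are intact (otherwise: "no
cryptic site"); the repeats in between become intronic. The post-gain
model has one more exon and unchanged flanking exons, and the new intron
retains degenerate repeat copies — which the detector can still find.

## Pairwise identity/similarity

Needleman–Wunsch with affine gaps (Gotoh), PAM250, gap open 10 / extend
0.5, end gaps penalized; traceback tie-break diagonal → up → left, so
output is deterministic. Percent identity counts identical aligned
pairs, similarity counts pairs with positive substitution score, both
over the length of the shorter ungapped sequence. The exact conventions
inside the original MatGAT tables (denominator, gap costs) are not
recoverable, so comparisons against published percentages carry a ±2
percentage-point tolerance; the DP itself is verified against exhaustive
alignment enumeration for short peptides and against an independent
aligner's optimal scores.

## Synthetic data

Generators are pure functions of (spec, seed) — bit-identical reruns —
and each emits a truth record (planted unit intervals, identities,
signal states, event logs).

* **Mirage genes**: every unit is an independently mutated copy
  (substitutions only, no indels, uniform base background) of one
  template carrying the canonical dinucleotides (AG closing the intronic
  segment, GT opening it), split 60% intronic / 40% exonic — the split
  point within real 150–160 bp units is not documented, so this choice
  is fixed here. The authentic junction's signals are restored after
  mutation; an optional knockout list destroys chosen units' signals
  ("many, but not all" units carry them). Presets: a 6×155 bp
  acceptor-side cluster (haplotype 1), a 3×155 bp sibling (haplotype 2),
  and a 2×157 bp donor-side cluster. Divergence defaults (8%, 5%) place
  pairwise unit identities inside the observed 81–100% band. What these
  fixtures do *not* emulate: unit length variation (±5 bp indels are out
  of scope in v1), codon structure of exonic flanks, and assembly
  artifacts; a green detection test therefore establishes operator
  correctness on substitution-diverged tandem arrays, not robustness to
  indel-riddled repeats.
* **Haplotype pairs**: substitutions at uniform positions with
  replacement residues weighted 2^PAM250-score (conservative exchanges
  dominate), divergence capped at 10%, realized identity reported by
  direct comparison — matching the ≥95% allelic band of the catalog.
* **Intron characters**: two-state Markov process (gain 0→1, loss 1→0)
  run branch-by-branch on a rooted binary tree with per-event logging;
  a deterministic mode plants exactly one gain on a chosen clade's stem.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally; GFF3 I/O converts to
1-based inclusive; minus-strand genes keep forward-strand exon intervals
and reverse traversal in CDS order. Catalog percentages print with one
decimal; the loader preserves leading comment lines so the packaged
fixture round-trips byte-identically. Empty catalogs summarize to zero
counts; an empty presence matrix yields an empty summary; an all-absent
character costs one loss under `loss_only` and zero gains under
`gain_only`. NJ requires a symmetric, zero-diagonal, non-negative matrix
and ≥3 labels. Alignment rejects empty sequences and names the position
of an illegal character.

## Known limitations

No probabilistic ancestral reconstruction; no genome-wide repeat
scanning (only windows around annotated junctions); no nucleotide mode
in the protein pairwise module; no BLAST-style homology search, external
phylogeny inference, or localization prediction — those stages run on
off-the-shelf tools and are outside this package's scope. GenBank
accession download is deliberately not a library function; all tests run
from generated or packaged text fixtures.
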