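# Methods

This note records the models, conventions, and numerical choices behind
fishkit, in the order data flows through the package.

## Coordinates and conventions

All genomic coordinates are 0-based, half-open (BED convention);
1-based inputs are converted at the reading boundary
(`convert_database(..., one_based=True)`). Probe size is the half-open
covered span, end of the last oligo minus start of the first, so a
single k-mer "probe" has size k and n abutting k-mers have size nk.
All outputs are sorted by (chromosome lexicographic, start) and every
operation is deterministic for fixed inputs and seeds.

## Oligo database pipeline (`seqdb`)

Stage order: unique k-mers → composition → homology → secondary
structure → Tm window → greedy non-overlap → off-target flagging.

* **Uniqueness** counts k-mers canonically by default (a k-mer and its
  reverse complement are the same species), because hybridization is
  strand-agnostic; `canonical=False` restores forward-only counting.
  k-mers containing N are excluded outright.
* **Composition**: longest homopolymer run ≤ 6 (runs of 7+ rejected)
  and GC fraction within [0.35, 0.80], both bounds inclusive.
* **Homology**: brute-force ungapped scan of both strands; a site
  counts when at least ⌈0.70·k⌉ of k positions match, and a candidate
  is dropped when more than one site exists (its own locus is one).
  Gapped alignment is deliberately out of scope; the scan is a
  pluggable surface should an external aligner be wanted. The scan is
  vectorised as a one-hot match-count matrix product in float32,
  chunked to bound memory, which keeps multi-10-kb genomes in the
  seconds range on one core.
* **Secondary structure**: candidates whose most stable hairpin has
  ΔG < 0 at 65 °C (the hybridization temperature) are dropped; ΔG = 0
  (no stabilizing fold) is retained.
* **Tm window**: the reference temperature is the mean Tm of the
  *post-composition* survivors — the stage where the mean is first
  computable with the fewest confounders — and candidates farther than
  ±10 °C from it are dropped later in the pipeline.
  `filter_tm_window` defaults to the mean of whatever set it is given
  when no reference is passed.
* **Non-overlap**: greedy left-to-right sweep; keep the first
  candidate, then every candidate starting at or beyond the end of the
  last kept one. Unsorted input is a contract violation and raises.
* **Off-targets**: sites at Hamming distance 1–5 on either strand are
  counted; more than 10 flags the oligo. Flagged oligos are retained
  with a boolean column so queries can include or exclude them.

Databases persist as a directory holding a headered `oligos.tsv` plus
`meta.json` (k, genome id, parameters, per-stage survivor counts):
diff-able, streaming-friendly, language-agnostic.

`database_stats` tiles the genome in non-overlapping windows; an oligo
counts for every window it overlaps even partially. The per-window gap
standard deviation uses the population convention (ddof = 0); windows
with fewer than two overlapping oligos contribute no gap s.d. and are
excluded from the median. Coverage is total oligo bases over genome
bases (oligos are non-overlapping, so base masking and summing lengths
agree).

## Thermodynamics (`thermo`)

Melting temperatures and dimer/hairpin free energies use a unified
nearest-neighbor ΔH/ΔS table (the standard unified DNA/DNA parameter
set) shipped as a packaged TSV and fully overridable. Tm combines
summed stack terms, per-end duplex initiation terms, an entropic
monovalent-salt correction (0.368·(n−1)·ln[Na⁺] cal/mol/K), and the
usual CT/4 strand-concentration term. Defaults: [Na⁺] = 50 mM, total
oligo concentration 0.25 M. The 0.25 M default is kept for consistency
with the filter thresholds used throughout (they were calibrated
against energies computed at that nominal value), although a quarter
molar oligo solution is not physically realistic; both concentrations
are parameters.

Dimer ΔG uses a deliberately reduced model: over every ungapped
antiparallel offset of the two strands, the single longest contiguous
Watson–Crick run is scored (stacks + initiation + salt entropy), and
the minimum over offsets is returned; no mismatch, bulge, or
dangling-end terms. 0.0 is the "no structure" sentinel and values are
clamped non-positive. For hetero-dimers the partner's reverse
complement is also considered (in a PCR pool both strands of the other
species exist); self-dimerization scores the oligo only against copies
of itself — an oligo and its perfect complement form the intended
product duplex, not a dimer artifact. At 37 °C every stack in the
shipped table is stabilizing, so the longest-run choice is provably
optimal among sub-runs; at higher temperatures weak stacks can turn
positive and the longest run is simply the model's definition.

Hairpins enumerate every contiguous stem (≥ 2 pairs) closing a loop of
≥ 3 nt; ΔG is the stem stack sum (salt-corrected, no duplex
initiation) plus a tabulated loop penalty. Loop penalties are ΔG at
37 °C with Jacobson–Stockmayer extrapolation beyond the table and are
scaled entropically (∝ absolute temperature) to other temperatures.
Filter semantics (signs and thresholds), not parity with any particular
folding program, are the contract.

## Probe design (`design`, `spotting`)

Candidates are windows of N consecutive database oligos fully inside
the region. Homogeneity uses the normalizer *outside* the square root:
σ_d = √(Σ(d_i − μ_d)²)/(N−1) over the N−1 gaps, H_p = 1/σ_d. This is
not the conventional sample standard deviation; it is implemented this
way by design, and `sd_convention="sample"` switches to the
conventional form. Zero spread (equal gaps, or a single gap) gives an
∞ sentinel that outranks every finite value; among several ∞
candidates the next feature breaks ties.

Ranking: the best value of the first feature (min for size, max for
centrality/homogeneity) defines a relative band — value ≤ best·(1+r)
when minimizing, ≥ best·(1−r) when maximizing, and exactly {∞} when
the best is the sentinel. Survivors are sorted by the second feature,
ties broken by the third, then by genomic start. The default tolerance
r = 0.1 is a package choice (the band width is inherently
user-tunable). The probe midpoint is computed from the covered span,
not the mean of oligo midpoints.

Spotting splits the region into M+1 equal windows (floor-rounded), runs
the single-probe designer on the first M, then shifts the window frame
by `shift_fraction·w` (default 0.1, a package choice) until the
cumulative shift reaches one window. A shift in which any window is
infeasible is discarded whole — the set score presupposes exactly M
probes. σ_S over probe sizes mirrors the printed σ_D form
(normalizer M−1 outside the root, mean over the M sizes). Ties between
shifts go to the smaller shift index for stability. M = 1 degenerates
to a single-probe design with the sentinel score.

## Adapters (`adapters`)

20-mer substrings of an orthogonal pool are filtered by genome homology
(discard at ≥ 16/20 matches anywhere, either strand) and self-dimer
ΔG ≤ −5 kcal/mol (boundary discards). The compatibility graph joins
pairs with hetero-dimer ΔG ≥ −9 kcal/mol, taking the minimum over the
partner and its reverse complement. Dimer temperature defaults to
37 °C (buffer conditions fix the salt, not the temperature; it is a
flag). The maximum clique is found by a deterministic branch-and-bound
with greedy-coloring upper bounds for graphs of up to `exact_limit`
(default 64) nodes, with ties resolved to the lexicographically
smallest node-index set via a feasibility-guided reconstruction; larger
graphs fall back to a degeneracy-ordered greedy heuristic and the
result is flagged as such. Scale, not semantics, is what a parallel
solver would add.

## Assembly (`assembly`)

Probe oligos are C+F+T+R (20/20/40/20 nt, configurable). The stored
oligo is the array-synthesized sense: T equals the database 40-mer on
the genome forward strand. Forward PCR primer = C∥F; reverse PCR
primer = T7 promoter ∥ revcomp(R); RT primer = C; per-oligo qPCR
forward primer = revcomp(T[0:20]). The default T7 promoter is the
standard minimal `TAATACGACTCACTATAG` and is configurable. (F, R)
combinations are consumed in pool order, so assignments are injective
and reproducible. Pool arithmetic: a pool of P oligos holds ⌊P/n⌋
probes of n oligos; drop-out rate is 100·failed/(probes·n) percent.

## Spatial statistics (`spatial`)

Dot tables carry (nucleus_id, label, x, y, z) with one consistent
length unit per table; anisotropic z can be handled by scaling
coordinates before analysis. Nuclei enter a pairwise analysis only when
each label's count is within ±30% (inclusive) of probes × ploidy
(2 for G1 diploid); the clustering analyses use ±20%.

* **Mixing index**: the grid is anchored at the minimum corner of the
  pair's joint bounding box (an explicit choice — the anchoring is
  otherwise underdetermined — making results deterministic); cube index
  = ⌊(coord − min)/side⌋ with max-boundary dots assigned to the last
  cube. Index = cubes with both labels / cubes with any dot.
* **Neighbor index**: per direction, the fraction of dots whose nearest
  neighbor among all dots of the pair (self excluded) is heterologous.
  Exact distance ties break toward homologous, which deflates apparent
  intermingling — the conservative direction.
* **Territory clustering**: k-means with k = 2 (10 restarts, fixed
  seed) unless the GAP statistic prefers k = 1. GAP uses uniform
  references over the axis-aligned bounding box (default B = 100) and
  the one-standard-error rule Gap(1) ≥ Gap(2) − s(2). Identical
  coordinates short-circuit to one cluster. Silhouette uses the
  standard per-dot definition with singleton clusters scoring 0; a
  single cluster returns NaN.
* **Territory volumes**: dots farther than 1300 nm (length units of the
  table) from every other dot are pruned; after clustering, every
  non-empty channel subset whose per-channel count is within ±30% of
  the expectation yields the convex-hull volume of its dots. Fewer than
  4 points, or coplanar points, give volume 0. The per-territory
  expectation is probes × ploidy_factor with ploidy_factor = 1 for one
  territory of a G1 diploid cell (the per-cell expectation of 2 splits
  across the two territories).

## Synthetic data (`fixtures`)

Generators emulate the *geometry* of the real inputs, not their
biology: genomes are iid base draws at a target GC (no repeat
structure, no isochores), databases place oligos at constant or
gamma-jittered gaps (no filter-induced gap clustering), dot clouds are
isotropic Gaussians (real territories are neither Gaussian nor
isotropic, and real images add detection noise and misses), and adapter
pools are random 20-mers with a rejection-sampled mutually compatible
subset plus planted cross-complementary decoys. Passing tests therefore
demonstrate algorithmic correctness — scoring, ranking, filtering,
clique search, spatial indices — on inputs with known ground truth;
they do not certify hybridization performance on real genomes. Every
generator is a pure function of its arguments including the seed.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale inputs
chosen as the smallest sizes that still exercise every code path with
non-trivial combinatorics: genomes of 12–34 kb, databases of 100–500
oligos, clique graphs of ≤ 15 nodes for brute-force comparison, and
50–100 seeded replicates for stochastic expectations. Genome-scale
database construction (tens of millions of oligos) is out of scope for
this implementation's brute-force homology scan, which is quadratic in
genome length.

## Known limitations

* Dimer/hairpin energetics ignore mismatches, bulges, dangling ends,
  coaxial stacking, and divalent cations; only signs and thresholds are
  contractual.
* The homology scan is ungapped; indel-containing near-matches are
  invisible to it (and to the Hamming-distance off-target counter).
* The GAP decision is limited to k ∈ {1, 2}: territories of higher
  multiplicity (aneuploid or S/G2 cells) are out of scope.
* The mixing index depends on cube side and dot density; values are
  comparable only within a fixed acquisition setting.
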