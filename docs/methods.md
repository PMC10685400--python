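# Methods

This note records the models and procedures implemented in `stabiliforge`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic generators do and do not emulate.

## Conventions

* **ΔΔG sign.** Negative = stabilizing, kcal/mol, throughout. All
  thresholds are inclusive (≤): a mutation scoring exactly −1.0 passes a
  −1.0 threshold. The published defaults only make sense under this
  convention, and inclusivity keeps the advertised threshold values usable.
* **Numbering.** Mutations are reported in query numbering with the PDB's
  author residue numbers taken as authoritative; alignment columns are
  translated through the query row's column→position map (columns gapped in
  the query have no position). The pipeline assumes structure numbering
  coincides with query numbering; renumber beforehand if it does not.
* **Mutation notation.** `<chain>/<wt><position><mut>`, chain omissible
  when unambiguous. The notation is this package's own convention.
* **Structure reading.** Standard amino-acid ATOM records only; waters and
  heteroatoms dropped; selenomethionine renamed to MET; highest-occupancy
  alternate locations kept (standard practice; the source protocol is
  silent on altlocs). B-factors are preserved as read.

## Homolog curation

Identity is computed from a global Needleman–Wunsch alignment (BLOSUM62,
affine gaps, open 10 / extend 0.5 — conventional protein defaults) as
identical columns divided by aligned columns excluding terminal-gap
overhangs; `X` never counts as a match. The pair is canonically ordered
before aligning so the measure is exactly symmetric under tie-broken
optimal alignments. Query coverage is the fraction of query positions
aligned to a subject residue in the same alignment. BLAST-style local
identities would differ slightly; global identity was chosen because no
search program runs inside the package, and it is exposed in the API.

The identity window (0.30–0.90) is **inclusive** at both ends: the
protocol's wording ("outside the thresholds are excluded") leaves the
boundary ambiguous, and inclusive bounds keep the advertised threshold
values themselves usable. Clustering is the greedy length-sorted pass of
UCLUST-style clustering with exact pairwise identities (no word-index
heuristics): descending length, ties by input order; a sequence joins the
first representative at ≥ 90% identity. Representatives are sorted by
coverage (desc), identity (desc), then id, and truncated to 200 — the cap
that keeps downstream alignment and correlation costs bounded.

## Conservation

Per column: JSD between the column's gap-free amino-acid frequency
distribution and the BLOSUM62 background frequencies (the customary
background for this score; the choice is configurable), log base 2 so the
score lies in [0, 1]. The raw score is multiplied by (1 − gap fraction) —
gappy columns are unreliable — and smoothed with a ±3-column window at
weight 0.5 (the cited conservation methodology's defaults; both exposed).
Grades discretise rank: grade = min(9, ⌊10 · fraction of columns with
strictly greater score⌋), so the most conserved column gets grade 0 and
ties share grades. The filter treats grade ≤ 4 as conserved. The source
protocol does not state its grade scale; strict-rank deciles with
low-=-conserved orientation reproduce the stated filter semantics and the
orientation is configurable.

## Correlated positions

Four statistics ship with the package, all over sequences non-gapped at
both columns of a pair:

* **MI** — mutual information in bits from joint frequency counts;
* **aMIc** — MI after average-product correction
  (out(i,j) = in(i,j) − mean_i·mean_j/mean_all over off-diagonal entries);
  the protocol cites a corrected-MI variant without defining it, and APC is
  implemented here without claiming equivalence;
* **OMES** — Σ (N_obs − N_exp)²/N over residue-pair cells;
* **McBASC** — Pearson correlation of McLachlan substitution scores over
  all sequence pairs, zero for zero-variance columns.

DCA/SCA/ELSC-style methods are plugin slots: any callable MSA → symmetric
matrix registered by name participates in the consensus. Because the
methods' scales are incommensurable and no per-method cutoffs are
published, each method flags its **top 1%** of off-diagonal pairs by score
(ties at the cutoff all kept; non-positive scores never flagged — an
all-zero matrix abstains). A pair's consensus is its number of flagging
methods; the published decision threshold 3.5 presumes a seven-method
panel, so with k methods it rescales to 3.5·k/7, keeping the default
meaningful. Equal method weights are assumed. Any position in a pair at or
above threshold is excluded from mutagenesis.

Pairs with fewer than two jointly non-gapped sequences score 0.

## Structure features

* **Distances**: minimal heavy-atom distance between residues is the
  default metric for the 10 Å pair rule (Cα and Cβ variants are exposed;
  the protocol does not define its metric and minimal heavy-atom distance
  is the most permissive reading of "within range").
* **SASA**: Shrake–Rupley sampling (960 deterministic Fibonacci points per
  atom, probe 1.4 Å, single-atom van der Waals radii; biotite backend).
  Relative SASA divides by the residue type's theoretical maximum (Tien et
  al. 2013); surface = relative SASA ≥ 0.25, a common burial threshold —
  the protocol never quantifies "surface". Unknown elements fall back to a
  carbon-like 1.8 Å radius with a warning.
* **Flexibility**: per-residue mean of atomic B-factors, z-scores across
  residues, ranking by descending mean with ties to the lower residue
  number. Both a fixed count (`top_n`) and a z-score cutoff (`z_min`) are
  exposed because the protocol does not state which selector its B-factor
  analysis uses. No cross-crystal normalization is attempted.

## Candidate generation and filters

* **Saturation**: 19 substitutions per position.
* **Back-to-consensus**: column frequencies exclude gaps from the
  denominator by default (`count_gaps` switches to the literal
  all-sequences reading; gap-rich columns otherwise can never reach 50%).
  Majority: freq(consensus) ≥ 0.50. Ratio: freq(consensus) ≥ 0.40 and
  ≥ 5 × freq(wild type) — compared as frequencies (identical to counts
  under a fixed denominator). Both comparisons inclusive. One candidate per
  position at most.
* **Ancestral**: each precomputed ancestral sequence (tree inference and
  reconstruction are out of scope; sequences are consumed as FASTA) is
  globally aligned to the query; substitutions at mutually non-gapped
  columns are reported in query numbering, insertions/deletions ignored.
  A substitution is kept when it recurs in ≥ 2 node sequences — mutations
  near the root are numerous and individually unreliable.
* **Filters** run in a fixed order — essential → conserved → correlated →
  msa-presence → charge-surface — and a rejected candidate records the
  first failing filter. The first three are position-level and always
  active; the last two are mutation-level and active only in the low-risk
  scenario. Charge classes: K/R positive, D/E negative, everything else
  (including histidine, at the pH 7 operating point) neutral. Essential
  residues come from a user-supplied `chain/position` list; database
  lookups are out of scope.

## Energy evaluation

Evaluators expose `single(mutation)` and `pair(mutation_a, mutation_b)`,
must be deterministic, and refuse same-position pairs.

* **TableEvaluator** adapts exported ΔΔG tables (plain TSV, PSSM-style
  grids, report-style rows; duplicate entries averaged with a warning).
  Missing singles raise; missing pairs fall back to additivity and are
  counted.
* **SurrogateEvaluator** is this package's own desk-scale potential — not
  a force field. Single ΔΔG = Σ over neighbours within 6.5 Å (side-chain
  reference point Cβ, Cα for glycine) of
  [e(mut, nb) − e(wt, nb) + packing_penalty] + noise, with
  e(a,b) = −0.1·(h(a) + h(b)) a hydrophobic-burial contact potential on
  Kyte–Doolittle hydropathies h. The per-contact packing penalty
  (0.3 kcal/mol) encodes that the wild type is locally near-optimal: with
  it, the surrogate's ΔΔG distribution has mean ≈ +1 kcal/mol and a
  single-digit-percent stabilizing tail, matching the empirically observed
  predominance of destabilizing mutations; without it half of all
  substitutions would look stabilizing and the clique stage would face
  astronomically many equivalent designs. Noise (amplitude 0.2 kcal/mol,
  hashed by CRC32 from seed/chain/position/wt/mut, so bit-stable across
  runs and platforms) keeps toy landscapes non-degenerate without flipping
  designed signs. Pair ΔΔG = sum of singles, plus the coupling term
  e(mut_a, mut_b) − e(wt_a, wt_b) when the sites are in contact — exactly
  additive otherwise. A site with no neighbours and zero noise scores
  exactly 0.
* **Stages**: stage 1 at −1.0 kcal/mol, stage 2 (evaluated lazily, only
  for stage-1 survivors) at −1.5 kcal/mol; both energies recorded on the
  candidate. Consensus candidates are checked at +0.5 kcal/mol — they are
  trusted evolutionarily, so only clearly destabilizing ones are removed.
  One published restatement of the second-stage threshold carries a
  positive sign; the signed −1.5 is used, as a positive stabilization
  threshold would contradict the sign convention. Structure
  repair/minimization before evaluation is out of scope: evaluators see
  the input structure as-is.

## Multiple-point design

Pairs of accepted singles at distinct positions within 10 Å are evaluated
explicitly; beyond 10 Å they are additive. Unevaluable pairs drop their
edge (no unverified co-occurrence). The antagonism rule removes edges with
ΔΔG(pair) > min(ΔΔG_a, ΔΔG_b). Maximal cliques are enumerated with
Bron–Kerbosch with Tomita pivoting (deterministic node ordering; isolated
nodes yield singleton cliques); beyond 25 accepted mutations a warning is
logged — the worst case is exponential and deliberately not mitigated.
The design is the clique minimizing the sum of single ΔΔG values: "best
evaluation of individual mutations" is read as the singles sum, keeping
selection independent of pair magnitudes (pair energies only decide edge
existence). Ties prefer the larger clique, then the lexicographically
smallest position list (the tie-break is this package's own, the protocol
being silent). When all singles are stabilizing, the optimum over all
valid subsets is attained at a maximal clique, so restricting selection to
maximal cliques loses nothing.

Combined designs re-run the construction on the union of the energy- and
evolution-design mutation sets; same-position conflicts keep the more
stabilizing single. Because evaluators are deterministic, re-evaluating
intra-pool pairs is equivalent to reusing them. The low-/high-risk design
pair differs only in the candidate pool (the mutation-level filters), not
in any graph parameter. The ancestral result is reported as a single-point
list, not a clique-selected design; for the mutant sequence one mutation
per position is kept (most recurrent first).

## Validation metrics

A mutation is experimentally stabilizing when its measured ΔΔG < 0
(strictly; 0 counts as not stabilizing) and predicted stabilizing when the
prediction ≤ a decision threshold (0 by default; moving it to the cascade
thresholds reproduces stricter operating points). Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), FDR = FP/(TP+FP) with FDR ≔ 0 when nothing is
predicted positive — operating points that predict nothing (FP = 0) stay
well-defined. Metrics are reported to 3 decimals. One published benchmark
row is internally inconsistent (its counts sum to 862, not 861, and its
printed sensitivity implies a different FN); only its self-consistent
cells (specificity, FDR) are checked.

## Synthetic data

The generators provide ground-truth fixtures, sized so the full test suite
and the acceptance run finish in seconds:

* **Structures**: ideal α-helix (rise 1.5 Å, twist 100°, radius 2.28 Å so
  consecutive Cα sit 3.8 Å apart) with approximate N/C/O placement and Cβ
  stubs; per-residue log-normal B-factors (median 20, σ = 0.3 in log
  space, typical of mid-resolution crystal structures) with an optional
  engineered flexible residue (B = 80). An occlusion shell of dummy atoms
  creates a guaranteed buried residue for SASA tests.
* **Alignments**: background columns each carry a dominant residue at a
  frequency drawn from U(0.3, 0.6) with BLOSUM62-background noise —
  uniform 20-letter columns would be unrealistically diverse and would
  drown coupling signals in finite-sample mutual-information noise.
  Planted directives: invariant columns, consensus residues at exact
  frequencies, bijectively coupled column pairs (8 symbols), optional gaps.
* **Landscapes**: explicit single ΔΔG values with pair overrides
  (antagonistic or synergistic); unoverridden pairs are exactly additive
  and placed outside the pair radius, overridden pairs inside it.

What the generators do **not** emulate: phylogenetic correlation between
sequences (every row is sampled independently given the column model), real
side-chain packing, loops/sheets and multi-domain topology, crystallographic
artefacts in B-factors, and genuine epistatic physics. Passing tests
therefore demonstrate the correctness of the rules, filters and graph
algorithms on known ground truth — not predictive accuracy on real
proteins, which depends on the external energy tables fed to the adapters.

## Known limitations

* No force-field execution, structure repair, homology modelling, tree
  inference or database search: those stages are consumed through file
  adapters or are out of scope by design.
* Clique enumeration is exact and exponential in the worst case; pools
  beyond ~25 accepted mutations warn rather than approximate.
* The surrogate potential ranks hydrophobic-burial effects only; it is a
  test and demonstration instrument, not a predictor.
* Sequence weighting (phylogenetic downweighting of redundant homologs) is
  not applied in the column statistics; the 90% clustering step is the only
  redundancy control.
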