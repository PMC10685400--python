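# stabiliforge

Automated design of thermostable multiple-point protein mutants.

Single stabilizing point mutations rarely add more than a degree or two of
melting temperature, but combining them blindly is risky: pairs of
individually stabilizing mutations can interact antagonistically and a
multi-mutant can end up worse than its best member. `stabiliforge`
implements the computational core of the automated design protocol that
addresses this: annotate the target protein, propose stabilizing
single-point mutations through several independent strategies, filter out
everything functionally risky, and then combine the survivors into
multiple-point designs whose pairwise compatibility has been checked
explicitly.

## Who this is for

Protein engineers and structural bioinformaticians who have a structure
(PDB), a homolog alignment and — optionally — exported force-field ΔΔG
tables or precomputed ancestral sequences, and who want reproducible
mutation designs with every filter decision recorded.

## Method

**Annotation.** Homologs are curated by a global-identity window (30–90%
by default, inclusive), clustered greedily at 90% identity and capped at
200 coverage-sorted representatives. From the alignment, each column gets

* a conservation score: Jensen–Shannon divergence of its amino-acid
  distribution *p* from the BLOSUM62 background *q*,
  JSD(p‖q) = ½·KL(p‖r) + ½·KL(q‖r) with r = (p+q)/2 (log base 2),
  gap-penalised and window-smoothed, discretised to decile grades 0–9
  (grade 0 = most conserved);
* correlation calls: a consensus over coevolution statistics (MI, its
  average-product-corrected variant, OMES, McBASC; more methods plug in by
  name). Each method flags its top 1% of column pairs; a pair flagged by
  ≥ 3.5·(k/7) of k methods marks both columns as correlated.

From the structure: per-residue minimal heavy-atom distances, Shrake–Rupley
solvent accessibility (surface = relative SASA ≥ 0.25) and per-residue
average B-factors (flexibility ranking for rigidifying saturation targets).

**Single-point candidates.** Three branches: (i) saturation mutagenesis
scored by a two-stage energy cascade (stage 1 keeps ΔΔG ≤ −1.0 kcal/mol,
stage 2 re-scores survivors and keeps ΔΔG ≤ −1.5 kcal/mol; negative =
stabilizing); (ii) back-to-consensus — the column consensus residue c
replaces the wild type w when freq(c) ≥ 0.50 (*majority*) or freq(c) ≥ 0.40
with freq(c) ≥ 5·freq(w) (*ratio*), kept unless clearly destabilizing
(ΔΔG > +0.5 kcal/mol); (iii) substitutions recurring in ≥ 2 precomputed
ancestral sequences. Position filters (essential, conservation grade ≤ 4,
correlated) apply everywhere; the *low-risk* scenario additionally requires
the mutant residue to occur in the alignment column and forbids
charge-changing mutations on the surface, while the *high-risk* scenario
skips those two checks.

**Multiple-point designs.** Accepted singles become nodes of a graph
weighted by ΔΔG. Pairs of mutations within 10 Å (minimal heavy-atom
distance) are evaluated explicitly; pairs beyond are additive. An edge
survives only if ΔΔG(pair) ≤ min(ΔΔG_a, ΔΔG_b) — the antagonism rule.
Maximal cliques are enumerated with Bron–Kerbosch (with pivoting) and the
clique with the most stabilizing sum of single ΔΔG values is the design.
Repeating the construction on the union of the energy- and evolution-based
designs yields the combined designs.

Energy values come from any *evaluator* — exported FoldX-/Rosetta-style
tables via `TableEvaluator`, or the built-in deterministic surrogate
potential for desk-scale runs and testing (no force-field software is ever
executed).

## Worked example

Everything below is generated in memory — an ideal 40-residue helix with
seeded B-factors and a 30-sequence synthetic alignment with planted
consensus columns:

```python
import stabiliforge as sf
from stabiliforge.synthetic import synth_structure, synth_msa

structure = synth_structure(40, seed=7)
query = structure.sequence("A")
msa = synth_msa(query, depth=30, conserved_positions=[5, 6],
                consensus_injections={10: ("S", 0.45), 24: ("T", 0.45),
                                      33: ("E", 0.45)},
                seed=3, gap_rate=0.05)
evaluator = sf.surrogate_evaluator(structure, seed=7)
result = sf.run_automated_design(structure, msa, evaluator)
for name in ("energy-low", "energy-high", "evolution",
             "combined-low", "combined-high"):
    d = result.designs[name]
    muts = ", ".join(str(m) for m in d.mutations) or "(wild type)"
    print(f"{name:14s} {d.size} mutation(s)  total ddG {d.total_score:+.2f}  {muts}")
```

prints

```
energy-low     3 mutation(s)  total ddG -6.07  A/H10I, A/N31L, A/N32I
energy-high    5 mutation(s)  total ddG -10.35  A/H10I, A/D17V, A/D19I, A/N31I, A/N32I
evolution      1 mutation(s)  total ddG +0.42  A/H10S
combined-low   3 mutation(s)  total ddG -6.07  A/H10I, A/N31L, A/N32I
combined-high  5 mutation(s)  total ddG -10.35  A/H10I, A/D17V, A/D19I, A/N31I, A/N32I
```

Reading this: the low-risk energy design keeps three mutations that pass
every filter and are pairwise non-antagonistic (total predicted
stabilization −6.07 kcal/mol); the high-risk design adds two
charge-removing substitutions (D17V, D19I) that the low-risk surface-charge
filter rejects. The evolution branch proposes the consensus substitution
H10S (+0.42 kcal/mol is within the +0.5 tolerance for evolutionarily
supported mutations); in the combined designs the same-position conflict
with the more stabilizing H10I is resolved in favour of the energy
candidate. `A/H10I` means: chain A, position 10, His → Ile.

The same run is available from the shell:

```bash
stabiliforge design --pdb protein.pdb --msa aln.fasta --query QUERY_ID \
    --surrogate-seed 7 -o designs/
```

which writes `designs.fasta`, `designs.csv` and `designs.json` (mutant
sequences, one row per mutation with its ΔΔG and source, full provenance).

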