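"""Combination of single-point mutations into multiple-point designs.

The central algorithm: accepted single mutations become nodes of a
compatibility graph weighted by their ddG.  Every unordered pair at
distinct positions gets a pair ddG — evaluated explicitly when the two
wild-type residues lie within 10 A of each other, assumed additive beyond.
*Antagonistic* edges, where the pair is worse than the more stabilizing of
the two singles (ddG_pair > min(ddG_a, ddG_b)), are removed.  Maximal
cliques of the remaining graph are enumerated with Bron-Kerbosch (with
pivoting) and the clique with the most stabilizing sum of single ddGs is
the design.  Repeating the procedure on the union of the energy- and
evolution-based designs yields the combined designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .energy_engine import EnergyEvaluator
from .formats_io import Mutation, ResidueId, StructureModel
from .structure_features import residue_min_distance

logger = logging.getLogger(__name__)

SCENARIOS = ("energy-low", "energy-high", "evolution",
             "combined-low", "combined-high", "ancestral")

PAIR_RADIUS = 10.0  # A; explicit pair evaluation within, additivity beyond


@dataclass(frozen=True)
class PairEnergy:
    """Unordered mutation pair with its distance and combined ddG."""

    mutation_a: Mutation
    mutation_b: Mutation
    distance: float
    ddg_pair: float | None
    additive: bool = False
    unevaluated: bool = False

    @property
    def key(self) -> frozenset:
        return frozenset((self.mutation_a, self.mutation_b))


@dataclass
class DesignGraph:
    """Nodes: accepted singles with ddG; edges: non-antagonistic pairs."""

    singles: dict[Mutation, float]
    edges: dict[frozenset, PairEnergy] = field(default_factory=dict)

    def neighbours(self, m: Mutation) -> set[Mutation]:
        out = set()
        for key in self.edges:
            if m in key:
                (other,) = key - {m}
                out.add(other)
        return out

    def has_edge(self, a: Mutation, b: Mutation) -> bool:
        return frozenset((a, b)) in self.edges


@dataclass
class StabilityDesign:
    """A selected mutation set with its score, scenario and sequence."""

    scenario: str
    mutations: tuple[Mutation, ...]
    single_ddgs: dict[Mutation, float]
    total_score: float
    mutant_sequence: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.mutations)


# ---------------------------------------------------------------------------
# Pair evaluation
# ---------------------------------------------------------------------------

def _structure_distance(
    structure: StructureModel, a: Mutation, b: Mutation, metric: str
) -> float:
    def rid(m: Mutation) -> ResidueId:
        for r in structure.residue_ids:
            if r.chain == m.chain and r.number == m.position:
                return r
        raise KeyError(f"structure has no residue {m.chain}/{m.position}")

    return residue_min_distance(structure, rid(a), rid(b), metric=metric)


def build_pair_set(
    singles: Mapping[Mutation, float],
    evaluator: EnergyEvaluator,
    structure: StructureModel | None = None,
    radius: float = PAIR_RADIUS,
    distance_metric: str = "min_heavy",
    distance_lookup: Callable[[Mutation, Mutation], float] | None = None,
) -> list[PairEnergy]:
    """Pair ddGs for all unordered mutation pairs at distinct positions.

    Pairs within ``radius`` Angstrom are evaluated by the evaluator; pairs
    beyond are additive (sum of singles).  Distances come from the
    structure's wild-type residues or from an explicit ``distance_lookup``.
    Evaluator failures mark the pair unevaluated (its edge is later dropped
    conservatively).
    """
    if distance_lookup is None:
        if structure is None:
            raise ValueError("need a structure or a distance_lookup")

        def distance_lookup(a: Mutation, b: Mutation) -> float:
            return _structure_distance(structure, a, b, distance_metric)

    muts = sorted(singles, key=lambda m: (m.chain, m.position, m.mut))
    out: list[PairEnergy] = []
    for i, a in enumerate(muts):
        for b in muts[i + 1:]:
            if (a.chain, a.position) == (b.chain, b.position):
                continue  # mutually exclusive alternatives, never paired
            d = float(distance_lookup(a, b))
            if d > radius:
                out.append(PairEnergy(a, b, d, singles[a] + singles[b],
                                      additive=True))
                continue
            try:
                ddg = float(evaluator.pair(a, b))
            except Exception as exc:
                logger.warning("pair evaluation failed for %s + %s: %s",
                               a, b, exc)
                out.append(PairEnergy(a, b, d, None, unevaluated=True))
                continue
            out.append(PairEnergy(a, b, d, ddg))
    return out


def build_design_graph(
    singles: Mapping[Mutation, float],
    pair_energies: Iterable[PairEnergy],
) -> DesignGraph:
    """Keep only non-antagonistic edges.

    An edge survives iff ``ddg_pair <= min(ddg_a, ddg_b)`` — the pair must
    be at least as stabilizing as its better member.  Unevaluated pairs are
    dropped (no unverified co-occurrence).
    """
    graph = DesignGraph(singles=dict(singles))
    for pe in pair_energies:
        if pe.mutation_a not in graph.singles or pe.mutation_b not in graph.singles:
            raise KeyError(f"pair references unknown single: {pe.key}")
        if pe.unevaluated or pe.ddg_pair is None:
            continue
        best_single = min(graph.singles[pe.mutation_a],
                          graph.singles[pe.mutation_b])
        if pe.ddg_pair <= best_single:
            graph.edges[pe.key] = pe
    return graph


# ---------------------------------------------------------------------------
# Clique enumeration (Bron-Kerbosch with pivoting)
# ---------------------------------------------------------------------------

def enumerate_maximal_cliques(graph: DesignGraph) -> list[tuple[Mutation, ...]]:
    """All maximal cliques, deterministically ordered.

    Bron-Kerbosch with the Tomita pivot (the vertex of P U X with most
    neighbours in P).  Each clique is sorted by position; the clique list
    is sorted lexicographically.  Isolated nodes yield singleton cliques.
    """
    nodes = sorted(graph.singles, key=lambda m: (m.chain, m.position, m.mut))
    if not nodes:
        return []
    if len(nodes) > 25:
        logger.warning(
            "clique enumeration over %d accepted mutations; worst case is "
            "exponential", len(nodes),
        )
    adjacency: dict[Mutation, set[Mutation]] = {n: set() for n in nodes}
    for key in graph.edges:
        a, b = tuple(key)
        adjacency[a].add(b)
        adjacency[b].add(a)

    cliques: list[tuple[Mutation, ...]] = []

    def expand(r: set[Mutation], p: set[Mutation], x: set[Mutation]) -> None:
        if not p and not x:
            cliques.append(tuple(sorted(
                r, key=lambda m: (m.chain, m.position, m.mut)
            )))
            return
        pivot = max(p | x, key=lambda u: len(adjacency[u] & p))
        for v in sorted(p - adjacency[pivot],
                        key=lambda m: (m.chain, m.position, m.mut)):
            expand(r | {v}, p & adjacency[v], x & adjacency[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(nodes), set())
    return sorted(cliques)


# ---------------------------------------------------------------------------
# Design selection
# ---------------------------------------------------------------------------

def clique_score(clique: Iterable[Mutation],
                 singles: Mapping[Mutation, float]) -> float:
    return sum(singles[m] for m in clique)


def select_design(
    cliques: list[tuple[Mutation, ...]],
    singles: Mapping[Mutation, float],
    scenario: str,
    query_sequence: str | None = None,
) -> StabilityDesign:
    """Pick the most stabilizing clique.

    Minimizes the sum of single ddGs; ties prefer the larger clique, then
    the lexicographically smallest position list.  An empty clique list
    yields the wild-type design.
    """
    if not cliques:
        return StabilityDesign(
            scenario=scenario, mutations=(), single_ddgs={},
            total_score=0.0,
            mutant_sequence=query_sequence or "",
        )
    best = min(
        cliques,
        key=lambda c: (clique_score(c, singles), -len(c),
                       tuple((m.chain, m.position, m.mut) for m in c)),
    )
    design = StabilityDesign(
        scenario=scenario,
        mutations=tuple(best),
        single_ddgs={m: float(singles[m]) for m in best},
        total_score=float(clique_score(best, singles)),
    )
    if query_sequence is not None:
        design.mutant_sequence = mutant_sequence(query_sequence, design)
    return design


def design_from_singles(
    singles: Mapping[Mutation, float],
    evaluator: EnergyEvaluator,
    scenario: str,
    structure: StructureModel | None = None,
    radius: float = PAIR_RADIUS,
    distance_metric: str = "min_heavy",
    distance_lookup: Callable[[Mutation, Mutation], float] | None = None,
    query_sequence: str | None = None,
) -> StabilityDesign:
    """Full pass: pair set, antagonism pruning, cliques, selection."""
    if not singles:
        return StabilityDesign(scenario=scenario, mutations=(),
                               single_ddgs={}, total_score=0.0,
                               mutant_sequence=query_sequence or "")
    if len(singles) == 1:
        (m, ddg), = singles.items()
        design = StabilityDesign(scenario=scenario, mutations=(m,),
                                 single_ddgs={m: float(ddg)},
                                 total_score=float(ddg))
        if query_sequence is not None:
            design.mutant_sequence = mutant_sequence(query_sequence, design)
        return design
    pairs = build_pair_set(singles, evaluator, structure=structure,
                           radius=radius, distance_metric=distance_metric,
                           distance_lookup=distance_lookup)
    graph = build_design_graph(singles, pairs)
    cliques = enumerate_maximal_cliques(graph)
    return select_design(cliques, singles, scenario,
                         query_sequence=query_sequence)


def combined_design(
    energy_design: StabilityDesign,
    evolution_design: StabilityDesign,
    evaluator: EnergyEvaluator,
    structure: StructureModel | None = None,
    radius: float = PAIR_RADIUS,
    distance_metric: str = "min_heavy",
    distance_lookup: Callable[[Mutation, Mutation], float] | None = None,
    scenario: str = "combined-low",
    query_sequence: str | None = None,
) -> StabilityDesign:
    """Re-run the clique construction on the union of two designs.

    Same-position conflicts between the pools keep the more stabilizing
    single.  Pair energies across and within the union are (re-)evaluated
    under the same radius rule; the deterministic evaluators make reuse and
    re-evaluation equivalent.
    """
    union: dict[Mutation, float] = {}
    by_position: dict[tuple[str, int], Mutation] = {}
    for design in (energy_design, evolution_design):
        for m in design.mutations:
            ddg = design.single_ddgs[m]
            key = (m.chain, m.position)
            incumbent = by_position.get(key)
            if incumbent is None or ddg < union[incumbent]:
                if incumbent is not None:
                    del union[incumbent]
                by_position[key] = m
                union[m] = ddg
    return design_from_singles(
        union, evaluator, scenario, structure=structure, radius=radius,
        distance_metric=distance_metric, distance_lookup=distance_lookup,
        query_sequence=query_sequence,
    )


def mutant_sequence(query: str, design: StabilityDesign) -> str:
    """Apply a design's substitutions to the query sequence."""
    seq = list(query)
    for m in design.mutations:
        if not 1 <= m.position <= len(seq):
            raise ValueError(f"{m}: position outside the query sequence")
        if seq[m.position - 1] != m.wt:
            raise ValueError(
                f"{m}: query has {seq[m.position - 1]!r} at position "
                f"{m.position}, not {m.wt!r}"
            )
        seq[m.position - 1] = m.mut
    return "".join(seq)
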