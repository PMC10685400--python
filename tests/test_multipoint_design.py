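import itertools

import networkx as nx
import numpy as np
import pytest

from stabiliforge.formats_io import Mutation
from stabiliforge.multipoint_design import (
    DesignGraph,
    PairEnergy,
    build_design_graph,
    build_pair_set,
    combined_design,
    design_from_singles,
    enumerate_maximal_cliques,
    mutant_sequence,
    select_design,
)
from stabiliforge.synthetic import (
    LandscapeSpec,
    synth_landscape,
    synth_structure,
)

from .oracles import brute_force_maximal_cliques, exhaustive_best_design

AA = "ACDEFGHIKLMNPQRSTVWY"


def _muts(n, chain="A"):
    return [Mutation(chain, p, "A", "W") for p in range(1, n + 1)]


def _graph(n, edge_list, singles=None):
    muts = _muts(n)
    singles = singles or {m: -1.0 for m in muts}
    edges = {}
    for i, j in edge_list:
        pe = PairEnergy(muts[i], muts[j], 5.0, -5.0)
        edges[pe.key] = pe
    return muts, DesignGraph(singles=singles, edges=edges)


class TestPairSet:
    def test_radius_rule(self):
        muts = _muts(3)
        singles = {m: -1.0 for m in muts}
        dists = {(1, 2): 4.0, (1, 3): 12.0, (2, 3): 15.0}

        def lookup(a, b):
            return dists[tuple(sorted((a.position, b.position)))]

        class Ev:
            def pair(self, a, b):
                return -2.5

        pairs = build_pair_set(singles, Ev(), distance_lookup=lookup)
        evaluated = [p for p in pairs if not p.additive]
        additive = [p for p in pairs if p.additive]
        assert len(evaluated) == 1 and len(additive) == 2
        assert all(p.ddg_pair == -2.0 for p in additive)

    def test_same_position_pairs_not_generated(self):
        a = Mutation("A", 5, "A", "W")
        b = Mutation("A", 5, "A", "I")

        class Ev:
            def pair(self, x, y):  # pragma: no cover
                raise AssertionError("must not be called")

        pairs = build_pair_set({a: -1.0, b: -2.0}, Ev(),
                               distance_lookup=lambda x, y: 3.0)
        assert pairs == []

    def test_all_distant_gives_full_additive_set(self):
        muts = _muts(6)
        singles = {m: -1.0 for m in muts}
        pairs = build_pair_set(singles, object(),
                               distance_lookup=lambda a, b: 99.0)
        assert len(pairs) == 15
        assert all(p.additive for p in pairs)

    def test_evaluator_failure_drops_edge(self):
        muts = _muts(2)
        singles = {m: -1.0 for m in muts}

        class Broken:
            def pair(self, a, b):
                raise RuntimeError("boom")

        pairs = build_pair_set(singles, Broken(),
                               distance_lookup=lambda a, b: 3.0)
        assert pairs[0].unevaluated
        graph = build_design_graph(singles, pairs)
        assert graph.edges == {}

    def test_structure_distances(self):
        helix = synth_structure(20, seed=7)
        seq = helix.sequence()

        def other(wt):
            return "W" if wt != "W" else "I"

        a = Mutation("A", 1, seq[0], other(seq[0]))
        b = Mutation("A", 2, seq[1], other(seq[1]))
        c = Mutation("A", 15, seq[14], other(seq[14]))
        singles = {a: -1.0, b: -1.0, c: -1.0}

        class Ev:
            def pair(self, x, y):
                return -9.0

        pairs = build_pair_set(singles, Ev(), structure=helix, radius=10.0)
        by_key = {p.key: p for p in pairs}
        assert not by_key[frozenset((a, b))].additive  # adjacent residues
        assert by_key[frozenset((a, c))].additive  # 14 residues apart


class TestAntagonismRule:
    def test_edge_kept_when_pair_beats_best_single(self):
        a, b = _muts(2)
        singles = {a: -1.0, b: -2.0}
        pe = PairEnergy(a, b, 5.0, -2.5)
        graph = build_design_graph(singles, [pe])
        assert graph.has_edge(a, b)

    def test_antagonistic_edge_removed(self):
        a, b = _muts(2)
        singles = {a: -1.0, b: -2.0}
        pe = PairEnergy(a, b, 5.0, -1.8)
        graph = build_design_graph(singles, [pe])
        assert not graph.has_edge(a, b)

    def test_additive_stabilizing_landscape_complete_graph(self):
        muts = _muts(6)
        singles = {m: float(v) for m, v in
                   zip(muts, [-0.5, -1.0, -1.5, -2.0, -2.5, -3.0])}
        pairs = build_pair_set(singles, object(),
                               distance_lookup=lambda a, b: 99.0)
        graph = build_design_graph(singles, pairs)
        assert len(graph.edges) == 15  # complete graph on 6 nodes
        design = select_design(enumerate_maximal_cliques(graph), singles,
                               "energy-low")
        assert set(design.mutations) == set(muts)
        assert design.total_score == pytest.approx(sum(singles.values()))

    def test_planted_antagonism_excludes_one_partner(self):
        muts = _muts(5)
        singles = {m: -1.5 for m in muts}
        spec = LandscapeSpec(
            singles=singles,
            pair_overrides={frozenset((muts[1], muts[3])): -1.0},
        )
        evaluator, lookup = synth_landscape(spec)
        pairs = build_pair_set(singles, evaluator, distance_lookup=lookup)
        graph = build_design_graph(singles, pairs)
        # exactly the planted edge is missing
        assert len(graph.edges) == 9
        assert not graph.has_edge(muts[1], muts[3])
        design = select_design(enumerate_maximal_cliques(graph), singles,
                               "energy-low")
        assert not {muts[1], muts[3]} <= set(design.mutations)
        assert len(design.mutations) == 4


class TestCliqueEnumeration:
    def test_triangle(self):
        muts, graph = _graph(3, [(0, 1), (0, 2), (1, 2)])
        assert enumerate_maximal_cliques(graph) == [tuple(muts)]

    def test_path(self):
        muts, graph = _graph(3, [(0, 1), (1, 2)])
        cliques = enumerate_maximal_cliques(graph)
        assert cliques == sorted([
            (muts[0], muts[1]), (muts[1], muts[2])])

    def test_isolated_node_singleton(self):
        muts, graph = _graph(3, [(0, 1)])
        cliques = enumerate_maximal_cliques(graph)
        assert (muts[2],) in cliques

    def test_empty_graph(self):
        assert enumerate_maximal_cliques(
            DesignGraph(singles={}, edges={})) == []

    def test_matches_exhaustive_and_networkx_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for trial in range(120):
            n = int(rng.integers(2, 13))
            p = float(rng.uniform(0.15, 0.7))
            edge_list = [
                (i, j) for i, j in itertools.combinations(range(n), 2)
                if rng.random() < p
            ]
            muts, graph = _graph(n, edge_list)
            got = {
                frozenset(m.position - 1 for m in c)
                for c in enumerate_maximal_cliques(graph)
            }
            expected = brute_force_maximal_cliques(
                n, {frozenset(e) for e in edge_list})
            assert got == expected, f"trial {trial}"
            # independent library cross-check
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edge_list)
            assert got == {frozenset(c) for c in nx.find_cliques(g)}


class TestDesignSelection:
    def test_lowest_total_wins(self):
        a, b, c = _muts(3)
        singles = {a: -1.5, b: -1.5, c: -2.9}
        design = select_design([(a, b), (c,)], singles, "energy-low")
        assert design.mutations == (a, b)
        assert design.total_score == pytest.approx(-3.0)

    def test_tie_prefers_larger_clique(self):
        a, b, c, d, e = _muts(5)
        singles = {a: -1.0, b: -2.0, c: -1.0, d: -1.0, e: -1.0}
        design = select_design([(a, b), (c, d, e)], singles, "energy-low")
        assert design.mutations == (c, d, e)

    def test_empty_cliques_wild_type(self):
        design = select_design([], {}, "energy-low", query_sequence="ACDE")
        assert design.mutations == ()
        assert design.mutant_sequence == "ACDE"

    def test_matches_exhaustive_search_on_random_landscapes(self):
        rng = np.random.default_rng(21)
        for trial in range(60):
            n = int(rng.integers(2, 9))
            muts = [Mutation("A", p, "A", AA[int(rng.integers(1, 20))])
                    for p in range(1, n + 1)]
            singles = {m: float(np.round(rng.uniform(-3.0, -0.2), 3))
                       for m in muts}
            overrides = {}
            for a, b in itertools.combinations(muts, 2):
                if rng.random() < 0.25:
                    overrides[frozenset((a, b))] = float(np.round(
                        singles[a] + singles[b] + rng.uniform(0.0, 3.0), 3))
            spec = LandscapeSpec(singles=singles, pair_overrides=overrides)
            evaluator, lookup = synth_landscape(spec)
            design = design_from_singles(singles, evaluator, "energy-low",
                                         distance_lookup=lookup)

            def edge_ok(a, b, _overrides=overrides, _s=singles):
                pair = _overrides.get(frozenset((a, b)), _s[a] + _s[b])
                return pair <= min(_s[a], _s[b])

            best_set, best_total = exhaustive_best_design(
                muts, singles, edge_ok)
            assert design.mutations == best_set, f"trial {trial}"
            assert design.total_score == pytest.approx(best_total)

    def test_node_deletion_never_improves_score(self):
        rng = np.random.default_rng(5)
        muts = _muts(7)
        singles = {m: float(rng.uniform(-3, -0.5)) for m in muts}
        overrides = {
            frozenset((muts[0], muts[3])): 0.5,
            frozenset((muts[2], muts[5])): 0.0,
        }
        spec = LandscapeSpec(singles=singles, pair_overrides=overrides)
        evaluator, lookup = synth_landscape(spec)
        full = design_from_singles(singles, evaluator, "x",
                                   distance_lookup=lookup)
        for drop in muts:
            reduced = {m: v for m, v in singles.items() if m != drop}
            sub = design_from_singles(reduced, evaluator, "x",
                                      distance_lookup=lookup)
            assert sub.total_score >= full.total_score - 1e-12


class TestCombinedDesign:
    @staticmethod
    def _design(scenario, singles):
        muts = tuple(sorted(singles, key=lambda m: m.position))
        from stabiliforge.multipoint_design import StabilityDesign
        return StabilityDesign(scenario=scenario, mutations=muts,
                               single_ddgs=dict(singles),
                               total_score=sum(singles.values()))

    def test_disjoint_distant_pools_fully_merged(self):
        e = {Mutation("A", p, "A", "W"): -1.5 for p in (1, 2)}
        v = {Mutation("A", p, "A", "S"): -0.5 for p in (5, 6, 7)}
        spec = LandscapeSpec(singles={**e, **v})
        evaluator, lookup = synth_landscape(spec)
        combo = combined_design(self._design("energy-low", e),
                                self._design("evolution", v),
                                evaluator, distance_lookup=lookup)
        assert len(combo.mutations) == 5

    def test_same_position_conflict_keeps_more_stabilizing(self):
        a = Mutation("A", 5, "A", "W")
        b = Mutation("A", 5, "A", "S")
        spec = LandscapeSpec(singles={a: -2.0, b: -1.0})
        evaluator, lookup = synth_landscape(spec)
        combo = combined_design(self._design("energy-low", {a: -2.0}),
                                self._design("evolution", {b: -1.0}),
                                evaluator, distance_lookup=lookup)
        assert combo.mutations == (a,)

    def test_empty_pool_reduces_to_other_design(self):
        v = {Mutation("A", p, "A", "S"): -0.5 for p in (5, 6)}
        spec = LandscapeSpec(singles=v)
        evaluator, lookup = synth_landscape(spec)
        combo = combined_design(self._design("energy-low", {}),
                                self._design("evolution", v),
                                evaluator, distance_lookup=lookup)
        assert set(combo.mutations) == set(v)

    def test_cross_pool_antagonism_resolved_like_oracle(self):
        e = {Mutation("A", p, "A", "W"): -2.0 for p in (1, 2)}
        v = {Mutation("A", p, "A", "S"): -1.0 for p in (5, 6)}
        singles = {**e, **v}
        bad = frozenset((Mutation("A", 2, "A", "W"),
                         Mutation("A", 5, "A", "S")))
        spec = LandscapeSpec(singles=singles, pair_overrides={bad: 0.0})
        evaluator, lookup = synth_landscape(spec)
        combo = combined_design(self._design("energy-low", e),
                                self._design("evolution", v),
                                evaluator, distance_lookup=lookup)

        def edge_ok(a, b):
            if frozenset((a, b)) == bad:
                return False
            return True

        best_set, _ = exhaustive_best_design(list(singles), singles, edge_ok)
        assert combo.mutations == best_set
        assert len(set(bad) & set(combo.mutations)) == 1


class TestMutantSequence:
    def test_substitution_applied(self):
        from stabiliforge.multipoint_design import StabilityDesign
        d = StabilityDesign("x", (Mutation("A", 3, "D", "N"),),
                            {Mutation("A", 3, "D", "N"): -1.0}, -1.0)
        assert mutant_sequence("ACDE", d) == "ACNE"

    def test_empty_design_identity(self):
        from stabiliforge.multipoint_design import StabilityDesign
        d = StabilityDesign("x", (), {}, 0.0)
        assert mutant_sequence("ACDE", d) == "ACDE"

    def test_wild_type_mismatch_rejected(self):
        from stabiliforge.multipoint_design import StabilityDesign
        m = Mutation("A", 4, "Q", "K")
        d = StabilityDesign("x", (m,), {m: -1.0}, -1.0)
        with pytest.raises(ValueError, match="position 4"):
            mutant_sequence("ACDE", d)
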