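import pytest

from stabiliforge.design_candidates import (
    FILTER_ORDER,
    FilterPolicy,
    ancestral_substitutions,
    apply_mutation_filters,
    apply_position_filters,
    back_to_consensus,
    recurrent_ancestral_filter,
    saturation_candidates,
)
from stabiliforge.formats_io import Msa, Mutation

from .oracles import gotoh_score


class TestSaturation:
    def test_nineteen_per_position(self):
        cands = saturation_candidates("ACDEF", positions=[3])
        assert len(cands) == 19
        assert all(c.mutation.wt == "D" and c.mutation.mut != "D"
                   for c in cands)

    def test_whole_protein_count(self):
        seq = "ACDEFGHIKL" * 30
        assert len(saturation_candidates(seq)) == 19 * 300

    def test_unknown_wild_type_rejected(self):
        with pytest.raises(ValueError):
            saturation_candidates("ACXDE", positions=[3])

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            saturation_candidates("ACDEF", positions=[6])


def _freq_msa(wt, column_letters):
    """Query 'A<wt>A' style MSA realizing an exact column composition."""
    rows = [f"A{wt}C"] + [f"A{ch}C" for ch in column_letters]
    ids = ["q"] + [f"s{i}" for i in range(len(column_letters))]
    return Msa(ids=ids, rows=rows, query_id="q")


class TestBackToConsensus:
    def test_majority_rule(self):
        # column: wt A appears 3x (incl query), S 6x, T 1x -> freq(S)=0.6
        msa = _freq_msa("A", "SSSSSSAATX"[:9])
        # letters: S*6, A*2, T*1 plus query A -> 10 rows: S .6, A .3, T .1
        msa = _freq_msa("A", "SSSSSSAAT")
        cands = back_to_consensus(msa)
        assert len(cands) == 1
        assert cands[0].mutation == Mutation("A", 2, "A", "S")
        assert cands[0].source == "consensus-majority"

    def test_ratio_rule(self):
        # 50 rows: T 21 (0.42), A(wt incl query) 4 (0.08), rest spread
        letters = "T" * 21 + "A" * 3 + "CDEFGHIKLMNPQRSVWY" + "CDEFGHI"
        assert len(letters) == 49
        msa = _freq_msa("A", letters)
        cands = back_to_consensus(msa)
        assert len(cands) == 1
        assert cands[0].mutation == Mutation("A", 2, "A", "T")
        assert cands[0].source == "consensus-ratio"

    def test_ratio_fails_without_five_fold(self):
        # T 0.42 but wt A 0.10 -> 0.42 < 5 * 0.10
        letters = "T" * 21 + "A" * 4 + "CDEFGHIKLMNPQRSVWY" + "CDEFGH"
        assert len(letters) == 49
        msa = _freq_msa("A", letters)
        assert back_to_consensus(msa) == []

    def test_consensus_equal_to_wild_type_no_candidate(self):
        msa = _freq_msa("A", "AAAAASSST")
        assert back_to_consensus(msa) == []

    def test_at_most_one_candidate_per_position_and_rules_hold(self):
        from stabiliforge.synthetic import synth_msa
        msa = synth_msa("ACDEFGHIKLMNPQRSTVWY", depth=30, seed=14)
        cands = back_to_consensus(msa)
        positions = [c.mutation.position for c in cands]
        assert len(positions) == len(set(positions))
        for c in cands:
            f_cons = c.annotations["consensus_frequency"]
            f_wt = c.annotations["wildtype_frequency"]
            if c.source == "consensus-majority":
                assert f_cons >= 0.50
            else:
                assert f_cons >= 0.40 and f_cons >= 5 * f_wt

    def test_boundary_frequencies_inclusive(self):
        # exactly 0.50 -> majority
        msa = _freq_msa("A", "SSSSSAAAT")  # S 5/10, A 4/10 (incl query)
        cands = back_to_consensus(msa)
        assert cands and cands[0].source == "consensus-majority"
        # exactly 0.40 with exactly 5x -> ratio
        letters = "T" * 20 + "A" * 3 + "CDEFGHIKLMNPQRSVWY" + "CDEFGHIK"
        assert len(letters) == 49
        msa = _freq_msa("A", letters)  # T .40, A .08
        cands = back_to_consensus(msa)
        assert cands and cands[0].source == "consensus-ratio"


class TestAncestral:
    def test_single_substitution(self):
        subs = ancestral_substitutions("ACDE", {"n1": "ACNE"})
        assert subs["n1"] == [Mutation("A", 3, "D", "N")]

    def test_identical_ancestor_empty(self):
        assert ancestral_substitutions("ACDE", {"n1": "ACDE"})["n1"] == []

    def test_deletion_reported_only_as_substitutions(self):
        # the DP oracle confirms the optimal alignment drops one residue;
        # remaining columns are identical, so no substitution is reported
        query, anc = "ACDEF", "ACEF"
        assert gotoh_score(query, anc) == gotoh_score(anc, query)
        subs = ancestral_substitutions(query, {"n1": anc})
        for m in subs["n1"]:
            assert query[m.position - 1] == m.wt
            assert m.wt != m.mut
        assert subs["n1"] == []

    def test_empty_ancestor_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            subs = ancestral_substitutions("ACDE", {"n1": ""})
        assert "n1" not in subs

    def test_recurrence_filter(self):
        d3n = Mutation("A", 3, "D", "N")
        e4q = Mutation("A", 4, "E", "Q")
        nodes = {
            "n1": [d3n], "n2": [d3n], "n3": [e4q], "n4": [], "n5": [],
        }
        kept = recurrent_ancestral_filter(nodes, min_nodes=2)
        assert [c.mutation for c in kept] == [d3n]
        union = recurrent_ancestral_filter(nodes, min_nodes=1)
        assert {c.mutation for c in union} == {d3n, e4q}


class TestPositionFilters:
    @staticmethod
    def _cands(*positions):
        return [
            saturation_candidates("A" * 50, positions=[p])[0]
            for p in positions
        ]

    def test_essential_rejected_with_reason(self):
        cands = self._cands(5)
        grades = {5: 9}
        out = apply_position_filters(cands, {5}, grades, set(),
                                     FilterPolicy())
        assert out == []
        assert cands[0].rejection_reason == "essential"

    def test_grade_boundary_four_rejected_five_passes(self):
        cands = self._cands(5, 6)
        grades = {5: 4, 6: 5}
        out = apply_position_filters(cands, set(), grades, set(),
                                     FilterPolicy())
        assert [c.mutation.position for c in out] == [6]
        assert cands[0].rejection_reason == "conserved"

    def test_correlated_rejected(self):
        cands = self._cands(5)
        out = apply_position_filters(cands, set(), {5: 9}, {5},
                                     FilterPolicy())
        assert out == []
        assert cands[0].rejection_reason == "correlated"

    def test_missing_annotation_names_position(self):
        cands = self._cands(5)
        with pytest.raises(KeyError, match="5"):
            apply_position_filters(cands, set(), {}, set(), FilterPolicy())

    def test_first_failing_filter_reported(self):
        # essential AND conserved: essential comes first in FILTER_ORDER
        cands = self._cands(5)
        apply_position_filters(cands, {5}, {5: 0}, {5}, FilterPolicy())
        assert cands[0].rejection_reason == FILTER_ORDER[0]


class TestMutationFilters:
    @staticmethod
    def _candidate(mut):
        from stabiliforge.design_candidates import MutationCandidate
        return MutationCandidate(mutation=mut, source="saturation")

    @staticmethod
    def _msa():
        rows = ["AAAA", "AKAA", "ACAA"]
        return Msa(ids=["q", "a", "b"], rows=rows, query_id="q")

    def test_surface_charge_change_rejected_low_risk(self):
        cand = self._candidate(Mutation("A", 2, "A", "K"))
        out = apply_mutation_filters([cand], self._msa(), {2},
                                     FilterPolicy(risk="low"))
        assert out == []
        assert cand.rejection_reason == "charge-surface"

    def test_same_mutation_passes_high_risk(self):
        cand = self._candidate(Mutation("A", 2, "A", "K"))
        out = apply_mutation_filters([cand], self._msa(), {2},
                                     FilterPolicy(risk="high"))
        assert out == [cand]

    def test_buried_charge_change_passes_low_risk(self):
        cand = self._candidate(Mutation("A", 2, "A", "K"))
        out = apply_mutation_filters([cand], self._msa(), set(),
                                     FilterPolicy(risk="low"))
        assert out == [cand]

    def test_absent_from_msa_rejected_low_risk_only(self):
        low = self._candidate(Mutation("A", 2, "A", "W"))
        high = self._candidate(Mutation("A", 2, "A", "W"))
        assert apply_mutation_filters([low], self._msa(), set(),
                                      FilterPolicy(risk="low")) == []
        assert low.rejection_reason == "msa-presence"
        assert apply_mutation_filters([high], self._msa(), set(),
                                      FilterPolicy(risk="high")) == [high]


class TestRiskMonotonicity:
    def test_high_risk_superset_of_low_risk(self):
        """High-risk survivors contain the low-risk survivors."""
        from stabiliforge.synthetic import synth_msa
        import numpy as np
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = 25
            query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            msa = synth_msa(query, depth=15, seed=100 + trial)
            grades = {p: int(g) for p, g in
                      zip(range(1, n + 1), rng.integers(0, 10, size=n))}
            correlated = set(rng.choice(np.arange(1, n + 1), size=3,
                                        replace=False).tolist())
            essential = {int(rng.integers(1, n + 1))}
            surface = set(rng.choice(np.arange(1, n + 1), size=n // 2,
                                     replace=False).tolist())
            survivors = {}
            for risk in ("low", "high"):
                cands = saturation_candidates(query)
                policy = FilterPolicy(risk=risk)
                kept = apply_position_filters(
                    cands, essential, grades, correlated, policy)
                kept = apply_mutation_filters(kept, msa, surface, policy)
                survivors[risk] = {c.mutation for c in kept}
            assert survivors["low"] <= survivors["high"]
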