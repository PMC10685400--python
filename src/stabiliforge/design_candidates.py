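"""Candidate single-point mutations and the filter cascades.

Candidates come from three branches: whole-protein (or targeted) saturation
mutagenesis, back-to-consensus substitutions read off the alignment column
frequencies (majority >= 50%, or ratio >= 40% with at least 5x the
wild-type frequency), and substitutions extracted from precomputed
ancestral sequences (kept when recurrent across internal nodes).

Two filter layers then discard risky candidates.  Position-level filters
apply in every scenario: essential residues, conserved positions
(conservation grade 4 or lower) and correlated positions are untouchable.
Mutation-level filters apply only in the low-risk scenario: the mutant
amino acid must occur in the position's alignment column, and
charge-changing mutations on the protein surface are disallowed.  Filters
are evaluated in a fixed order (essential, conserved, correlated,
msa-presence, charge-surface) and a rejected candidate records the first
failing filter as its reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._data import AA_INDEX, AMINO_ACIDS, AA_SET, GAP_CHARS, charge_class
from .alignment import needleman_wunsch
from .formats_io import Msa, Mutation

SOURCES = ("saturation", "consensus-majority", "consensus-ratio",
           "ancestral", "user")

FILTER_ORDER = ("essential", "conserved", "correlated",
                "msa-presence", "charge-surface")


@dataclass
class FilterPolicy:
    """Which filters apply, and their thresholds.

    The high-risk scenario disables exactly the mutation-level filters
    (msa-presence and charge-surface); position-level filters are always
    enforced.
    """

    risk: str = "low"
    conservation_max_grade: int = 4
    correlation_threshold: float = 3.5
    surface_rel_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.risk not in ("low", "high"):
            raise ValueError("risk must be 'low' or 'high'")

    @property
    def mutation_filters_enabled(self) -> bool:
        return self.risk == "low"


@dataclass
class MutationCandidate:
    """A candidate substitution with its annotations and filter verdicts."""

    mutation: Mutation
    source: str
    annotations: dict = field(default_factory=dict)
    energies: dict = field(default_factory=dict)
    verdicts: list = field(default_factory=list)  # (filter, passed, reason)

    def record(self, filter_name: str, passed: bool, reason: str = "") -> None:
        self.verdicts.append((filter_name, passed, reason))

    @property
    def rejected(self) -> bool:
        return any(not passed for _, passed, _ in self.verdicts)

    @property
    def rejection_reason(self) -> str | None:
        for name, passed, reason in self.verdicts:
            if not passed:
                return reason or name
        return None


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def saturation_candidates(
    query_sequence: str,
    positions: list[int] | None = None,
    chain: str = "A",
) -> list[MutationCandidate]:
    """All 19 substitutions at each position (whole protein by default)."""
    if positions is None:
        positions = list(range(1, len(query_sequence) + 1))
    out: list[MutationCandidate] = []
    for pos in positions:
        if not 1 <= pos <= len(query_sequence):
            raise ValueError(f"position {pos} outside 1..{len(query_sequence)}")
        wt = query_sequence[pos - 1]
        if wt not in AA_SET:
            raise ValueError(
                f"position {pos}: wild-type {wt!r} is not a standard amino acid"
            )
        for aa in AMINO_ACIDS:
            if aa == wt:
                continue
            out.append(MutationCandidate(
                mutation=Mutation(chain=chain, position=pos, wt=wt, mut=aa),
                source="saturation",
            ))
    return out


def _column_frequencies(
    msa: Msa, col: int, count_gaps: bool = False
) -> tuple[np.ndarray, int]:
    """20-vector of column frequencies; gaps optionally in the denominator."""
    column = msa.column(col)
    counts = np.zeros(20)
    gaps = 0
    for ch in column:
        if ch in GAP_CHARS:
            gaps += 1
        elif ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
    denom = counts.sum() + (gaps if count_gaps else 0)
    if denom == 0:
        return counts, 0
    return counts / denom, int(counts.sum())


def back_to_consensus(
    msa: Msa,
    chain: str = "A",
    majority_threshold: float = 0.50,
    ratio_threshold: float = 0.40,
    ratio_factor: float = 5.0,
    count_gaps: bool = False,
) -> list[MutationCandidate]:
    """Back-to-consensus candidates from column frequencies.

    At each query position with consensus residue c != wild type: a
    *majority* candidate if freq(c) >= 0.50, else a *ratio* candidate if
    freq(c) >= 0.40 and freq(c) >= 5 * freq(wt).  At most one candidate per
    position.  Frequencies exclude gaps from the denominator unless
    ``count_gaps`` is set.
    """
    out: list[MutationCandidate] = []
    for pos, col in sorted(msa.pos_to_col.items()):
        wt = msa.query_row[col]
        if wt not in AA_INDEX:
            continue
        freqs, n_obs = _column_frequencies(msa, col, count_gaps=count_gaps)
        if n_obs == 0:
            continue
        best = int(np.argmax(freqs))
        consensus = AMINO_ACIDS[best]
        if consensus == wt:
            continue
        f_cons = float(freqs[best])
        f_wt = float(freqs[AA_INDEX[wt]])
        source = None
        if f_cons >= majority_threshold:
            source = "consensus-majority"
        elif f_cons >= ratio_threshold and f_cons >= ratio_factor * f_wt:
            source = "consensus-ratio"
        if source is None:
            continue
        out.append(MutationCandidate(
            mutation=Mutation(chain=chain, position=pos, wt=wt, mut=consensus),
            source=source,
            annotations={
                "consensus_frequency": f_cons,
                "wildtype_frequency": f_wt,
            },
        ))
    return out


def ancestral_substitutions(
    query: str, ancestral_sequences: dict[str, str], chain: str = "A"
) -> dict[str, list[Mutation]]:
    """Substitutions of each ancestral sequence relative to the query.

    Each ancestor is globally aligned to the query; mismatches at columns
    where both rows carry a residue become mutations in query numbering,
    while insertions and deletions are ignored.
    """
    out: dict[str, list[Mutation]] = {}
    for node_id, seq in ancestral_sequences.items():
        if not seq:
            warnings.warn(f"skipping empty ancestral sequence {node_id!r}",
                          stacklevel=2)
            continue
        row_q, row_a, _ = needleman_wunsch(query, seq)
        muts: list[Mutation] = []
        pos = 0
        for cq, ca in zip(row_q, row_a):
            if cq != "-":
                pos += 1
            if cq == "-" or ca == "-" or cq == ca:
                continue
            if cq in AA_SET and ca in AA_SET:
                muts.append(Mutation(chain=chain, position=pos, wt=cq, mut=ca))
        out[node_id] = muts
    return out


def recurrent_ancestral_filter(
    per_node_lists: dict[str, list[Mutation]], min_nodes: int = 2
) -> list[MutationCandidate]:
    """Keep mutations recurring in at least ``min_nodes`` ancestral nodes."""
    if min_nodes < 1:
        raise ValueError("min_nodes must be >= 1")
    node_count: dict[Mutation, int] = {}
    for muts in per_node_lists.values():
        for m in set(muts):
            node_count[m] = node_count.get(m, 0) + 1
    kept = sorted(
        (m for m, k in node_count.items() if k >= min_nodes),
        key=lambda m: (m.chain, m.position, m.mut),
    )
    return [
        MutationCandidate(
            mutation=m, source="ancestral",
            annotations={"n_nodes": node_count[m]},
        )
        for m in kept
    ]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_position_filters(
    candidates: list[MutationCandidate],
    essential_positions: set[int],
    conservation_grade_by_position: dict[int, int],
    correlated_positions: set[int],
    policy: FilterPolicy,
) -> list[MutationCandidate]:
    """Position-level safety filters (always on, both risk modes).

    A candidate is rejected if its position is essential, conserved (grade
    <= ``policy.conservation_max_grade``) or correlated.  Verdicts are
    recorded in order; evaluation of a candidate stops at the first failure.
    """
    for cand in candidates:
        pos = cand.mutation.position
        if pos not in conservation_grade_by_position:
            raise KeyError(f"no conservation annotation for position {pos}")
        if pos in essential_positions:
            cand.record("essential", False, "essential")
            cand.annotations["essential"] = True
            continue
        cand.record("essential", True)
        grade = conservation_grade_by_position[pos]
        cand.annotations["conservation_grade"] = grade
        if grade <= policy.conservation_max_grade:
            cand.record("conserved", False, "conserved")
            continue
        cand.record("conserved", True)
        correlated = pos in correlated_positions
        cand.annotations["correlated"] = correlated
        if correlated:
            cand.record("correlated", False, "correlated")
            continue
        cand.record("correlated", True)
    return [c for c in candidates if not c.rejected]


def apply_mutation_filters(
    candidates: list[MutationCandidate],
    msa: Msa,
    surface_positions: set[int],
    policy: FilterPolicy,
) -> list[MutationCandidate]:
    """Mutation-level filters; active only in the low-risk scenario.

    Low risk rejects (a) target amino acids never observed in the
    position's alignment column, then (b) charge-class changes at surface
    positions.  High risk records both checks as skipped-pass.
    """
    for cand in candidates:
        if cand.rejected:
            continue
        m = cand.mutation
        col = msa.pos_to_col.get(m.position)
        present = False
        if col is not None:
            present = m.mut in msa.column(col)
        cand.annotations["msa_presence"] = present
        surface = m.position in surface_positions
        changes_charge = charge_class(m.wt) != charge_class(m.mut)
        cand.annotations["surface"] = surface
        cand.annotations["charge_change"] = changes_charge
        if not policy.mutation_filters_enabled:
            cand.record("msa-presence", True, "skipped (high risk)")
            cand.record("charge-surface", True, "skipped (high risk)")
            continue
        if not present:
            cand.record("msa-presence", False, "msa-presence")
            continue
        cand.record("msa-presence", True)
        if changes_charge and surface:
            cand.record("charge-surface", False, "charge-surface")
            continue
        cand.record("charge-surface", True)
    return [c for c in candidates if not c.rejected]


def read_essential_positions(path) -> set[tuple[str, int]]:
    """Read an essential-residue list, one ``chain/position`` per line."""
    out: set[tuple[str, int]] = set()
    for raw in open(path):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "/" in line:
            chain, pos = line.split("/", 1)
        else:
            chain, pos = "A", line
        out.add((chain, int(pos)))
    return out
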