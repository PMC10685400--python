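"""End-to-end automated design: annotate, filter, evaluate, combine.

Orchestrates the module layers into the standard run: conservation and
correlation annotation of the alignment, surface and flexibility annotation
of the structure, the three single-point branches (energy-based saturation
under low- and high-risk filter policies, back-to-consensus, ancestral),
and the clique-based multiple-point designs including the combined pools.

Positions are query numbering; the structure's author numbering is assumed
to coincide with it (renumber the structure beforehand if it does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design_candidates import (
    FilterPolicy,
    MutationCandidate,
    ancestral_substitutions,
    apply_mutation_filters,
    apply_position_filters,
    back_to_consensus,
    recurrent_ancestral_filter,
    saturation_candidates,
)
from .energy_engine import (
    EnergyEvaluator,
    StagePolicy,
    consensus_energy_filter,
    energy_stage_filter,
)
from .formats_io import Msa, StructureModel
from .msa_scores import (
    ConservationTrack,
    compute_correlations,
    consensus_correlated,
    jsd_conservation,
)
from .multipoint_design import (
    StabilityDesign,
    combined_design,
    design_from_singles,
    mutant_sequence,
)
from .structure_features import shrake_rupley_sasa, surface_mask


@dataclass
class AnnotationBundle:
    """Position-level annotations shared by all branches (query numbering)."""

    conservation: ConservationTrack
    grade_by_position: dict[int, int]
    correlated_positions: set[int]
    surface_positions: set[int]


@dataclass
class PipelineResult:
    annotations: AnnotationBundle
    candidates: dict[str, list[MutationCandidate]] = field(default_factory=dict)
    designs: dict[str, StabilityDesign] = field(default_factory=dict)


def annotate(
    structure: StructureModel,
    msa: Msa,
    chain: str = "A",
    correlation_methods: list[str] | None = None,
    flag_fraction: float = 0.01,
    correlation_threshold: float = 3.5,
    surface_rel_threshold: float = 0.25,
) -> AnnotationBundle:
    """Compute the position-level annotations used by every filter."""
    track = jsd_conservation(msa)
    grade_by_position = {
        pos: int(track.grades[col]) for col, pos in msa.col_to_pos.items()
    }
    matrices = compute_correlations(msa, correlation_methods)
    corr = consensus_correlated(
        matrices, flag_fraction=flag_fraction, threshold=correlation_threshold
    )
    correlated_positions = {
        msa.col_to_pos[c] for c in corr.correlated_columns
        if c in msa.col_to_pos
    }
    annotation = shrake_rupley_sasa(structure,
                                    rel_threshold=surface_rel_threshold)
    surface_positions = {
        rid.number for rid in surface_mask(annotation) if rid.chain == chain
    }
    return AnnotationBundle(
        conservation=track,
        grade_by_position=grade_by_position,
        correlated_positions=correlated_positions,
        surface_positions=surface_positions,
    )


def _energy_branch(
    query: str,
    msa: Msa,
    annotations: AnnotationBundle,
    evaluator_stage1: EnergyEvaluator,
    evaluator_stage2: EnergyEvaluator,
    policy: FilterPolicy,
    stage_policy: StagePolicy,
    essential_positions: set[int],
    chain: str,
    positions: list[int] | None = None,
) -> list[MutationCandidate]:
    candidates = saturation_candidates(query, positions=positions, chain=chain)
    candidates = [
        c for c in candidates
        if c.mutation.position in annotations.grade_by_position
    ]
    survivors = apply_position_filters(
        candidates, essential_positions, annotations.grade_by_position,
        annotations.correlated_positions, policy,
    )
    survivors = apply_mutation_filters(
        survivors, msa, annotations.surface_positions, policy
    )
    return energy_stage_filter(
        survivors, evaluator_stage1, evaluator_stage2, stage_policy
    )


def run_automated_design(
    structure: StructureModel,
    msa: Msa,
    evaluator: EnergyEvaluator,
    chain: str = "A",
    essential_positions: set[int] | None = None,
    ancestral_sequences: dict[str, str] | None = None,
    stage_policy: StagePolicy | None = None,
    correlation_methods: list[str] | None = None,
    pair_radius: float = 10.0,
    min_ancestral_nodes: int = 2,
) -> PipelineResult:
    """The full automated run, producing up to six designs.

    The same evaluator serves both energy stages (their thresholds differ),
    the consensus check and the pair evaluations; plug in different
    :class:`TableEvaluator` instances per stage to reproduce a two-program
    cascade from exported tables.
    """
    essential_positions = essential_positions or set()
    stage_policy = stage_policy or StagePolicy()
    query = msa.query_sequence
    annotations = annotate(structure, msa, chain=chain,
                           correlation_methods=correlation_methods)
    result = PipelineResult(annotations=annotations)

    # --- energy branch, one pass per risk scenario -------------------------
    for risk in ("low", "high"):
        policy = FilterPolicy(risk=risk)
        accepted = _energy_branch(
            query, msa, annotations, evaluator, evaluator, policy,
            stage_policy, essential_positions, chain,
        )
        result.candidates[f"energy-{risk}"] = accepted
        singles = {c.mutation: c.energies["stage2"] for c in accepted}
        result.designs[f"energy-{risk}"] = design_from_singles(
            singles, evaluator, f"energy-{risk}", structure=structure,
            radius=pair_radius, query_sequence=query,
        )

    # --- evolution branch (back-to-consensus) ------------------------------
    consensus = back_to_consensus(msa, chain=chain)
    consensus = apply_position_filters(
        consensus, essential_positions, annotations.grade_by_position,
        annotations.correlated_positions, FilterPolicy(risk="low"),
    )
    consensus = consensus_energy_filter(
        consensus, evaluator, threshold=stage_policy.consensus_threshold
    )
    result.candidates["evolution"] = consensus
    evo_singles = {c.mutation: c.energies["consensus"] for c in consensus}
    result.designs["evolution"] = design_from_singles(
        evo_singles, evaluator, "evolution", structure=structure,
        radius=pair_radius, query_sequence=query,
    )

    # --- combined designs ---------------------------------------------------
    for risk in ("low", "high"):
        result.designs[f"combined-{risk}"] = combined_design(
            result.designs[f"energy-{risk}"], result.designs["evolution"],
            evaluator, structure=structure, radius=pair_radius,
            scenario=f"combined-{risk}", query_sequence=query,
        )

    # --- ancestral branch (reported single-point list) ----------------------
    if ancestral_sequences:
        per_node = ancestral_substitutions(query, ancestral_sequences,
                                           chain=chain)
        recurrent = recurrent_ancestral_filter(per_node,
                                               min_nodes=min_ancestral_nodes)
        recurrent = apply_position_filters(
            recurrent, essential_positions, annotations.grade_by_position,
            annotations.correlated_positions, FilterPolicy(risk="low"),
        )
        result.candidates["ancestral"] = recurrent
        # reported as a list, not a clique; one mutation per position
        by_pos: dict[int, MutationCandidate] = {}
        for cand in recurrent:
            pos = cand.mutation.position
            incumbent = by_pos.get(pos)
            if incumbent is None or (
                cand.annotations.get("n_nodes", 0)
                > incumbent.annotations.get("n_nodes", 0)
            ):
                by_pos[pos] = cand
        muts = tuple(sorted(
            (c.mutation for c in by_pos.values()),
            key=lambda m: (m.chain, m.position, m.mut),
        ))
        ddgs = {}
        for m in muts:
            try:
                ddgs[m] = float(evaluator.single(m))
            except Exception:
                ddgs[m] = float("nan")
        design = StabilityDesign(
            scenario="ancestral", mutations=muts, single_ddgs=ddgs,
            total_score=float(sum(v for v in ddgs.values() if v == v)),
        )
        design.mutant_sequence = mutant_sequence(query, design)
        result.designs["ancestral"] = design

    return result
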