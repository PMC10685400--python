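"""Energy evaluation: the evaluator contract, adapters and threshold stages.

The pipeline never runs force-field software itself.  It speaks to an
*evaluator* — anything with ``single(mutation) -> ddG`` and
``pair(mutation_a, mutation_b) -> ddG`` in kcal/mol, negative =
stabilizing, deterministic for fixed inputs.  Two evaluators ship here:

* :class:`TableEvaluator` feeds exported FoldX-/Rosetta-style ddG tables
  into the pipeline (missing pairs fall back to additivity);
* :class:`SurrogateEvaluator` is a fast deterministic stand-in potential
  for desk-scale runs and testing: a hydrophobic-burial contact term over
  neighbours within a contact radius plus a small position-hashed noise
  term, with an explicit pair coupling when the two residues are in
  contact.

The threshold stages mirror the two-step cascade of the energy branch
(first screen at -1.0 kcal/mol, survivors re-scored and kept at
-1.5 kcal/mol) and the milder consensus check (consensus candidates kept
unless clearly destabilizing, above +0.5 kcal/mol).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol

import numpy as np

from ._data import KD_HYDROPATHY, THREE_TO_ONE
from .design_candidates import MutationCandidate
from .formats_io import DdgTable, Mutation, StructureModel

logger = logging.getLogger(__name__)


class EnergyEvaluator(Protocol):
    """Contract every energy backend satisfies."""

    def single(self, mutation: Mutation) -> float: ...

    def pair(self, mutation_a: Mutation, mutation_b: Mutation) -> float: ...


@dataclass
class StagePolicy:
    """Thresholds of the staged energy filters (kcal/mol, inclusive)."""

    stage1_threshold: float = -1.0
    stage2_threshold: float = -1.5
    consensus_threshold: float = 0.5


def _check_distinct_positions(a: Mutation, b: Mutation) -> None:
    if (a.chain, a.position) == (b.chain, b.position):
        raise ValueError(
            f"pair evaluation refused for same-position mutations {a} / {b}"
        )


# ---------------------------------------------------------------------------
# Surrogate potential
# ---------------------------------------------------------------------------

def _contact_potential(aa_a: str, aa_b: str) -> float:
    """Hydrophobic-burial contact energy in kcal/mol.

    More hydrophobic residue pairs in contact are favourable (negative);
    scaled so typical single-mutation effects land in the +-2 kcal/mol
    range familiar from empirical ddG scales.
    """
    return -0.1 * (KD_HYDROPATHY[aa_a] + KD_HYDROPATHY[aa_b])


class SurrogateEvaluator:
    """Deterministic desk-scale surrogate ddG potential.

    ``single``: sum over wild-type neighbours within ``contact_radius`` of
    the mutated site (side-chain reference point: CB, CA for glycine) of
    the contact-potential change plus a per-contact ``packing_penalty``
    (the wild type is assumed locally optimal, so any substitution pays a
    small price per disturbed contact — this reproduces the empirical
    regime where the large majority of mutations destabilize, with a mean
    ddG near +1 kcal/mol), plus seeded noise of amplitude
    ``noise_amplitude`` hashed from (seed, chain, position, wt, mut) — so
    values are bit-stable across runs and machines.  A site with no
    neighbours in contact and zero noise scores exactly 0.

    ``pair``: the sum of the singles, plus a coupling term
    ``cp(mut_a, mut_b) - cp(wt_a, wt_b)`` when the two sites are in
    contact; exactly additive otherwise.
    """

    def __init__(
        self,
        structure: StructureModel,
        seed: int = 0,
        contact_radius: float = 6.5,
        noise_amplitude: float = 0.2,
        packing_penalty: float = 0.3,
    ) -> None:
        self.structure = structure
        self.seed = int(seed)
        self.contact_radius = float(contact_radius)
        self.noise_amplitude = float(noise_amplitude)
        self.packing_penalty = float(packing_penalty)
        self._site_coord: dict[tuple[str, int], np.ndarray] = {}
        self._site_aa: dict[tuple[str, int], str] = {}
        for rid, name in zip(structure.residue_ids, structure.residue_names):
            idx = structure.residue_atom_indices(rid)
            names = structure.atom_name[idx]
            ref = idx[names == "CB"]
            if ref.size == 0:
                ref = idx[names == "CA"]
            if ref.size == 0:
                ref = idx[:1]
            key = (rid.chain, rid.number)
            self._site_coord[key] = structure.coord[ref[0]]
            self._site_aa[key] = THREE_TO_ONE.get(name, "A")

    # -- helpers ------------------------------------------------------------

    def _site(self, m: Mutation) -> tuple[str, int]:
        key = (m.chain, m.position)
        if key not in self._site_coord:
            raise KeyError(f"structure has no residue {m.chain}/{m.position}")
        return key

    def _neighbours(self, key: tuple[str, int]) -> list[tuple[str, int]]:
        own = self._site_coord[key]
        out = []
        for other, coord in self._site_coord.items():
            if other == key:
                continue
            if np.linalg.norm(coord - own) <= self.contact_radius:
                out.append(other)
        return out

    def _in_contact(self, key_a, key_b) -> bool:
        d = np.linalg.norm(self._site_coord[key_a] - self._site_coord[key_b])
        return d <= self.contact_radius

    def _noise(self, m: Mutation) -> float:
        if self.noise_amplitude == 0.0:
            return 0.0
        token = f"{self.seed}|{m.chain}|{m.position}|{m.wt}|{m.mut}"
        h = zlib.crc32(token.encode())
        u = h / 0xFFFFFFFF  # uniform in [0, 1]
        return self.noise_amplitude * (2.0 * u - 1.0)

    # -- contract -----------------------------------------------------------

    def single(self, mutation: Mutation) -> float:
        key = self._site(mutation)
        ddg = 0.0
        for nb in self._neighbours(key):
            nb_aa = self._site_aa[nb]
            ddg += (_contact_potential(mutation.mut, nb_aa)
                    - _contact_potential(mutation.wt, nb_aa)
                    + self.packing_penalty)
        return ddg + self._noise(mutation)

    def pair(self, mutation_a: Mutation, mutation_b: Mutation) -> float:
        _check_distinct_positions(mutation_a, mutation_b)
        if (mutation_b.chain, mutation_b.position, mutation_b.mut) < (
            mutation_a.chain, mutation_a.position, mutation_a.mut
        ):
            mutation_a, mutation_b = mutation_b, mutation_a
        total = self.single(mutation_a) + self.single(mutation_b)
        key_a, key_b = self._site(mutation_a), self._site(mutation_b)
        if self._in_contact(key_a, key_b):
            total += (_contact_potential(mutation_a.mut, mutation_b.mut)
                      - _contact_potential(mutation_a.wt, mutation_b.wt))
        return total


def surrogate_evaluator(
    structure: StructureModel,
    seed: int = 0,
    contact_radius: float = 6.5,
    noise_amplitude: float = 0.2,
    packing_penalty: float = 0.3,
) -> SurrogateEvaluator:
    """Build the built-in surrogate evaluator for a structure."""
    return SurrogateEvaluator(structure, seed=seed,
                              contact_radius=contact_radius,
                              noise_amplitude=noise_amplitude,
                              packing_penalty=packing_penalty)


# ---------------------------------------------------------------------------
# Table adapter
# ---------------------------------------------------------------------------

class TableEvaluator:
    """Evaluator backed by exported ddG tables.

    Missing single entries raise; missing pair entries fall back to the sum
    of singles, counted in ``additive_fallbacks``.
    """

    def __init__(
        self,
        ddg_single: DdgTable,
        ddg_pairs: Mapping[frozenset, float] | None = None,
    ) -> None:
        self.singles = ddg_single
        self.pairs = dict(ddg_pairs or {})
        self.additive_fallbacks = 0

    def single(self, mutation: Mutation) -> float:
        if mutation not in self.singles:
            raise LookupError(f"no ddG entry for mutation {mutation}")
        return self.singles[mutation]

    def pair(self, mutation_a: Mutation, mutation_b: Mutation) -> float:
        _check_distinct_positions(mutation_a, mutation_b)
        key = frozenset((mutation_a, mutation_b))
        if key in self.pairs:
            return float(self.pairs[key])
        self.additive_fallbacks += 1
        return self.single(mutation_a) + self.single(mutation_b)


def table_evaluator(
    ddg_single: DdgTable,
    ddg_pairs: Mapping[frozenset, float] | None = None,
) -> TableEvaluator:
    return TableEvaluator(ddg_single, ddg_pairs)


# ---------------------------------------------------------------------------
# Threshold stages
# ---------------------------------------------------------------------------

def energy_stage_filter(
    candidates: list[MutationCandidate],
    evaluator_stage1: EnergyEvaluator,
    evaluator_stage2: EnergyEvaluator,
    policy: StagePolicy | None = None,
) -> list[MutationCandidate]:
    """Two-stage energy cascade of the saturation branch.

    Stage 1 keeps candidates with ddG <= ``stage1_threshold`` (default
    -1.0); only those are evaluated by stage 2 and kept at
    ``stage2_threshold`` (default -1.5).  Both energies are recorded on the
    candidate; evaluator failures exclude the candidate and are logged.
    """
    policy = policy or StagePolicy()
    survivors: list[MutationCandidate] = []
    for cand in candidates:
        try:
            e1 = evaluator_stage1.single(cand.mutation)
        except Exception as exc:
            logger.warning("stage-1 evaluation failed for %s: %s",
                           cand.mutation, exc)
            cand.record("energy-stage1", False, "unevaluated")
            continue
        cand.energies["stage1"] = e1
        if e1 > policy.stage1_threshold:
            cand.record("energy-stage1", False, "energy-stage1")
            continue
        cand.record("energy-stage1", True)
        try:
            e2 = evaluator_stage2.single(cand.mutation)
        except Exception as exc:
            logger.warning("stage-2 evaluation failed for %s: %s",
                           cand.mutation, exc)
            cand.record("energy-stage2", False, "unevaluated")
            continue
        cand.energies["stage2"] = e2
        if e2 > policy.stage2_threshold:
            cand.record("energy-stage2", False, "energy-stage2")
            continue
        cand.record("energy-stage2", True)
        survivors.append(cand)
    return survivors


def consensus_energy_filter(
    candidates: list[MutationCandidate],
    evaluator: EnergyEvaluator,
    threshold: float = 0.5,
    stabilizing_flag_threshold: float = -1.0,
) -> list[MutationCandidate]:
    """Energy check of the back-to-consensus branch.

    Consensus candidates are trusted evolutionarily; the energy check only
    removes clearly destabilizing ones (ddG > ``threshold``, default
    +0.5 kcal/mol).  Survivors that are also strongly stabilizing (ddG <=
    ``stabilizing_flag_threshold``) get an ``energy_stabilizing`` flag.
    """
    survivors: list[MutationCandidate] = []
    for cand in candidates:
        try:
            ddg = evaluator.single(cand.mutation)
        except Exception as exc:
            logger.warning("consensus evaluation failed for %s: %s",
                           cand.mutation, exc)
            cand.record("energy-consensus", False, "unevaluated")
            continue
        cand.energies["consensus"] = ddg
        if ddg > threshold:
            cand.record("energy-consensus", False, "energy-consensus")
            continue
        cand.record("energy-consensus", True)
        cand.annotations["energy_stabilizing"] = (
            ddg <= stabilizing_flag_threshold
        )
        survivors.append(cand)
    return survivors
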