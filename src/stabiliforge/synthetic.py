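"""Synthetic structures, alignments and energy landscapes with known ground
truth.

These generators make the whole pipeline runnable and testable without any
external structure, homolog database or force-field software:

* :func:`synth_structure` — an ideal alpha-helix backbone with CB stubs,
  seeded log-normal B-factors and optional engineered flexible residues;
* :func:`with_occlusion_shell` — wraps a residue in a spherical shell of
  dummy atoms, creating a guaranteed buried residue for SASA tests;
* :func:`synth_msa` — alignments with planted invariant columns,
  consensus-dominant columns and bijectively coupled column pairs;
* :func:`synth_landscape` — an energy evaluator realizing an explicit list
  of single ddGs with optional antagonistic/synergistic pair overrides.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._data import AMINO_ACIDS, BLOSUM62_BACKGROUND, ONE_TO_THREE
from .formats_io import Msa, Mutation, ResidueId, StructureModel

# Ideal alpha-helix geometry: 1.5 A rise and 100 degrees twist per residue;
# the helix radius is chosen so consecutive CA atoms sit 3.8 A apart.
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.28


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def synth_structure(
    n_residues: int,
    seed: int = 0,
    sequence: str | None = None,
    chain: str = "A",
    flexible_index: int | None = None,
    flexible_bfactor: float = 80.0,
) -> StructureModel:
    """Ideal alpha-helix with N/CA/C/O backbone and CB stubs.

    Per-residue B-factors are drawn from a seeded log-normal (median 20);
    ``flexible_index`` (a 1-based position) overrides one residue's
    B-factor to engineer a known most-flexible site.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    bfactors = np.exp(rng.normal(np.log(20.0), 0.3, size=n_residues))
    if flexible_index is not None:
        if not 1 <= flexible_index <= n_residues:
            raise ValueError("flexible_index outside the sequence")
        bfactors[flexible_index - 1] = flexible_bfactor

    chain_id, res_number, icode = [], [], []
    res_name, atom_name, element = [], [], []
    coords, occupancy, bfac = [], [], []

    def add(i: int, name3: str, aname: str, elem: str, xyz: np.ndarray) -> None:
        chain_id.append(chain)
        res_number.append(i + 1)
        icode.append("")
        res_name.append(name3)
        atom_name.append(aname)
        element.append(elem)
        coords.append(xyz)
        occupancy.append(1.0)
        bfac.append(bfactors[i])

    twist = np.deg2rad(HELIX_TWIST_DEG)
    for i in range(n_residues):
        theta = twist * i
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * i])
        # local tangent along the helix, for approximate N/C placement
        tangent = np.array([
            -HELIX_RADIUS * twist * np.sin(theta),
            HELIX_RADIUS * twist * np.cos(theta),
            HELIX_RISE,
        ])
        tangent /= np.linalg.norm(tangent)
        name3 = ONE_TO_THREE[sequence[i]]
        add(i, name3, "N", "N", ca - 1.46 * tangent)
        add(i, name3, "CA", "C", ca)
        add(i, name3, "C", "C", ca + 1.52 * tangent)
        add(i, name3, "O", "O", ca + 1.52 * tangent + 1.23 * radial)
        if sequence[i] != "G":
            add(i, name3, "CB", "C", ca + 1.53 * radial)

    return StructureModel(
        np.array(chain_id), np.array(res_number), np.array(icode),
        np.array(res_name), np.array(atom_name), np.array(element),
        np.array(coords), np.array(occupancy), np.array(bfac),
    )


def with_occlusion_shell(
    model: StructureModel,
    position: int,
    chain: str = "A",
    shell_radius: float = 6.0,
    n_shell: int = 400,
    shell_chain: str = "Z",
) -> StructureModel:
    """Enclose one residue in a spherical shell of dummy carbon atoms.

    The shell guarantees the residue is buried (near-zero SASA) — a
    constructed ground truth for the surface filter, not a physical model.
    """
    rid = ResidueId(chain, position)
    idx = model.residue_atom_indices(rid)
    center = model.coord[idx].mean(axis=0)
    shell = center + shell_radius * _fibonacci_sphere(n_shell)
    n = len(shell)
    return StructureModel(
        np.concatenate([model.chain_id, np.full(n, shell_chain)]),
        np.concatenate([model.res_number, np.arange(1, n + 1)]),
        np.concatenate([model.icode, np.full(n, "")]),
        np.concatenate([model.res_name, np.full(n, "ALA")]),
        np.concatenate([model.atom_name, np.full(n, "CB")]),
        np.concatenate([model.element, np.full(n, "C")]),
        np.concatenate([model.coord, shell]),
        np.concatenate([model.occupancy, np.ones(n)]),
        np.concatenate([model.bfactor, np.full(n, 20.0)]),
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def synth_msa(
    query: str,
    depth: int,
    conserved_positions: Sequence[int] = (),
    consensus_injections: Mapping[int, tuple[str, float]] | None = None,
    coupled_pairs: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    gap_rate: float = 0.0,
    query_id: str = "query",
    background_conservation: tuple[float, float] = (0.3, 0.6),
    coupled_symbols: int = 8,
) -> Msa:
    """Alignment with planted statistical structure.

    ``conserved_positions``: columns invariant at the query residue.
    ``consensus_injections``: {position: (residue, frequency)} places a
    non-wild-type residue at (approximately round(freq * depth) / depth)
    frequency.  ``coupled_pairs``: bijective residue mapping (over
    ``coupled_symbols`` residues) between two columns.  Remaining columns
    emulate ordinary homologous columns: each has its own consensus residue
    at a frequency drawn from ``background_conservation``, the rest sampled
    from the BLOSUM62 background — uniform 20-letter columns would be
    unrealistically diverse and would drown coupling signals in
    finite-sample noise.  Non-query rows get gaps at ``gap_rate``.
    Directives must not overlap.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    consensus_injections = dict(consensus_injections or {})
    n = len(query)
    claimed: set[int] = set()
    for pos in list(conserved_positions) + list(consensus_injections):
        if not 1 <= pos <= n:
            raise ValueError(f"position {pos} outside the query")
        if pos in claimed:
            raise ValueError(f"overlapping directives at position {pos}")
        claimed.add(pos)
    for a, b in coupled_pairs:
        for pos in (a, b):
            if not 1 <= pos <= n:
                raise ValueError(f"position {pos} outside the query")
            if pos in claimed:
                raise ValueError(f"overlapping directives at position {pos}")
            claimed.add(pos)

    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    bg = np.array([BLOSUM62_BACKGROUND[a] for a in aas])
    bg = bg / bg.sum()

    cols = np.empty((depth, n), dtype="U1")
    cols[0, :] = list(query)
    # default background columns: a dominant residue plus background noise
    lo, hi = background_conservation
    for c in range(n):
        level = rng.uniform(lo, hi)
        dominant = query[c]
        fill = rng.choice(aas, size=depth - 1, p=bg)
        keep = rng.random(depth - 1) < level
        fill[keep] = dominant
        cols[1:, c] = fill
    # conserved columns
    for pos in conserved_positions:
        cols[:, pos - 1] = query[pos - 1]
    # consensus-dominant columns
    for pos, (aa, freq) in consensus_injections.items():
        if aa == query[pos - 1]:
            raise ValueError(
                f"injection at {pos} must differ from the wild type"
            )
        k = int(round(freq * depth))
        others = [a for a in aas if a != aa]
        fill = rng.choice(others, size=depth - 1)
        cols[1:, pos - 1] = fill
        rows = rng.choice(np.arange(1, depth), size=min(k, depth - 1),
                          replace=False)
        cols[rows, pos - 1] = aa
    # coupled column pairs: bijective mapping over a small symbol set
    for a, b in coupled_pairs:
        symbols = rng.choice(aas, size=coupled_symbols, replace=False)
        mapped = rng.permutation(symbols)
        mapping = dict(zip(symbols, mapped))
        draw = rng.choice(symbols, size=depth)
        cols[:, a - 1] = draw
        cols[:, b - 1] = [mapping[s] for s in draw]
    # gaps in non-query rows of unclaimed columns
    if gap_rate > 0:
        for c in range(n):
            if (c + 1) in claimed:
                continue
            mask = rng.random(depth - 1) < gap_rate
            col = cols[1:, c]
            col[mask] = "-"
            cols[1:, c] = col

    ids = [query_id] + [f"seq{i}" for i in range(1, depth)]
    rows = ["".join(cols[i, :]) for i in range(depth)]
    return Msa(ids=ids, rows=rows, query_id=query_id)


# ---------------------------------------------------------------------------
# Energy landscapes
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSpec:
    """Explicit ground-truth landscape: singles plus pair overrides."""

    singles: dict[Mutation, float]
    pair_overrides: dict[frozenset, float] = field(default_factory=dict)
    contact_distance: float = 5.0
    far_distance: float = 20.0

    def __post_init__(self) -> None:
        for key in self.pair_overrides:
            pair = tuple(key)
            if len(pair) != 2:
                raise ValueError("pair overrides must reference two mutations")
            a, b = pair
            if a not in self.singles or b not in self.singles:
                raise ValueError(f"override references unknown mutation: {key}")
            if (a.chain, a.position) == (b.chain, b.position):
                raise ValueError(
                    f"override pairs mutations at the same position: {key}"
                )


class LandscapeEvaluator:
    """Evaluator realizing a :class:`LandscapeSpec` exactly."""

    def __init__(self, spec: LandscapeSpec) -> None:
        self.spec = spec

    def single(self, mutation: Mutation) -> float:
        if mutation not in self.spec.singles:
            raise LookupError(f"landscape has no mutation {mutation}")
        return float(self.spec.singles[mutation])

    def pair(self, mutation_a: Mutation, mutation_b: Mutation) -> float:
        if (mutation_a.chain, mutation_a.position) == (
            mutation_b.chain, mutation_b.position
        ):
            raise ValueError("same-position pair refused")
        key = frozenset((mutation_a, mutation_b))
        if key in self.spec.pair_overrides:
            return float(self.spec.pair_overrides[key])
        return self.single(mutation_a) + self.single(mutation_b)


def synth_landscape(
    spec: LandscapeSpec,
) -> tuple[LandscapeEvaluator, Callable[[Mutation, Mutation], float]]:
    """Evaluator plus a distance lookup placing overridden pairs in contact
    (inside the pair-evaluation radius) and all other pairs far apart."""
    evaluator = LandscapeEvaluator(spec)

    def distance_lookup(a: Mutation, b: Mutation) -> float:
        if frozenset((a, b)) in spec.pair_overrides:
            return spec.contact_distance
        return spec.far_distance

    return evaluator, distance_lookup
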