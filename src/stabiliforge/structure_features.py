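"""Structure-derived annotations.

Three ingredients of the filter cascade and the pair-energy graph come from
the structure: inter-residue distances (the 10 A pair-evaluation rule),
solvent accessibility (the surface-charge filter) and per-residue average
B-factors (flexibility ranking for rigidifying saturation targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._data import MAX_ASA, THREE_TO_ONE
from .formats_io import ResidueId, StructureModel

_HYDROGEN = {"H", "D"}

DISTANCE_METRICS = ("min_heavy", "ca", "cb")


def _heavy_coords(structure: StructureModel, rid: ResidueId) -> np.ndarray:
    idx = structure.residue_atom_indices(rid)
    heavy = [i for i in idx if structure.element[i] not in _HYDROGEN]
    if not heavy:
        raise ValueError(f"residue {rid} has no heavy atoms")
    return structure.coord[heavy]


def _metric_coords(
    structure: StructureModel, rid: ResidueId, metric: str
) -> np.ndarray:
    if metric == "min_heavy":
        return _heavy_coords(structure, rid)
    atom = {"ca": "CA", "cb": "CB"}[metric]
    idx = structure.residue_atom_indices(rid)
    names = structure.atom_name[idx]
    hit = idx[names == atom]
    if hit.size == 0 and metric == "cb":  # glycine fallback
        hit = idx[names == "CA"]
    if hit.size == 0:
        raise ValueError(f"residue {rid} lacks a {atom} atom")
    return structure.coord[hit[:1]]


def residue_min_distance(
    structure: StructureModel,
    res_a: ResidueId,
    res_b: ResidueId,
    metric: str = "min_heavy",
) -> float:
    """Distance between two residues in Angstrom.

    ``min_heavy`` (default) is the minimum over all heavy-atom pairs;
    ``ca``/``cb`` use single backbone/sidechain reference atoms.
    """
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"unknown distance metric {metric!r}")
    if res_a == res_b:
        return 0.0
    ca = _metric_coords(structure, res_a, metric)
    cb = _metric_coords(structure, res_b, metric)
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def distance_map(
    structure: StructureModel,
    residues: Iterable[ResidueId] | None = None,
    metric: str = "min_heavy",
) -> dict[tuple[ResidueId, ResidueId], float]:
    """Symmetric pairwise distance map over the given residues."""
    rids = list(residues) if residues is not None else structure.residue_ids
    out: dict[tuple[ResidueId, ResidueId], float] = {}
    for i, a in enumerate(rids):
        out[(a, a)] = 0.0
        for b in rids[i + 1:]:
            d = residue_min_distance(structure, a, b, metric=metric)
            out[(a, b)] = out[(b, a)] = d
    return out


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

@dataclass
class SurfaceAnnotation:
    """Per-residue SASA, relative SASA and the threshold used to flag
    surface residues."""

    residue_ids: list[ResidueId]
    sasa: np.ndarray
    rel_sasa: np.ndarray
    rel_threshold: float = 0.25

    @property
    def surface_flags(self) -> np.ndarray:
        return self.rel_sasa >= self.rel_threshold


def shrake_rupley_sasa(
    structure: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    rel_threshold: float = 0.25,
) -> SurfaceAnnotation:
    """Shrake-Rupley solvent-accessible surface area per residue.

    Sphere sampling with a deterministic Fibonacci point set and single-atom
    van der Waals radii; relative SASA divides by the residue type's
    theoretical maximum accessibility.  Atoms of unknown element fall back
    to a 1.8 A radius (treated as carbon) with a warning.
    """
    import biotite.structure as struc
    from biotite.structure.info import vdw_radius_single

    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    arr = structure.to_atom_array()
    unknown = [
        el for el in np.unique(arr.element) if vdw_radius_single(el) is None
    ]
    if unknown:
        warnings.warn(
            f"unknown element radii for {unknown}; using carbon-like 1.8 A",
            stacklevel=2,
        )
        arr.element[np.isin(arr.element, unknown)] = "C"
    atom_sasa = struc.sasa(
        arr, probe_radius=probe, point_number=n_points, vdw_radii="Single"
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    residue_ids = structure.residue_ids
    res_names = structure.residue_names
    sasa = np.zeros(len(residue_ids))
    rel = np.zeros(len(residue_ids))
    for i, (rid, name) in enumerate(zip(residue_ids, res_names)):
        idx = structure.residue_atom_indices(rid)
        sasa[i] = atom_sasa[idx].sum()
        one = THREE_TO_ONE.get(name)
        max_asa = MAX_ASA.get(one, float(np.mean(list(MAX_ASA.values()))))
        rel[i] = sasa[i] / max_asa
    return SurfaceAnnotation(
        residue_ids=residue_ids, sasa=sasa, rel_sasa=rel,
        rel_threshold=rel_threshold,
    )


def surface_mask(
    annotation: SurfaceAnnotation, rel_threshold: float | None = None
) -> set[ResidueId]:
    """Residues whose relative SASA is at or above the threshold."""
    thr = annotation.rel_threshold if rel_threshold is None else rel_threshold
    return {
        rid
        for rid, rel in zip(annotation.residue_ids, annotation.rel_sasa)
        if rel >= thr
    }


# ---------------------------------------------------------------------------
# B-factor flexibility
# ---------------------------------------------------------------------------

@dataclass
class FlexibilityTrack:
    """Per-residue mean B-factors, z-scores and a descending-flexibility
    ranking (ties resolved toward the lower residue number)."""

    residue_ids: list[ResidueId]
    mean_bfactor: np.ndarray
    zscores: np.ndarray
    ranking: list[ResidueId]


def residue_avg_bfactor(structure: StructureModel) -> FlexibilityTrack:
    """Average the atomic B-factors of each residue and rank by flexibility."""
    residue_ids = structure.residue_ids
    if not residue_ids:
        raise ValueError("structure has no residues")
    means = np.array([
        float(structure.bfactor[structure.residue_atom_indices(rid)].mean())
        for rid in residue_ids
    ])
    if np.allclose(means, 0.0):
        warnings.warn(
            "all B-factors are zero or missing; flexibility ranking falls "
            "back to residue order", stacklevel=2,
        )
        z = np.zeros_like(means)
        ranking = list(residue_ids)
        return FlexibilityTrack(residue_ids, means, z, ranking)
    std = means.std()
    z = (means - means.mean()) / std if std > 0 else np.zeros_like(means)
    order = sorted(
        range(len(residue_ids)),
        key=lambda i: (-means[i], residue_ids[i].chain,
                       residue_ids[i].number, residue_ids[i].icode),
    )
    ranking = [residue_ids[i] for i in order]
    return FlexibilityTrack(residue_ids, means, z, ranking)


def flexible_positions(
    track: FlexibilityTrack,
    top_n: int | None = None,
    z_min: float | None = None,
) -> list[ResidueId]:
    """Most flexible residues, as saturation-mutagenesis targets.

    Either the ``top_n`` residues by mean B-factor or all residues with
    z-score >= ``z_min``; exactly one selector must be given.
    """
    if (top_n is None) == (z_min is None):
        raise ValueError("give exactly one of top_n or z_min")
    if z_min is not None:
        by_id = dict(zip(track.residue_ids, track.zscores))
        return [rid for rid in track.ranking if by_id[rid] >= z_min]
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > len(track.ranking):
        warnings.warn(
            f"top_n={top_n} exceeds residue count {len(track.ranking)}; "
            "returning all residues", stacklevel=2,
        )
        top_n = len(track.ranking)
    return track.ranking[:top_n]
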