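"""Per-column conservation and inter-column correlation of an MSA.

Conservation is the Jensen-Shannon divergence of the column's amino-acid
distribution from a background distribution (BLOSUM62 frequencies by
default), gap-penalised and window-smoothed, then discretised to a 0-9
grade (grade 0 = most conserved).  Correlated column pairs are called by a
consensus over several coevolution statistics (mutual information, its
average-product-corrected variant, OMES and McBASC ship with the package;
further methods plug in by name).  A pair flagged by enough methods marks
both of its columns as correlated, and correlated positions are excluded
from mutagenesis downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ._data import AA_INDEX, AMINO_ACIDS, BLOSUM62_BACKGROUND, GAP_CHARS
from .formats_io import Msa

N_REFERENCE_METHODS = 7  # size of the method panel the 3.5 default assumes


# ---------------------------------------------------------------------------
# Column encoding helpers
# ---------------------------------------------------------------------------

def _encode(msa: Msa) -> np.ndarray:
    """Encode the MSA as int codes: 0..19 amino acids, -1 gap/unknown."""
    mat = msa.matrix
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for aa, idx in AA_INDEX.items():
        codes[mat == aa] = idx
    return codes


@dataclass
class ColumnProfile:
    """Amino-acid counts, gap fraction and depth of one alignment column."""

    counts: np.ndarray  # length 20, order of AMINO_ACIDS
    gap_fraction: float
    depth: int

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(20)
        return self.counts / total


def column_profiles(msa: Msa) -> list[ColumnProfile]:
    codes = _encode(msa)
    mat = msa.matrix
    profiles = []
    for c in range(msa.n_cols):
        col = codes[:, c]
        counts = np.bincount(col[col >= 0], minlength=20).astype(float)
        gaps = int(np.isin(mat[:, c], list(GAP_CHARS)).sum())
        profiles.append(
            ColumnProfile(counts=counts, gap_fraction=gaps / msa.depth,
                          depth=msa.depth)
        )
    return profiles


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationTrack:
    """Per-column JSD conservation scores and 0-9 grades."""

    scores: np.ndarray
    grades: np.ndarray

    def grade_for_column(self, col: int) -> int:
        return int(self.grades[col])


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits (base 2); bounded by 1."""
    r = 0.5 * (p + q)
    kl_pr = sum(
        pi * math.log2(pi / ri) for pi, ri in zip(p, r) if pi > 0
    )
    kl_qr = sum(
        qi * math.log2(qi / ri) for qi, ri in zip(q, r) if qi > 0
    )
    return 0.5 * kl_pr + 0.5 * kl_qr


def background_vector(background: Mapping[str, float] | None = None) -> np.ndarray:
    bg = BLOSUM62_BACKGROUND if background is None else background
    vec = np.array([bg[aa] for aa in AMINO_ACIDS], dtype=float)
    if not math.isclose(vec.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background distribution must sum to 1")
    return vec / vec.sum()


def jsd_conservation(
    msa: Msa,
    background: Mapping[str, float] | None = None,
    window: int = 3,
    window_weight: float = 0.5,
) -> ConservationTrack:
    """Gap-penalised, window-smoothed JSD conservation per column.

    The raw column score is ``JSD(p, background) * (1 - gap_fraction)``;
    the final score mixes it with the mean raw score of up to ``window``
    columns on each side: ``(1 - w) * own + w * neighbour_mean``.
    """
    if msa.depth < 2:
        raise ValueError("conservation scoring needs an alignment of depth >= 2")
    if not 0.0 <= window_weight <= 1.0:
        raise ValueError("window_weight must be in [0, 1]")
    q = background_vector(background)
    profiles = column_profiles(msa)
    if all(p.gap_fraction >= 1.0 for p in profiles):
        raise ValueError("alignment consists entirely of gaps")
    raw = np.zeros(msa.n_cols)
    for c, prof in enumerate(profiles):
        if prof.gap_fraction >= 1.0:
            raw[c] = 0.0
            continue
        raw[c] = _jsd(prof.frequencies, q) * (1.0 - prof.gap_fraction)
    if window <= 0 or window_weight == 0.0:
        scores = raw.copy()
    else:
        scores = np.empty_like(raw)
        for c in range(len(raw)):
            lo, hi = max(0, c - window), min(len(raw), c + window + 1)
            neigh = [raw[i] for i in range(lo, hi) if i != c]
            mean = float(np.mean(neigh)) if neigh else raw[c]
            scores[c] = (1.0 - window_weight) * raw[c] + window_weight * mean
    return ConservationTrack(scores=scores, grades=conservation_grades(scores))


def conservation_grades(scores: np.ndarray) -> np.ndarray:
    """Decile grades from strict score ranks; grade 0 = most conserved.

    ``grade = min(9, floor(10 * fraction of columns with strictly greater
    score))``, so the highest-scoring (most conserved) column gets 0 and
    ties share a grade.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scored columns")
    n = scores.size
    greater = (scores[None, :] > scores[:, None]).sum(axis=1)
    return np.minimum(9, (10 * greater) // n).astype(int)


# ---------------------------------------------------------------------------
# Correlation methods
# ---------------------------------------------------------------------------

def _joint_valid(codes: np.ndarray, i: int, j: int) -> np.ndarray:
    return (codes[:, i] >= 0) & (codes[:, j] >= 0)


def mi_matrix(msa: Msa) -> np.ndarray:
    """Mutual information (bits) between columns, over jointly non-gapped
    sequences; pairs with fewer than two such sequences score 0."""
    if msa.depth < 2:
        raise ValueError("correlation scoring needs depth >= 2")
    codes = _encode(msa)
    n = msa.n_cols
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = _joint_valid(codes, i, j)
            if valid.sum() < 2:
                continue
            ci, cj = codes[valid, i], codes[valid, j]
            m = valid.sum()
            joint: dict[tuple[int, int], int] = {}
            for a, b in zip(ci, cj):
                joint[(a, b)] = joint.get((a, b), 0) + 1
            pi = np.bincount(ci, minlength=20) / m
            pj = np.bincount(cj, minlength=20) / m
            mi = 0.0
            for (a, b), cnt in joint.items():
                pab = cnt / m
                mi += pab * math.log2(pab / (pi[a] * pj[b]))
            out[i, j] = out[j, i] = max(mi, 0.0)
    return out


def omes_matrix(msa: Msa) -> np.ndarray:
    """Observed-minus-expected-squared covariation between columns."""
    if msa.depth < 2:
        raise ValueError("correlation scoring needs depth >= 2")
    codes = _encode(msa)
    n = msa.n_cols
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = _joint_valid(codes, i, j)
            m = int(valid.sum())
            if m < 2:
                continue
            ci, cj = codes[valid, i], codes[valid, j]
            joint: dict[tuple[int, int], int] = {}
            for a, b in zip(ci, cj):
                joint[(a, b)] = joint.get((a, b), 0) + 1
            ni = np.bincount(ci, minlength=20)
            nj = np.bincount(cj, minlength=20)
            score = 0.0
            seen_pairs = {
                (a, b) for a in np.flatnonzero(ni) for b in np.flatnonzero(nj)
            }
            for a, b in seen_pairs:
                obs = joint.get((a, b), 0)
                exp = ni[a] * nj[b] / m
                score += (obs - exp) ** 2 / m
            out[i, j] = out[j, i] = score
    return out


def _mclachlan_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load("MCLACHLAN")
    table = np.zeros((20, 20))
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            table[AA_INDEX[a], AA_INDEX[b]] = sub[a, b]
    return table


def mcbasc_matrix(
    msa: Msa, substitution_matrix: np.ndarray | None = None
) -> np.ndarray:
    """McBASC: Pearson correlation of substitution-score vectors.

    For each column, every sequence pair contributes the substitution score
    (McLachlan by default) of its two residues; two columns correlate if
    these vectors do.  Columns with zero score variance contribute 0.
    """
    if msa.depth < 2:
        raise ValueError("correlation scoring needs depth >= 2")
    table = _mclachlan_matrix() if substitution_matrix is None else substitution_matrix
    codes = _encode(msa)
    n = msa.n_cols
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = _joint_valid(codes, i, j)
            m = int(valid.sum())
            if m < 2:
                continue
            ci, cj = codes[valid, i], codes[valid, j]
            iu = np.triu_indices(m, k=1)
            si = table[ci[:, None], ci[None, :]][iu]
            sj = table[cj[:, None], cj[None, :]][iu]
            if si.std() == 0.0 or sj.std() == 0.0:
                continue
            r = float(np.corrcoef(si, sj)[0, 1])
            out[i, j] = out[j, i] = r
    return out


def apc_correction(matrix: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric coupling matrix.

    ``out(i,j) = in(i,j) - mean_i * mean_j / mean_all`` with means over the
    off-diagonal entries; an all-zero matrix is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("expected a symmetric matrix")
    n = matrix.shape[0]
    if n < 2:
        return matrix.copy()
    off = matrix - np.diag(np.diag(matrix))
    mean_i = off.sum(axis=1) / (n - 1)
    mean_all = off.sum() / (n * (n - 1))
    if mean_all == 0.0:
        return matrix.copy()
    out = matrix - np.outer(mean_i, mean_i) / mean_all
    np.fill_diagonal(out, 0.0)
    return out


def amic_matrix(msa: Msa) -> np.ndarray:
    """Average-product-corrected mutual information."""
    return apc_correction(mi_matrix(msa))


# Registry of correlation methods: any callable Msa -> symmetric matrix may
# be registered; DCA/SCA/ELSC-style scores plug in here.
CORRELATION_METHODS: dict[str, Callable[[Msa], np.ndarray]] = {
    "MI": mi_matrix,
    "aMIc": amic_matrix,
    "OMES": omes_matrix,
    "McBASC": mcbasc_matrix,
}


def register_correlation_method(
    name: str, fn: Callable[[Msa], np.ndarray]
) -> None:
    CORRELATION_METHODS[name] = fn


def compute_correlations(
    msa: Msa, methods: list[str] | None = None
) -> dict[str, np.ndarray]:
    names = list(CORRELATION_METHODS) if methods is None else methods
    return {name: CORRELATION_METHODS[name](msa) for name in names}


# ---------------------------------------------------------------------------
# Consensus over methods
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Per-method matrices, per-pair consensus votes and the correlated
    column set."""

    method_matrices: dict[str, np.ndarray]
    consensus_counts: np.ndarray
    effective_threshold: float
    correlated_columns: set[int] = field(default_factory=set)


def consensus_correlated(
    method_matrices: Mapping[str, np.ndarray],
    flag_fraction: float = 0.01,
    threshold: float = 3.5,
    n_reference_methods: int = N_REFERENCE_METHODS,
) -> CorrelationResult:
    """Consensus call of correlated columns.

    Each method flags its top ``flag_fraction`` of off-diagonal pairs by
    score (ties at the cutoff are all kept; non-positive scores are never
    flagged).  A pair's consensus is the number of flagging methods; with k
    methods the decision threshold is rescaled to ``threshold * k /
    n_reference_methods``.  A column is correlated if it belongs to at
    least one pair at or above that threshold.
    """
    if not method_matrices:
        raise ValueError("at least one correlation method matrix is required")
    if not 0.0 < flag_fraction <= 1.0:
        raise ValueError("flag_fraction must be in (0, 1]")
    names = sorted(method_matrices)
    shapes = {method_matrices[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError("method matrices must share a shape")
    n = next(iter(shapes))[0]
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    n_pairs = len(iu[0])
    n_flag = max(1, math.ceil(flag_fraction * n_pairs))
    for name in names:
        scores = np.asarray(method_matrices[name], dtype=float)[iu]
        positive = scores[scores > 0]
        if positive.size == 0:
            continue
        cutoff = np.sort(positive)[::-1][min(n_flag, positive.size) - 1]
        flagged = (scores >= cutoff) & (scores > 0)
        counts[iu[0][flagged], iu[1][flagged]] += 1
    counts = counts + counts.T
    k = len(names)
    effective = threshold * k / n_reference_methods
    correlated: set[int] = set()
    hit_i, hit_j = np.nonzero(np.triu(counts, k=1) >= effective)
    for a, b in zip(hit_i, hit_j):
        correlated.add(int(a))
        correlated.add(int(b))
    return CorrelationResult(
        method_matrices=dict(method_matrices),
        consensus_counts=counts,
        effective_threshold=effective,
        correlated_columns=correlated,
    )
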