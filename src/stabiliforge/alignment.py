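"""Global pairwise alignment and identity/coverage measures.

A single Needleman-Wunsch parameterisation (BLOSUM62, affine gaps with
open 10 / extend 0.5) is shared by homolog curation and by the extraction
of ancestral substitutions, so identities are comparable across the
pipeline.  Alignment itself is delegated to Biopython's PairwiseAligner.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from ._data import AA_SET

_ALLOWED = AA_SET | {"X"}


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _check(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"{label} sequence has invalid letters: {sorted(bad)}")
    return seq


def needleman_wunsch(seq_a: str, seq_b: str) -> tuple[str, str, float]:
    """Optimal global alignment; returns gapped rows and the score."""
    seq_a = _check(seq_a, "first")
    seq_b = _check(seq_b, "second")
    alignment = _aligner().align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Optimal global alignment score only."""
    seq_a = _check(seq_a, "first")
    seq_b = _check(seq_b, "second")
    return float(_aligner().score(seq_a, seq_b))


def _trimmed_columns(row_a: str, row_b: str) -> tuple[int, int]:
    """Column range [start, stop) excluding terminal-gap overhangs."""
    n = len(row_a)
    start_a = next(i for i, c in enumerate(row_a) if c != "-")
    start_b = next(i for i, c in enumerate(row_b) if c != "-")
    stop_a = n - next(i for i, c in enumerate(reversed(row_a)) if c != "-")
    stop_b = n - next(i for i, c in enumerate(reversed(row_b)) if c != "-")
    return max(start_a, start_b), min(stop_a, stop_b)


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the global alignment.

    Denominator: aligned columns excluding terminal-gap overhangs.  ``X``
    never counts as a match.  Symmetric by construction (the pair is
    canonically ordered before aligning).
    """
    seq_a = _check(seq_a, "first")
    seq_b = _check(seq_b, "second")
    if seq_b < seq_a:  # canonical order makes the measure exactly symmetric
        seq_a, seq_b = seq_b, seq_a
    row_a, row_b, _ = needleman_wunsch(seq_a, seq_b)
    start, stop = _trimmed_columns(row_a, row_b)
    if stop <= start:
        return 0.0
    matches = sum(
        1
        for i in range(start, stop)
        if row_a[i] == row_b[i] and row_a[i] != "-" and row_a[i] != "X"
    )
    return matches / (stop - start)


def identity_and_coverage(query: str, subject: str) -> tuple[float, float]:
    """Identity (as :func:`global_identity`) plus query coverage.

    Coverage is the fraction of query positions aligned to a subject
    residue (non-gap in both rows) in the same global alignment.
    """
    query = _check(query, "query")
    subject = _check(subject, "subject")
    row_q, row_s, _ = needleman_wunsch(query, subject)
    aligned_query = sum(
        1 for a, b in zip(row_q, row_s) if a != "-" and b != "-"
    )
    return global_identity(query, subject), aligned_query / len(query)
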