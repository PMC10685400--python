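"""Curation of the homolog sequence set.

Mirrors the usual pre-alignment pipeline: sequences whose identity to the
query falls outside a window (30-90% by default, inclusive bounds) are
dropped, the survivors are clustered greedily at 90% identity (an exact
re-statement of UCLUST's length-sorted greedy pass, without its word-index
heuristics) and one representative per cluster is kept, sorted by query
coverage and capped at 200 sequences for the downstream alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import global_identity, identity_and_coverage


@dataclass
class HomologRecord:
    """A homolog with its identity and coverage relative to the query."""

    id: str
    sequence: str
    identity_to_query: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if not 0.0 <= self.identity_to_query <= 1.0:
            raise ValueError(f"{self.id}: identity outside [0, 1]")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"{self.id}: coverage outside [0, 1]")


@dataclass
class Cluster:
    representative: HomologRecord
    members: list[HomologRecord] = field(default_factory=list)


def annotate_homologs(query: str, sequences: dict[str, str]) -> list[HomologRecord]:
    """Compute identity and query coverage for every homolog."""
    records = []
    for seq_id, seq in sequences.items():
        ident, cov = identity_and_coverage(query, seq)
        records.append(HomologRecord(seq_id, seq, ident, min(cov, 1.0)))
    return records


def filter_by_identity(
    homologs: list[HomologRecord],
    min_identity: float = 0.30,
    max_identity: float = 0.90,
) -> list[HomologRecord]:
    """Keep homologs with identity inside the window (bounds inclusive)."""
    if not 0.0 <= min_identity < max_identity <= 1.0:
        raise ValueError("need 0 <= min_identity < max_identity <= 1")
    return [
        h for h in homologs
        if min_identity <= h.identity_to_query <= max_identity
    ]


def greedy_cluster(
    homologs: list[HomologRecord], threshold: float = 0.90
) -> list[Cluster]:
    """Greedy identity clustering of length-sorted sequences.

    Sequences are processed in descending length order (ties keep input
    order); each joins the first existing representative with identity >=
    ``threshold``, otherwise it founds a new cluster.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(
        enumerate(homologs), key=lambda t: (-len(t[1].sequence), t[0])
    )
    clusters: list[Cluster] = []
    for _, rec in ordered:
        for cluster in clusters:
            if global_identity(rec.sequence,
                               cluster.representative.sequence) >= threshold:
                cluster.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    return clusters


def select_representatives(
    clusters: list[Cluster], cap: int = 200
) -> list[HomologRecord]:
    """One representative per cluster, best query coverage first.

    Sort keys: coverage descending, then identity descending, then id;
    the list is truncated to ``cap`` entries.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    reps = sorted(
        (c.representative for c in clusters),
        key=lambda r: (-r.query_coverage, -r.identity_to_query, r.id),
    )
    return reps[:cap]


def curate_homologs(
    query: str,
    sequences: dict[str, str],
    min_identity: float = 0.30,
    max_identity: float = 0.90,
    cluster_threshold: float = 0.90,
    cap: int = 200,
) -> list[HomologRecord]:
    """Full curation pass: window filter, clustering, capped selection."""
    records = annotate_homologs(query, sequences)
    kept = filter_by_identity(records, min_identity, max_identity)
    clusters = greedy_cluster(kept, cluster_threshold)
    return select_representatives(clusters, cap)
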