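"""Redundancy reduction and same-strand overlap resolution.

Homologous targets produce many calls of the same gene. Calls on one
(contig, strand) are clustered greedily: ordered by the contig start of
their first exon (sub-ordered by decreasing exon count), the first
unassigned call seeds a cluster and is its tentative representative;
following calls whose start lies before the representative's last exon end
are assigned to the cluster iff they share an exon id with it. The final
prediction of each cluster is its highest-scoring member. Predictions that
overlap a better-E-value prediction on the same strand are then removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from splicecall.spliced_join import GeneCall


@dataclass
class CallCluster:
    members: list[GeneCall]
    tentative_representative: GeneCall

    @property
    def prediction(self) -> GeneCall:
        return max(
            self.members, key=lambda c: (c.S_set, -c.e_value, c.target_id)
        )

    @property
    def m(self) -> int:
        """Last contig position of the tentative representative's last exon
        (in scan direction)."""
        rep = self.tentative_representative
        return rep.span_high if rep.strand == "+" else rep.span_low


def _scan_key(call: GeneCall) -> tuple:
    # contig start of the first exon in scan direction; minus-strand scans
    # right-to-left so coordinates are mirrored
    start = call.first_exon_sc if call.strand == "+" else -call.first_exon_sc
    return (start, -call.k, call.target_id)


def cluster_calls(calls: list[GeneCall]) -> list[CallCluster]:
    """Greedy single-pass clustering of calls from one (contig, strand)."""
    if not calls:
        return []
    key0 = (calls[0].contig_id, calls[0].strand)
    if any((c.contig_id, c.strand) != key0 for c in calls):
        raise ValueError("cluster_calls expects calls from one contig and strand")
    minus = calls[0].strand == "-"
    ordered = sorted(calls, key=_scan_key)
    assigned = [False] * len(ordered)
    clusters: list[CallCluster] = []
    for i, seed in enumerate(ordered):
        if assigned[i]:
            continue
        assigned[i] = True
        cluster = CallCluster(members=[seed], tentative_representative=seed)
        rep_exons = seed.exon_ids
        m = cluster.m
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            cand = ordered[j]
            start = cand.first_exon_sc
            inside = (start < m) if not minus else (start > m)
            if not inside:
                break
            if rep_exons & cand.exon_ids:
                cluster.members.append(cand)
                assigned[j] = True
        clusters.append(cluster)
    return clusters


def resolve_overlaps(predictions: list[GeneCall]) -> list[GeneCall]:
    """E-value-ascending scan keeping only non-overlapping predictions.

    Overlap means the contig spans share at least one nucleotide. Ties on
    E-value break by higher bit-score, then smaller span start, then target
    id. Output is ordered by contig position.
    """
    if not predictions:
        return []
    key0 = (predictions[0].contig_id, predictions[0].strand)
    if any((p.contig_id, p.strand) != key0 for p in predictions):
        raise ValueError("resolve_overlaps expects one contig and strand")
    ordered = sorted(
        predictions,
        key=lambda p: (p.e_value, -p.S_set, p.span_low, p.target_id),
    )
    kept: list[GeneCall] = []
    for p in ordered:
        if all(
            p.span_high <= q.span_low or q.span_high <= p.span_low for q in kept
        ):
            kept.append(p)
    kept.sort(key=lambda p: p.span_low)
    return kept


def reduce_calls(calls: list[GeneCall]) -> tuple[list[GeneCall], int]:
    """Cluster and resolve all calls; returns (predictions, n_clusters)."""
    predictions: list[GeneCall] = []
    n_clusters = 0
    keyfn = lambda c: (c.contig_id, c.strand)
    for _, group in groupby(sorted(calls, key=keyfn), key=keyfn):
        clusters = cluster_calls(list(group))
        n_clusters += len(clusters)
        reps = [cl.prediction for cl in clusters]
        predictions.extend(resolve_overlaps(reps))
    predictions.sort(key=lambda p: (p.contig_id, p.span_low, p.strand))
    return predictions, n_clusters


def dedup_identical_proteins(predictions: list[GeneCall]) -> list[GeneCall]:
    """Collapse predictions with identical protein strings (helper)."""
    seen: dict[str, GeneCall] = {}
    for p in predictions:
        cur = seen.get(p.protein)
        if cur is None or p.e_value < cur.e_value:
            seen[p.protein] = p
    return sorted(seen.values(), key=lambda p: (p.contig_id, p.span_low))
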