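"""Taxonomic labels for predictions (best annotated hit, identity-dependent
rank truncation) and for contigs (best labeled prediction)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

RANKS = (
    "domain", "kingdom", "phylum", "class", "order", "family", "genus", "species"
)

# identity must EXCEED the cutoff to be assigned at that rank
IDENTITY_CUTOFFS = (
    (0.95, "species"),
    (0.80, "genus"),
    (0.65, "family"),
    (0.50, "order"),
    (0.40, "class"),
    (0.30, "phylum"),
    (0.20, "kingdom"),
)


@dataclass(frozen=True)
class Lineage:
    """Ranked labels from domain downward; present ranks are contiguous."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) > len(RANKS):
            raise ValueError("lineage deeper than supported ranks")

    @classmethod
    def from_list(cls, labels) -> "Lineage":
        return cls(labels=tuple(labels))

    def truncate_at(self, rank: str) -> "Lineage":
        """Keep ranks down to ``rank``; skips to the nearest present
        ancestor when the lineage is shallower."""
        depth = RANKS.index(rank) + 1
        return Lineage(labels=self.labels[:depth])

    @property
    def deepest_rank(self) -> str | None:
        return RANKS[len(self.labels) - 1] if self.labels else None

    def __str__(self) -> str:
        return ";".join(self.labels)


def rank_for_identity(identity: float) -> str:
    """Rank permitted by a prediction-to-target sequence identity."""
    for cutoff, rank in IDENTITY_CUTOFFS:
        if identity > cutoff:
            return rank
    return "domain"


@dataclass(frozen=True)
class TaxHit:
    target_id: str
    bit_score: float
    e_value: float
    identity: float


def assign_prediction_taxonomy(
    prediction_hits: list[TaxHit],
    lineages: dict[str, Lineage],
    max_evalue: float = 1e-5,
) -> Lineage | None:
    """Label from the best-bit-score hit with E < ``max_evalue``.

    The lineage is truncated at the rank the hit's identity allows; returns
    ``None`` (unassigned) when no hit qualifies or the best hit's target
    has no lineage.
    """
    qualifying = [h for h in prediction_hits if h.e_value < max_evalue]
    if not qualifying:
        return None
    best = max(
        qualifying, key=lambda h: (h.bit_score, -h.e_value, h.target_id)
    )
    lineage = lineages.get(best.target_id)
    if lineage is None:
        logger.warning("target %s has no lineage; unassigned", best.target_id)
        return None
    return lineage.truncate_at(rank_for_identity(best.identity))


def assign_contig_taxonomy(
    contig_predictions: list[tuple[Lineage | None, float]],
) -> Lineage | None:
    """Label of the smallest-E-value labeled prediction on the contig."""
    labeled = [(lin, ev) for lin, ev in contig_predictions if lin is not None]
    if not labeled:
        return None
    return min(labeled, key=lambda x: (x[1], str(x[0])))[0]


def krona_rows(labels: list[Lineage | None]) -> list[tuple[str, int]]:
    """Plain-TSV summary: semicolon node path -> count (deterministic)."""
    counts: dict[str, int] = {}
    for lin in labels:
        key = str(lin) if lin is not None else "unassigned"
        counts[key] = counts.get(key, 0) + 1
    return sorted(counts.items())
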