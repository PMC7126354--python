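"""End-to-end orchestration of the five prediction stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from splicecall import reduce as reduce_mod
from splicecall import search, spliced_join, translate
from splicecall.config import RunConfig
from splicecall.seqio import Contig, ReferenceDB

logger = logging.getLogger(__name__)


@dataclass
class PredictResult:
    predictions: list
    calls: list
    counts: dict[str, int] = field(default_factory=dict)


def predict(
    contigs: list[Contig],
    reference_db: ReferenceDB,
    cfg: RunConfig | None = None,
    hits=None,
    invert: bool = False,
) -> PredictResult:
    """Run translate -> search -> spliced join -> reduce on a set of contigs.

    ``hits`` may carry externally computed local hits (skips the built-in
    search). ``invert=True`` character-reverses every fragment before the
    search — the null model in which every prediction is a false positive.
    """
    cfg = cfg or RunConfig()
    fragments = []
    for contig in contigs:
        fragments.extend(
            translate.extract_fragments(
                contig, cfg.genetic_code, cfg.min_fragment_aa
            )
        )
    if invert:
        fragments = translate.invert_fragments(fragments)
    counts = {"contigs": len(contigs), "fragments": len(fragments)}
    if hits is None:
        if reference_db.targets:
            hits = search.search_fragments(
                fragments,
                reference_db,
                cfg.scoring,
                max_exon_evalue=cfg.max_exon_evalue,
                prefilter_kmer=cfg.prefilter_kmer,
                exhaustive=cfg.exhaustive_search,
            )
        else:
            hits = []
    counts["hits"] = len(hits)
    groups = spliced_join.build_putative_exons(hits, fragments, cfg.min_exon_aa)
    counts["putative_exons"] = sum(len(v) for v in groups.values())
    calls = spliced_join.join_all_groups(groups, max(reference_db.D, 1), cfg)
    counts["calls"] = len(calls)
    target_lengths = {t.id: t.length for t in reference_db.targets}
    kept = spliced_join.filter_calls(
        calls, target_lengths, cfg.max_call_evalue, cfg.min_tcov
    )
    counts["calls_after_filter"] = len(kept)
    predictions, n_clusters = reduce_mod.reduce_calls(kept)
    counts["clusters"] = n_clusters
    counts["predictions"] = len(predictions)
    logger.info("pipeline counts: %s", counts)
    return PredictResult(predictions=predictions, calls=kept, counts=counts)
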