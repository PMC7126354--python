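"""Benchmark harness: mapping predictions to gold annotations, exon
coverage, sensitivity under identity exclusions, precision-recall, split
genes, the inverted-fragment null model, and scaffold fragmentation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve

from splicecall import pipeline
from splicecall.config import RunConfig, ScoringScheme
from splicecall.search import make_aligner
from splicecall.seqio import AnnotationGene, Contig, ReferenceDB


@dataclass
class Mapping:
    """A prediction globally mapped to an annotated gene."""

    prediction_idx: int
    gene_id: str
    overlap_fraction: float        # of the larger requirement side actually met
    mismatch_fraction: float
    exon_covered: list[bool]

    @property
    def exon_coverage_fraction(self) -> float:
        return sum(self.exon_covered) / len(self.exon_covered)


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def protein_mismatch_fraction(
    prot_a: str, prot_b: str, scheme: ScoringScheme | None = None
) -> float:
    """Mismatch fraction of an end-gap-free global alignment.

    Mismatches are aligned non-identical residue pairs; gap columns count
    toward the alignment length but not as mismatches.
    """
    if not prot_a or not prot_b:
        return 1.0
    aligner = make_aligner(scheme or ScoringScheme(), mode="global")
    aln = next(iter(aligner.align(prot_a, prot_b)))
    a_blocks, b_blocks = aln.aligned[0], aln.aligned[1]
    n_mm = aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        aligned_cols += a1 - a0
        n_mm += sum(x != y for x, y in zip(prot_a[a0:a1], prot_b[b0:b1]))
    if not aligned_cols:
        return 1.0
    a_lo, a_hi = a_blocks[0][0], a_blocks[-1][1]
    b_lo, b_hi = b_blocks[0][0], b_blocks[-1][1]
    gap_cols = (a_hi - a_lo) + (b_hi - b_lo) - 2 * aligned_cols
    return n_mm / (aligned_cols + gap_cols)


def exon_coverage(
    pred_intervals: list[tuple[int, int]],
    ann_intervals: list[tuple[int, int]],
    min_cov: float = 0.8,
) -> list[bool]:
    """Annotated exon covered iff some predicted exon overlaps >= 80% of it."""
    flags = []
    for a in ann_intervals:
        alen = a[1] - a[0]
        flags.append(
            any(_span_overlap(p, a) >= min_cov * alen for p in pred_intervals)
        )
    return flags


def map_predictions(
    predictions,
    annotations: list[AnnotationGene],
    min_span_overlap: float = 0.8,
    max_mismatch: float = 0.1,
    scheme: ScoringScheme | None = None,
) -> list[Mapping]:
    """Globally map predictions to annotated genes.

    A prediction maps to a gene when their boundary spans overlap by at
    least 80% of the global contig length of either of them and their
    protein alignment has less than 10% mismatches. A prediction maps to at
    most one gene (best span overlap); a gene may receive several
    predictions.
    """
    by_contig: dict[str, list[AnnotationGene]] = {}
    for g in annotations:
        by_contig.setdefault(g.contig_id, []).append(g)
    mappings: list[Mapping] = []
    for pi, pred in enumerate(predictions):
        pspan = (pred.span_low, pred.span_high)
        plen = pspan[1] - pspan[0]
        best: Mapping | None = None
        best_ov = -1
        for gene in by_contig.get(pred.contig_id, []):
            gspan = gene.span
            glen = gspan[1] - gspan[0]
            ov = _span_overlap(pspan, gspan)
            if ov < min_span_overlap * min(plen, glen):
                continue
            mm = protein_mismatch_fraction(pred.protein, gene.protein, scheme)
            if mm >= max_mismatch:
                continue
            if ov > best_ov:
                best_ov = ov
                best = Mapping(
                    prediction_idx=pi,
                    gene_id=gene.gene_id,
                    overlap_fraction=ov / min(plen, glen),
                    mismatch_fraction=mm,
                    exon_covered=exon_coverage(
                        pred.exon_contig_intervals(), gene.exons
                    ),
                )
        if best is not None:
            mappings.append(best)
    return mappings


def sensitivity(
    mappings: list[Mapping],
    annotations: list[AnnotationGene],
    prediction_identities: list[float] | None = None,
    identity_thresholds: tuple[float, ...] = (0.9, 0.8, 0.6, 0.4),
) -> dict[str, float]:
    """Fraction of annotated genes mapped, at base and after excluding
    predictions above each identity threshold (simulated divergence)."""
    n_genes = len(annotations)
    if n_genes == 0:
        raise ValueError("no annotations")
    out = {"base": len({m.gene_id for m in mappings}) / n_genes}
    if prediction_identities is not None:
        for thr in identity_thresholds:
            kept = {
                m.gene_id
                for m in mappings
                if prediction_identities[m.prediction_idx] <= thr
            }
            out[f"max_id_{int(100 * thr)}"] = len(kept) / n_genes
    return out


def precision_recall(
    e_values: list[float], is_true: list[bool]
) -> tuple[np.ndarray, np.ndarray, float]:
    """PR curve over E-value thresholds (smaller E = higher confidence)
    and the trapezoid AUC over recall."""
    if len(e_values) != len(is_true) or not e_values:
        raise ValueError("need matching, non-empty scores and labels")
    score = [-math.log10(max(e, 1e-300)) for e in e_values]
    precision, recall, _ = precision_recall_curve(
        np.asarray(is_true, dtype=int), np.asarray(score)
    )
    order = np.argsort(recall)
    auc = float(np.trapezoid(np.asarray(precision)[order],
                             np.asarray(recall)[order]))
    return precision, recall, auc


def split_gene_rate(mappings: list[Mapping]) -> float:
    """Fraction of mapped genes hit by two or more predictions."""
    counts: dict[str, int] = {}
    for m in mappings:
        counts[m.gene_id] = counts.get(m.gene_id, 0) + 1
    if not counts:
        return 0.0
    return sum(1 for v in counts.values() if v >= 2) / len(counts)


def inverted_null_run(
    contigs: list[Contig], reference_db: ReferenceDB, cfg: RunConfig | None = None
) -> int:
    """Run the full pipeline on character-reversed fragments.

    Every resulting prediction is a false positive; the count bounds the
    false discovery rate without any annotation.
    """
    if not contigs:
        return 0
    result = pipeline.predict(contigs, reference_db, cfg, invert=True)
    return len(result.predictions)


# Contig-length quantile anchors of a typical metagenomic assembly:
# (cumulative probability, length in bp)
LENGTH_ANCHORS = (
    (0.0, 5002),
    (0.25, 5661),
    (0.5, 6763),
    (0.75, 9020),
    (1.0, 1_524_677),
)


def sample_contig_length(rng: np.random.Generator, anchors=LENGTH_ANCHORS) -> int:
    """Inverse-CDF sampling, piecewise linear between quantile anchors
    (log-linear on the heavy upper tail)."""
    u = rng.random()
    for (p0, x0), (p1, x1) in zip(anchors, anchors[1:]):
        if u <= p1 or (p1, x1) == anchors[-1]:
            t = (u - p0) / (p1 - p0)
            if p1 == 1.0:
                return int(round(x0 * (x1 / x0) ** t))
            return int(round(x0 + t * (x1 - x0)))
    return anchors[-1][1]


def fragment_scaffolds(
    scaffolds: list[Contig], seed: int = 0, anchors=LENGTH_ANCHORS
) -> tuple[list[Contig], dict[str, tuple[str, int]]]:
    """Cut scaffolds into contigs with metagenome-typical lengths.

    Deterministic given the seed. Concatenating the emitted contigs
    reproduces each scaffold; the returned offset map (contig id ->
    (scaffold id, offset)) lifts truth coordinates onto the new contigs.
    """
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    offsets: dict[str, tuple[str, int]] = {}
    for scaf in scaffolds:
        pos = 0
        idx = 0
        while pos < scaf.length:
            length = min(sample_contig_length(rng, anchors), scaf.length - pos)
            cid = f"{scaf.id}_part{idx}"
            contigs.append(Contig(id=cid, seq=scaf.seq[pos:pos + length]))
            offsets[cid] = (scaf.id, pos)
            pos += length
            idx += 1
    return contigs, offsets
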