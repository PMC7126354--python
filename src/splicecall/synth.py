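"""Synthetic genomes with multi-exon genes, truth annotations and diverged
reference proteins.

Genes are built from random proteins: each exon is a whole-codon
back-translated protein segment, introns are random nucleotides carrying a
stop codon in all three reading frames (so multi-exon genes can never be
found as a single translated fragment), and genes are placed without
overlap, separated by random intergenic stretches. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from splicecall.seqio import AnnotationGene, Contig, TargetProtein
from splicecall.translate import reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# stop codons in all three frames: TAA at offsets 1, 5 and 9
_STOP_BLOCK = "TTAATTAATTAA"


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 50
    n_contigs: int = 5
    min_exons: int = 1
    max_exons: int = 5
    min_exon_aa: int = 15
    max_exon_aa: int = 90
    min_intron_nt: int = 30
    max_intron_nt: int = 600
    min_intergenic_nt: int = 150
    max_intergenic_nt: int = 1200
    minus_strand_prob: float = 0.5
    n_decoys: int = 0
    decoy_len_aa: tuple[int, int] = (80, 300)

    def __post_init__(self) -> None:
        if not 15 <= self.min_intron_nt <= self.max_intron_nt <= 10_000:
            raise ValueError("intron lengths must stay inside [15, 10000]")
        if self.min_exon_aa < 10:
            raise ValueError("exon lengths must be >= the 10-aa minimal exon")


def _codon_choices(genetic_code: int = 1) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        choices.setdefault(aa, []).append(codon)
    return choices


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def back_translate(protein: str, rng: np.random.Generator,
                   genetic_code: int = 1) -> str:
    """Back-translate with uniformly drawn synonymous codons."""
    choices = _codon_choices(genetic_code)
    return "".join(choices[aa][rng.integers(len(choices[aa]))] for aa in protein)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _make_intron(rng: np.random.Generator, length: int) -> str:
    nt = _random_nt(rng, length)
    pos = (length - len(_STOP_BLOCK)) // 2
    if pos >= 0:
        nt = nt[:pos] + _STOP_BLOCK + nt[pos + len(_STOP_BLOCK):]
    return nt


@dataclass
class SynthGenome:
    contigs: list[Contig]
    genes: list[AnnotationGene]
    proteins: list[TargetProtein] = field(default_factory=list)

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.contigs)


def generate_genome(cfg: SynthConfig, seed: int = 0) -> SynthGenome:
    """Contigs + truth annotations + true proteins, deterministic per seed."""
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    genes: list[AnnotationGene] = []
    proteins: list[TargetProtein] = []
    per_contig = np.array_split(np.arange(cfg.n_genes), cfg.n_contigs)
    for ci, gene_idxs in enumerate(per_contig):
        contig_id = f"syn{ci}"
        parts: list[str] = []
        pos = 0
        for gi in gene_idxs:
            gap = int(rng.integers(cfg.min_intergenic_nt, cfg.max_intergenic_nt + 1))
            parts.append(_random_nt(rng, gap))
            pos += gap
            gene_id = f"gene{gi}"
            k = int(rng.integers(cfg.min_exons, cfg.max_exons + 1))
            exon_lens = [
                int(rng.integers(cfg.min_exon_aa, cfg.max_exon_aa + 1))
                for _ in range(k)
            ]
            protein = _random_protein(rng, sum(exon_lens))
            strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
            # assemble the gene in transcription orientation
            segs: list[str] = []
            local_exons: list[tuple[int, int]] = []
            off = 0
            aa_off = 0
            for ei, elen in enumerate(exon_lens):
                exon_nt = back_translate(
                    protein[aa_off:aa_off + elen], rng
                )
                segs.append(exon_nt)
                local_exons.append((off, off + len(exon_nt)))
                off += len(exon_nt)
                aa_off += elen
                if ei < k - 1:
                    ilen = int(
                        rng.integers(cfg.min_intron_nt, cfg.max_intron_nt + 1)
                    )
                    segs.append(_make_intron(rng, ilen))
                    off += ilen
            gene_nt = "".join(segs)
            if strand == "+":
                placed = gene_nt
                exons = [(pos + s, pos + e) for s, e in local_exons]
            else:
                placed = reverse_complement(gene_nt)
                L = len(gene_nt)
                exons = [(pos + L - e, pos + L - s) for s, e in local_exons]
            parts.append(placed)
            pos += len(placed)
            genes.append(
                AnnotationGene(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    strand=strand,
                    exons=exons,
                    protein=protein,
                )
            )
            proteins.append(TargetProtein(id=gene_id, seq=protein))
        tail = int(rng.integers(cfg.min_intergenic_nt, cfg.max_intergenic_nt + 1))
        parts.append(_random_nt(rng, tail))
        contigs.append(Contig(id=contig_id, seq="".join(parts)))
    return SynthGenome(contigs=contigs, genes=genes, proteins=proteins)


def diverge_proteins(
    true_proteins: list[TargetProtein],
    divergence: float,
    seed: int = 0,
    suffix: str = "_ref",
) -> tuple[list[TargetProtein], float]:
    """Substitute each site with probability ``divergence``.

    Replacements are drawn BLOSUM62-weighted (2^(score/2) over the 19
    non-identical residues). Returns the diverged targets and the realized
    mean identity to the originals.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    blosum = substitution_matrices.load("BLOSUM62")
    weights: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in AA20:
        others = [b for b in AA20 if b != aa]
        w = np.array([2.0 ** (blosum[aa, b] / 2.0) for b in others])
        weights[aa] = (others, w / w.sum())
    out: list[TargetProtein] = []
    same = total = 0
    for prot in true_proteins:
        chars = list(prot.seq)
        for i, aa in enumerate(chars):
            if rng.random() < divergence:
                others, w = weights[aa]
                chars[i] = others[rng.choice(len(others), p=w)]
        new = "".join(chars)
        same += sum(a == b for a, b in zip(prot.seq, new))
        total += len(new)
        out.append(TargetProtein(id=prot.id + suffix, seq=new))
    identity = same / total if total else 1.0
    return out, identity


def make_decoys(cfg: SynthConfig, seed: int = 1) -> list[TargetProtein]:
    """Random proteins with no ancestry shared with any implanted gene."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.decoy_len_aa
    return [
        TargetProtein(
            id=f"decoy{i}", seq=_random_protein(rng, int(rng.integers(lo, hi + 1)))
        )
        for i in range(cfg.n_decoys)
    ]
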