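"""FASTA/GFF3 input-output and the coordinate conventions of the pipeline.

Internal coordinates are 0-based, half-open, always on the plus strand of
the contig. GFF3 output is 1-based inclusive. Writers emit deterministic,
sorted output.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")


@dataclass
class Contig:
    """A nucleotide sequence with an identifier."""

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class TargetProtein:
    """A reference amino-acid sequence (no stop symbols)."""

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceDB:
    """Target proteins plus D, the total amino-acid count of the database."""

    targets: list[TargetProtein]
    by_id: dict[str, TargetProtein] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_id = {}
        for t in self.targets:
            if t.id in self.by_id:
                raise ValueError(f"duplicate target id: {t.id}")
            self.by_id[t.id] = t

    @property
    def D(self) -> int:
        return sum(t.length for t in self.targets)


@dataclass
class AnnotationGene:
    """A gold-standard gene: CDS intervals on the contig plus its protein.

    ``exons`` are internal (0-based half-open) plus-strand intervals,
    sorted and non-overlapping.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    protein: str = ""

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty/reversed CDS interval {s},{e}")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


def _validate_seq(seq: str, alphabet: set[str], rec_id: str, kind: str) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"record {rec_id}: illegal {kind} characters {sorted(bad)}")
    if not seq:
        raise ValueError(f"record {rec_id}: empty sequence")


def read_fasta(path, alphabet: str = "nt"):
    """Read a FASTA file as contigs (``alphabet='nt'``) or proteins (``'aa'``).

    Records come back in file order; the description after the first
    whitespace is kept separately from the id. Raises on empty files,
    duplicate ids, and characters outside the declared alphabet.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError("alphabet must be 'nt' or 'aa'")
    cls = Contig if alphabet == "nt" else TargetProtein
    charset = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _validate_seq(seq, charset, rec.id, alphabet)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(cls(id=rec.id, seq=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=getattr(r, "description", ""))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_reference(path) -> ReferenceDB:
    return ReferenceDB(targets=read_fasta(path, alphabet="aa"))


def read_gff3(path, proteins: dict[str, str] | None = None) -> list[AnnotationGene]:
    """Read gene/mRNA/CDS features into :class:`AnnotationGene` records.

    CDS features are grouped by their top-level gene ancestor; coordinates
    are converted from GFF3 1-based inclusive to internal half-open. An
    optional ``proteins`` mapping (gene id -> aa sequence) fills the
    protein field.
    """
    if os.path.getsize(path) == 0 or _gff_has_no_features(path):
        return []
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[AnnotationGene] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds_list = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds_list:
            continue
        exons = []
        for cds in cds_list:
            if cds.start > cds.end:
                raise ValueError(f"malformed CDS coordinates in gene {gene.id}")
            exons.append((cds.start - 1, cds.end))
        genes.append(
            AnnotationGene(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                protein=(proteins or {}).get(gene.id, ""),
            )
        )
    orphans = [
        f.id for f in db.features_of_type("CDS")
        if not any(a.featuretype == "gene" for a in db.parents(f))
    ]
    if orphans:
        raise ValueError(f"CDS features without a gene parent: {orphans[:5]}")
    return genes


def _gff_has_no_features(path) -> bool:
    with open(path) as fh:
        return all(line.startswith("#") or not line.strip() for line in fh)


def write_gff3_annotations(genes, path) -> None:
    """Write truth annotations (gene + CDS features) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.span[0], g.gene_id)):
            lo, hi = g.span
            fh.write(
                f"{g.contig_id}\tsplicecall\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.contig_id}\tsplicecall\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{_phase(g, i)}\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def _phase(gene: AnnotationGene, idx: int) -> int:
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    consumed = 0
    order = exons.index(gene.exons[idx])
    for s, e in exons[:order]:
        consumed += e - s
    return (3 - consumed % 3) % 3


def prediction_header(pred) -> str:
    """Pipe-delimited self-describing FASTA header for one prediction."""
    coords = "|".join(f"{lo}-{hi}" for lo, hi in pred.exon_contig_intervals())
    return (
        f"{pred.target_id}|{pred.contig_id}|{pred.strand}|"
        f"{pred.S_set:.3f}|{pred.e_value:.3e}|{pred.k}|{coords}"
    )


def write_predictions(predictions, contigs, gff_path, protein_path, codon_path) -> None:
    """Write predictions as GFF3 plus protein and codon FASTA files.

    GFF3 has one gene feature and one CDS feature per exon, CDS lines in
    increasing contig coordinate. The codon FASTA concatenates exon
    nucleotide segments in translation order; the protein FASTA is the
    concatenation of exon amino-acid segments in target order.
    """
    contig_by_id = {c.id: c for c in contigs}
    for p in predictions:
        if p.contig_id not in contig_by_id:
            raise ValueError(f"prediction references unknown contig {p.contig_id}")
    preds = sorted(
        predictions, key=lambda p: (p.contig_id, p.span_low, p.strand, p.target_id)
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, p in enumerate(preds):
            pid = f"pred{n}"
            attrs = (
                f"ID={pid};target={p.target_id};score={p.S_set:.3f};"
                f"evalue={p.e_value:.3e};num_exons={p.k}"
            )
            fh.write(
                f"{p.contig_id}\tsplicecall\tgene\t{p.span_low + 1}\t{p.span_high}\t"
                f"{p.S_set:.3f}\t{p.strand}\t.\t{attrs}\n"
            )
            for i, (lo, hi) in enumerate(sorted(p.exon_contig_intervals())):
                fh.write(
                    f"{p.contig_id}\tsplicecall\tCDS\t{lo + 1}\t{hi}\t.\t{p.strand}\t"
                    f".\tID={pid}.cds{i};Parent={pid}\n"
                )
    prot_records, codon_records = [], []
    for p in preds:
        header = prediction_header(p)
        codon = p.codon_sequence(contig_by_id[p.contig_id].seq)
        prot_records.append(TargetProtein(id=header, seq=p.protein))
        codon_records.append(Contig(id=header, seq=codon))
    _write_raw_fasta(prot_records, protein_path)
    _write_raw_fasta(codon_records, codon_path)


def _write_raw_fasta(records, path, width: int = 60) -> None:
    # headers contain '|' and '-' so bypass SeqRecord id munging
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


def read_lineage_tsv(path) -> dict[str, list[str]]:
    """Read ``target_id <tab> domain;kingdom;...;species`` lines."""
    lineages: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, _, lin = line.partition("\t")
            if not lin:
                raise ValueError(f"malformed lineage line: {line!r}")
            lineages[tid] = [x for x in lin.split(";") if x]
    return lineages


def roundtrip_gff_interval(lo: int, hi: int) -> tuple[int, int]:
    """Internal half-open -> GFF3 1-based inclusive -> internal (identity)."""
    g_start, g_end = lo + 1, hi
    return (g_start - 1, g_end)
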