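"""Six-frame extraction of stop-free translated fragments from contigs.

Every maximal stop-free stretch in each of the six reading frames becomes a
fragment; stretches abutting contig ends (with no bounding stop codon) are
kept. Stop codons are excluded from fragments. Minus-strand fragments are
translated from the reverse complement but their contig span is reported in
plus-strand coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

from splicecall.seqio import Contig

_RUN = re.compile(r"[^*]+")


@dataclass(frozen=True)
class TranslatedFragment:
    """One inter-stop amino-acid fragment with frame/strand and contig span.

    ``contig_start``/``contig_end`` are plus-strand half-open nucleotide
    coordinates of the translated span; ``3 * len(aa_seq) == contig_end -
    contig_start`` always holds. The fragment id doubles as the exon id
    downstream.
    """

    fragment_id: str
    contig_id: str
    strand: str
    frame: int
    aa_seq: str
    contig_start: int
    contig_end: int
    inverted: bool = False

    def __post_init__(self) -> None:
        assert 3 * len(self.aa_seq) == self.contig_end - self.contig_start


def _check_code(genetic_code: int) -> None:
    try:
        CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code table: {genetic_code}") from exc


def translate_nt(nt: str, genetic_code: int = 1) -> str:
    """Translate a nucleotide string; codons with non-ACGT bases give 'X'.

    Trailing partial codons are discarded.
    """
    _check_code(genetic_code)
    nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=genetic_code))
    if "N" in nt:  # Biopython may emit 'X' already, but force non-stop reading
        aa = "".join(
            "X" if set(nt[3 * i:3 * i + 3]) - set("ACGT") else c
            for i, c in enumerate(aa)
        )
    return aa


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def extract_fragments(
    contig: Contig, genetic_code: int = 1, min_fragment_aa: int = 20
) -> list[TranslatedFragment]:
    """All six-frame stop-free fragments of at least ``min_fragment_aa`` aa."""
    _check_code(genetic_code)
    if min_fragment_aa < 1:
        raise ValueError("min_fragment_aa must be >= 1")
    length = contig.length
    fragments: list[TranslatedFragment] = []
    for strand in "+-":
        seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for frame in range(3):
            n_codons = (length - frame) // 3
            if n_codons < 1:
                continue
            aa = translate_nt(seq[frame:frame + 3 * n_codons], genetic_code)
            for m in _RUN.finditer(aa):
                if m.end() - m.start() < min_fragment_aa:
                    continue
                # codon span on the read strand, then lift to plus coordinates
                s = frame + 3 * m.start()
                e = frame + 3 * m.end()
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = length - e, length - s
                fragments.append(
                    TranslatedFragment(
                        fragment_id=f"{contig.id}|{strand}|{frame}|{start}",
                        contig_id=contig.id,
                        strand=strand,
                        frame=frame,
                        aa_seq=m.group(),
                        contig_start=start,
                        contig_end=end,
                    )
                )
    return fragments


def invert_fragments(fragments) -> list[TranslatedFragment]:
    """Character-reverse each fragment's amino-acid string (null model).

    No complementation is applied; coordinates are retained and ids are
    flagged so downstream stages can tell the sets apart. Applying this
    twice restores the original sequences.
    """
    out = []
    for f in fragments:
        out.append(
            replace(
                f,
                aa_seq=f.aa_seq[::-1],
                inverted=not f.inverted,
                fragment_id=(
                    f.fragment_id[:-4] if f.inverted else f.fragment_id + "|inv"
                ),
            )
        )
    return out
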