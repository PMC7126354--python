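"""Local protein search: fragments versus reference targets.

The built-in aligner is an optimal affine-gap Smith-Waterman (Biopython's
PairwiseAligner) with BLAST-style gap costs and Karlin-Altschul statistics.
A shared-k-mer prefilter keeps desk-scale runs fast; ``exhaustive=True``
aligns every (fragment, target) pair. Externally computed hits can be
imported from BLAST/MMseqs2 tabular (m8) files instead.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from splicecall.config import ScoringScheme
from splicecall.seqio import ReferenceDB

_ALLOWED_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class LocalHit:
    """One best local alignment of a fragment against a target.

    Alignment coordinates are half-open on both sequences; ``identity`` is
    the fraction of identical residue pairs over alignment columns
    (including gap columns).
    """

    fragment_id: str
    target_id: str
    frag_aln_start: int
    frag_aln_end: int
    target_aln_start: int
    target_aln_end: int
    raw_score: float
    bit_score: float
    e_value: float
    identity: float
    aln_len: int
    n_mismatch: int = 0
    n_gapopen: int = 0

    def __post_init__(self) -> None:
        assert 0 <= self.frag_aln_start < self.frag_aln_end
        assert 0 <= self.target_aln_start < self.target_aln_end


def bit_from_raw(raw: float, scheme: ScoringScheme) -> float:
    return (scheme.lmbda * raw - math.log(scheme.k_param)) / math.log(2.0)


def raw_from_bit(bit: float, scheme: ScoringScheme) -> float:
    return (bit * math.log(2.0) + math.log(scheme.k_param)) / scheme.lmbda


def hit_evalue(raw: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul E-value K*m*n*exp(-lambda*raw) for one comparison."""
    return scheme.k_param * m * n * math.exp(-scheme.lmbda * raw)


def make_aligner(scheme: ScoringScheme, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner(mode=mode)
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    # BLAST convention: gap of length L costs open + L*extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    if mode == "global":
        # end-gap-free global alignment for protein-vs-protein comparisons
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _validate_aa(seq: str, what: str) -> None:
    bad = set(seq) - _ALLOWED_AA
    if bad:
        raise ValueError(f"{what}: unsupported amino-acid characters {sorted(bad)}")


def alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int]:
    """(qs, qe, ts, te, aln_len, n_ident, n_mismatch, gapopen) of one alignment."""
    q_blocks, t_blocks = alignment.aligned[0], alignment.aligned[1]
    query, target = alignment.sequences
    n_ident = n_mm = aligned_cols = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for a, b in zip(query[qs:qe], target[ts:te]):
            if a == b:
                n_ident += 1
            else:
                n_mm += 1
        aligned_cols += qe - qs
    qs0, qe0 = q_blocks[0][0], q_blocks[-1][1]
    ts0, te0 = t_blocks[0][0], t_blocks[-1][1]
    gap_cols = (qe0 - qs0) + (te0 - ts0) - 2 * aligned_cols
    aln_len = aligned_cols + gap_cols
    gapopen = (len(q_blocks) - 1)
    return qs0, qe0, ts0, te0, aln_len, n_ident, n_mm, gapopen


def smith_waterman(
    query_aa: str, target_aa: str, scheme: ScoringScheme | None = None
):
    """Best local alignment; returns ``None`` if the optimum is <= 0.

    Result is a dict with raw score, half-open aligned intervals on both
    sequences, identity and column counts. Traceback is Biopython's
    deterministic first alignment.
    """
    scheme = scheme or ScoringScheme()
    if not query_aa or not target_aa:
        raise ValueError("empty sequence")
    _validate_aa(query_aa, "query")
    _validate_aa(target_aa, "target")
    aligner = make_aligner(scheme)
    score = aligner.score(query_aa, target_aa)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query_aa, target_aa)))
    qs, qe, ts, te, aln_len, n_ident, n_mm, gapopen = alignment_stats(aln)
    return {
        "raw_score": float(score),
        "frag_aln_start": qs,
        "frag_aln_end": qe,
        "target_aln_start": ts,
        "target_aln_end": te,
        "aln_len": aln_len,
        "identity": n_ident / aln_len if aln_len else 0.0,
        "n_mismatch": n_mm,
        "n_gapopen": gapopen,
    }


def _kmer_index(reference_db: ReferenceDB, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for ti, t in enumerate(reference_db.targets):
        seen: set[str] = set()
        for i in range(len(t.seq) - k + 1):
            kmer = t.seq[i:i + k]
            if kmer not in seen:
                seen.add(kmer)
                index[kmer].append(ti)
    return dict(index)


def search_fragments(
    fragments,
    reference_db: ReferenceDB,
    scheme: ScoringScheme | None = None,
    max_exon_evalue: float = 100.0,
    prefilter_kmer: int = 5,
    exhaustive: bool = False,
) -> list[LocalHit]:
    """All fragment-target local hits with E-value <= ``max_exon_evalue``.

    E-values use m = fragment length and n = D (total reference residues).
    One best alignment is kept per (fragment, target) pair.
    """
    scheme = scheme or ScoringScheme()
    if not reference_db.targets:
        raise ValueError("empty reference database")
    D = reference_db.D
    aligner = make_aligner(scheme)
    index = None if exhaustive else _kmer_index(reference_db, prefilter_kmer)
    hits: list[LocalHit] = []
    for frag in fragments:
        m = len(frag.aa_seq)
        if exhaustive:
            candidates = range(len(reference_db.targets))
        else:
            cand: set[int] = set()
            for i in range(m - prefilter_kmer + 1):
                cand.update(index.get(frag.aa_seq[i:i + prefilter_kmer], ()))
            candidates = sorted(cand)
        # minimal raw score that can still pass the E-value cutoff
        min_raw = math.log(scheme.k_param * m * D / max_exon_evalue) / scheme.lmbda
        for ti in candidates:
            target = reference_db.targets[ti]
            score = aligner.score(frag.aa_seq, target.seq)
            if score <= 0 or score < min_raw:
                continue
            ev = hit_evalue(score, m, D, scheme)
            if ev > max_exon_evalue:
                continue
            aln = next(iter(aligner.align(frag.aa_seq, target.seq)))
            qs, qe, ts, te, aln_len, n_ident, n_mm, gapopen = alignment_stats(aln)
            hits.append(
                LocalHit(
                    fragment_id=frag.fragment_id,
                    target_id=target.id,
                    frag_aln_start=qs,
                    frag_aln_end=qe,
                    target_aln_start=ts,
                    target_aln_end=te,
                    raw_score=float(score),
                    bit_score=bit_from_raw(score, scheme),
                    e_value=ev,
                    identity=n_ident / aln_len if aln_len else 0.0,
                    aln_len=aln_len,
                    n_mismatch=n_mm,
                    n_gapopen=gapopen,
                )
            )
    hits.sort(key=lambda h: (h.fragment_id, h.target_id))
    return hits


M8_COLUMNS = (
    "query target pident alnlen mismatch gapopen "
    "qstart qend tstart tend evalue bits"
).split()


def write_hits_m8(hits, path) -> None:
    """Write hits in 12-column BLAST tabular format (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.fragment_id}\t{h.target_id}\t{100.0 * h.identity:.1f}\t"
                f"{h.aln_len}\t{h.n_mismatch}\t{h.n_gapopen}\t"
                f"{h.frag_aln_start + 1}\t{h.frag_aln_end}\t"
                f"{h.target_aln_start + 1}\t{h.target_aln_end}\t"
                f"{h.e_value:.6e}\t{h.bit_score:.6f}\n"
            )


def import_hits_m8(
    path, fragments, reference_db: ReferenceDB, scheme: ScoringScheme | None = None
) -> list[LocalHit]:
    """Read externally computed hits from a BLAST/MMseqs2 tabular file.

    Query ids must be fragment ids; coordinates are converted from the
    1-based inclusive m8 convention to internal half-open. Bit-scores are
    taken as given; raw scores are back-computed from them.
    """
    scheme = scheme or ScoringScheme()
    frag_ids = {f.fragment_id for f in fragments}
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"line {ln}: expected >=12 m8 columns")
            (qid, tid, pident, alnlen, mism, gapopen,
             qstart, qend, tstart, tend, evalue, bits) = parts[:12]
            if qid not in frag_ids:
                raise ValueError(f"line {ln}: unknown fragment id {qid}")
            if tid not in reference_db.by_id:
                raise ValueError(f"line {ln}: unknown target id {tid}")
            qs, qe = int(qstart), int(qend)
            ts, te = int(tstart), int(tend)
            if qs > qe or ts > te:
                raise ValueError(f"line {ln}: reversed alignment coordinates")
            bit = float(bits)
            hits.append(
                LocalHit(
                    fragment_id=qid,
                    target_id=tid,
                    frag_aln_start=qs - 1,
                    frag_aln_end=qe,
                    target_aln_start=ts - 1,
                    target_aln_end=te,
                    raw_score=raw_from_bit(bit, scheme),
                    bit_score=bit,
                    e_value=float(evalue),
                    identity=float(pident) / 100.0,
                    aln_len=int(alnlen),
                    n_mismatch=int(mism),
                    n_gapopen=int(gapopen),
                )
            )
    return hits
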