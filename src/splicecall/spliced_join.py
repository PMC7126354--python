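"""Spliced joining of putative exons into gene calls by dynamic programming.

A putative exon is the aligned part of a translated fragment against one
target. Exons from the same (contig, strand, target) group are chained into
the highest-scoring compatible set. Conventions:

* Target coordinates ST/ET are stored inclusive (first and last aligned
  amino acid), so perfect adjacency of consecutive exons gives
  ``l = ST_next - ET_prev = 1``, which is exempt from the gap penalty.
* SC/EC are plus-strand nucleotide coordinates of where translation of the
  aligned part starts and ends. On '+' the exon occupies ``[SC, EC)`` and
  ``SC < EC``; on '-' it occupies ``[EC, SC)`` and ``SC > EC`` (translation
  runs from high to low plus-strand coordinates).

The composite bit-score of a k-exon set is the sum of per-exon bit-scores,
minus ``|l|`` for every inter-exon target gap/overlap ``l != 1``, plus a
``log2(k!)`` ordering reward. The set E-value is ``2 * D * 2**(-S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from splicecall.config import RunConfig
from splicecall.translate import reverse_complement, translate_nt


@dataclass(frozen=True)
class PutativeExon:
    exon_id: str           # equals the source fragment id
    target_id: str
    contig_id: str
    strand: str
    ST: int                # target aa start, inclusive
    ET: int                # target aa end, inclusive
    SC: int                # contig nt coordinate where translation starts
    EC: int                # contig nt coordinate where translation ends
    bit_score: float
    e_value: float
    aligned_aa_length: int
    aa_seq: str = ""

    def __post_init__(self) -> None:
        assert self.ST <= self.ET
        if self.strand == "+":
            assert self.SC < self.EC
        else:
            assert self.SC > self.EC

    @property
    def contig_low(self) -> int:
        return min(self.SC, self.EC)

    @property
    def contig_high(self) -> int:
        return max(self.SC, self.EC)


@dataclass
class GeneCall:
    """An ordered compatible exon set for one (contig, strand, target)."""

    contig_id: str
    strand: str
    target_id: str
    exons: list[PutativeExon]          # ordered by ST (translation order)
    S_set: float
    e_value: float

    @property
    def k(self) -> int:
        return len(self.exons)

    @property
    def gaps(self) -> list[int]:
        return [
            self.exons[i + 1].ST - self.exons[i].ET for i in range(self.k - 1)
        ]

    @property
    def span_low(self) -> int:
        return min(e.contig_low for e in self.exons)

    @property
    def span_high(self) -> int:
        return max(e.contig_high for e in self.exons)

    @property
    def protein(self) -> str:
        return "".join(e.aa_seq for e in self.exons)

    @property
    def exon_ids(self) -> frozenset[str]:
        return frozenset(e.exon_id for e in self.exons)

    @property
    def first_exon_sc(self) -> int:
        return self.exons[0].SC

    @property
    def call_id(self) -> str:
        return f"{self.contig_id}|{self.strand}|{self.target_id}"

    def exon_contig_intervals(self) -> list[tuple[int, int]]:
        return [(e.contig_low, e.contig_high) for e in self.exons]

    def codon_sequence(self, contig_seq: str) -> str:
        """Concatenated exon nucleotide segments in translation order."""
        parts = []
        for e in self.exons:
            seg = contig_seq[e.contig_low:e.contig_high]
            parts.append(seg if self.strand == "+" else reverse_complement(seg))
        return "".join(parts)

    def translated_codon_protein(self, contig_seq: str, genetic_code: int = 1) -> str:
        return translate_nt(self.codon_sequence(contig_seq), genetic_code)


def build_putative_exons(
    hits, fragments, min_exon_aa: int = 10
) -> dict[tuple[str, str, str], list[PutativeExon]]:
    """Turn local hits into putative exons grouped by (contig, strand, target).

    Contig coordinates come from the fragment span plus three times the
    fragment-internal amino-acid offsets of the aligned part. Hits aligned
    over fewer than ``min_exon_aa`` amino acids (on the fragment) are
    dropped.
    """
    frag_by_id = {f.fragment_id: f for f in fragments}
    groups: dict[tuple[str, str, str], list[PutativeExon]] = {}
    for h in hits:
        frag = frag_by_id.get(h.fragment_id)
        if frag is None:
            raise ValueError(f"hit references unknown fragment {h.fragment_id}")
        alen = h.frag_aln_end - h.frag_aln_start
        if alen < min_exon_aa:
            continue
        if h.frag_aln_end > len(frag.aa_seq):
            raise ValueError(
                f"hit coordinates exceed fragment {h.fragment_id} length"
            )
        if frag.strand == "+":
            sc = frag.contig_start + 3 * h.frag_aln_start
            ec = frag.contig_start + 3 * h.frag_aln_end
        else:
            sc = frag.contig_end - 3 * h.frag_aln_start
            ec = frag.contig_end - 3 * h.frag_aln_end
        exon = PutativeExon(
            exon_id=h.fragment_id,
            target_id=h.target_id,
            contig_id=frag.contig_id,
            strand=frag.strand,
            ST=h.target_aln_start,
            ET=h.target_aln_end - 1,
            SC=sc,
            EC=ec,
            bit_score=h.bit_score,
            e_value=h.e_value,
            aligned_aa_length=alen,
            aa_seq=frag.aa_seq[h.frag_aln_start:h.frag_aln_end],
        )
        groups.setdefault((frag.contig_id, frag.strand, h.target_id), []).append(exon)
    return groups


def compatible(
    p_i: PutativeExon, p_j: PutativeExon, cfg: RunConfig | None = None
) -> bool:
    """Can ``p_i`` (earlier on the target) be followed by ``p_j``?

    Requires ST_i < ST_j; contig order must match target order; the contig
    distance between them must fit the intron window [15, 10000]; their
    target matches may overlap by at most 10 aa.
    """
    cfg = cfg or RunConfig()
    if (p_i.contig_id, p_i.strand, p_i.target_id) != (
        p_j.contig_id, p_j.strand, p_j.target_id
    ):
        raise ValueError("exons from different (contig, strand, target) groups")
    if not p_i.ST < p_j.ST:
        return False
    if p_j.ST - p_i.ET < -cfg.max_target_overlap_aa:
        return False
    if p_i.strand == "+":
        if not p_i.SC < p_j.SC:
            return False
        dist = p_j.SC - p_i.EC
    else:
        if not p_i.SC > p_j.SC:
            return False
        dist = p_i.EC - p_j.SC
    return cfg.min_intron_nt <= dist <= cfg.max_intron_nt


def gap_penalty(l: int) -> float:
    """C(l): 0 for l == 1, else -|l| (bits)."""
    return 0.0 if l == 1 else -abs(l)


def call_score(exons: list[PutativeExon], cfg: RunConfig | None = None) -> float:
    """Composite bit-score of a compatible ordered exon set."""
    cfg = cfg or RunConfig()
    exons = sorted(exons, key=lambda e: e.ST)
    for a, b in zip(exons, exons[1:]):
        if not compatible(a, b, cfg):
            raise ValueError(f"incompatible consecutive exons {a.exon_id}, {b.exon_id}")
    k = len(exons)
    total = sum(e.bit_score for e in exons)
    total += sum(gap_penalty(b.ST - a.ET) for a, b in zip(exons, exons[1:]))
    total += math.log2(math.factorial(k))
    return total


def call_evalue(s_set: float, D: int) -> float:
    """Expected chance matches at this score over both strands: 2*D*2^-S."""
    if D < 1:
        raise ValueError("D must be >= 1")
    return 2.0 * D * 2.0 ** (-s_set)


def _sort_for_dp(exons: list[PutativeExon], strand: str) -> list[PutativeExon]:
    # translation order along the contig; deterministic tie-breaks
    if strand == "+":
        return sorted(exons, key=lambda e: (e.SC, e.ET, e.exon_id))
    return sorted(exons, key=lambda e: (-e.SC, e.ET, e.exon_id))


@dataclass
class _DPState:
    """A chain ending in one exon: score, length, backtrace."""

    S: float
    k: int
    exon_idx: int
    first_sc: int
    prev: "_DPState | None"


def best_exon_set(
    exons: list[PutativeExon], D: int, cfg: RunConfig | None = None
) -> GeneCall | None:
    """Highest-scoring compatible exon subset for one group, by DP.

    Exons are processed in translation order along the contig. Each exon
    carries a Pareto frontier of chain states (score S, length k): because
    extending a chain of length k adds a ``log2(k+1)`` reward, a longer but
    lower-scoring chain can overtake after extension, so one (S, k, b)
    triple per exon is not sufficient for exactness — a state survives only
    if no other state at the same exon has both >= S and >= k. Ties prefer
    the earlier predecessor; ties for the global optimum prefer the chain
    whose first exon starts earliest on the contig. O(n^2) frontier
    extensions, O(n) states per exon worst case.
    """
    cfg = cfg or RunConfig()
    if not exons:
        return None
    strand = exons[0].strand
    order = _sort_for_dp(exons, strand)
    n = len(order)
    states: list[list[_DPState]] = []
    for j in range(n):
        pj = order[j]
        # candidate states per chain length k: keep the best score for each
        best_by_k: dict[int, _DPState] = {
            1: _DPState(S=pj.bit_score, k=1, exon_idx=j, first_sc=pj.SC,
                        prev=None)
        }
        for i in range(j):
            if not compatible(order[i], pj, cfg):
                continue
            penalty = gap_penalty(pj.ST - order[i].ET)
            for st in states[i]:
                cand = _DPState(
                    S=st.S + pj.bit_score + penalty + math.log2(st.k + 1),
                    k=st.k + 1,
                    exon_idx=j,
                    first_sc=st.first_sc,
                    prev=st,
                )
                cur = best_by_k.get(cand.k)
                if cur is None or cand.S > cur.S or (
                    cand.S == cur.S and cand.first_sc < cur.first_sc
                ):
                    best_by_k[cand.k] = cand
        # Pareto prune: walking k upward, drop states not improving on S
        frontier: list[_DPState] = []
        best_s = -math.inf
        for k in sorted(best_by_k, reverse=True):
            st = best_by_k[k]
            if st.S > best_s:
                frontier.append(st)
                best_s = st.S
        states.append(frontier)
    best = max(
        (st for frontier in states for st in frontier),
        key=lambda st: (st.S, -st.first_sc),
    )
    chain: list[PutativeExon] = []
    st: _DPState | None = best
    while st is not None:
        chain.append(order[st.exon_idx])
        st = st.prev
    chain.reverse()
    s_set = best.S
    return GeneCall(
        contig_id=chain[0].contig_id,
        strand=strand,
        target_id=chain[0].target_id,
        exons=chain,
        S_set=s_set,
        e_value=call_evalue(s_set, D),
    )


def join_all_groups(
    exon_groups: dict[tuple[str, str, str], list[PutativeExon]],
    D: int,
    cfg: RunConfig | None = None,
) -> list[GeneCall]:
    """One best call per (contig, strand, target) group."""
    calls = []
    for key in sorted(exon_groups):
        call = best_exon_set(exon_groups[key], D, cfg)
        if call is not None:
            calls.append(call)
    return calls


def filter_calls(
    calls: list[GeneCall],
    target_lengths: dict[str, int],
    max_call_evalue: float = 1e-4,
    min_tcov: float = 0.6,
) -> list[GeneCall]:
    """Keep calls with E <= cutoff and protein/target length ratio >= min_tcov."""
    kept = []
    for c in calls:
        if c.e_value > max_call_evalue:
            continue
        tlen = target_lengths[c.target_id]
        if min_tcov > 0 and len(c.protein) / tlen < min_tcov:
            continue
        kept.append(c)
    return kept
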