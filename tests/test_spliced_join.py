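import math
import random

import pytest

from splicecall.config import RunConfig
from splicecall.spliced_join import (
    PutativeExon,
    best_exon_set,
    build_putative_exons,
    call_evalue,
    call_score,
    compatible,
    filter_calls,
    gap_penalty,
)
from splicecall.translate import TranslatedFragment

CFG = RunConfig()


def exon(st, et, sc, ec, bits=20.0, strand="+", eid=None, target="T"):
    return PutativeExon(
        exon_id=eid or f"e{st}_{sc}",
        target_id=target,
        contig_id="c",
        strand=strand,
        ST=st, ET=et, SC=sc, EC=ec,
        bit_score=bits,
        e_value=1.0,
        aligned_aa_length=et - st + 1,
        aa_seq="A" * (et - st + 1),
    )


# ---------------------------------------------------------------- exons


def test_build_exon_coordinate_arithmetic_plus():
    frag = TranslatedFragment(
        fragment_id="c|+|0|300", contig_id="c", strand="+", frame=0,
        aa_seq="M" * 30, contig_start=300, contig_end=390,
    )

    class Hit:
        fragment_id = "c|+|0|300"
        target_id = "T"
        frag_aln_start, frag_aln_end = 5, 15
        target_aln_start, target_aln_end = 0, 10
        bit_score, e_value = 25.0, 0.5

    groups = build_putative_exons([Hit()], [frag], min_exon_aa=10)
    (ex,) = groups[("c", "+", "T")]
    assert (ex.SC, ex.EC) == (315, 345)
    assert (ex.ST, ex.ET) == (0, 9)  # inclusive target coordinates


def test_build_exon_min_length_filter():
    frag = TranslatedFragment(
        fragment_id="c|+|0|300", contig_id="c", strand="+", frame=0,
        aa_seq="M" * 30, contig_start=300, contig_end=390,
    )

    class Hit:
        fragment_id = "c|+|0|300"
        target_id = "T"
        frag_aln_start, frag_aln_end = 5, 14  # 9 aa < 10
        target_aln_start, target_aln_end = 0, 9
        bit_score, e_value = 25.0, 0.5

    assert build_putative_exons([Hit()], [frag], min_exon_aa=10) == {}


def test_build_exon_minus_strand_sc_above_ec():
    frag = TranslatedFragment(
        fragment_id="c|-|0|300", contig_id="c", strand="-", frame=0,
        aa_seq="M" * 30, contig_start=300, contig_end=390,
    )

    class Hit:
        fragment_id = "c|-|0|300"
        target_id = "T"
        frag_aln_start, frag_aln_end = 5, 15
        target_aln_start, target_aln_end = 0, 10
        bit_score, e_value = 25.0, 0.5

    groups = build_putative_exons([Hit()], [frag], min_exon_aa=10)
    (ex,) = groups[("c", "-", "T")]
    assert ex.SC > ex.EC
    assert (ex.SC, ex.EC) == (390 - 15, 390 - 45)


# -------------------------------------------------------- compatibility


def test_contig_gap_boundaries_plus():
    a = exon(0, 9, 370, 400)
    ok = exon(20, 29, 415, 445)
    assert compatible(a, ok, CFG)            # gap exactly 15
    too_close = exon(20, 29, 414, 444)
    assert not compatible(a, too_close, CFG)  # gap 14


def test_contig_gap_upper_boundary_plus():
    a = exon(0, 9, 370, 400)
    far_ok = exon(20, 29, 400 + 10_000, 400 + 10_030)
    assert compatible(a, far_ok, CFG)
    too_far = exon(20, 29, 400 + 10_001, 400 + 10_031)
    assert not compatible(a, too_far, CFG)


def test_target_overlap_boundary():
    a = exon(0, 20, 370, 433)
    ok = exon(11, 30, 463, 523)   # ST_j - ET_i = -9... use exact -10
    b10 = exon(10, 30, 463, 526)  # ST_j - ET_i = -10
    assert compatible(a, b10, CFG)
    b11 = exon(9, 30, 463, 529)   # -11
    assert not compatible(a, b11, CFG)
    assert compatible(a, ok, CFG)


def test_minus_strand_conditions():
    # translation runs right to left: exon i occupies [EC, SC) with SC > EC
    a = exon(0, 9, 1000, 970, strand="-")
    ok = exon(20, 29, 955, 925, strand="-")   # EC_i - SC_j = 970-955 = 15
    assert compatible(a, ok, CFG)
    close = exon(20, 29, 956, 926, strand="-")  # 14
    assert not compatible(a, close, CFG)
    wrong_order = exon(20, 29, 1100, 1070, strand="-")  # SC_j > SC_i
    assert not compatible(a, wrong_order, CFG)
    far = exon(20, 29, 970 - 10_001, 970 - 10_031, strand="-")
    assert not compatible(a, far, CFG)
    far_ok = exon(20, 29, 970 - 10_000, 970 - 10_030, strand="-")
    assert compatible(a, far_ok, CFG)


def test_contig_order_must_match_target_order():
    a = exon(0, 9, 500, 530)
    behind = exon(20, 29, 400, 430)  # later on target, earlier on contig
    assert not compatible(a, behind, CFG)


def test_requires_same_group():
    a = exon(0, 9, 370, 400)
    other = exon(20, 29, 415, 445, target="OTHER")
    with pytest.raises(ValueError):
        compatible(a, other, CFG)


def test_st_order_precondition_returns_false():
    a = exon(10, 19, 370, 400)
    b = exon(10, 19, 445, 475)
    assert not compatible(a, b, CFG)


# ------------------------------------------------------ scores, E-values


def test_gap_penalty_values():
    assert gap_penalty(1) == 0.0
    assert gap_penalty(4) == -4.0
    assert gap_penalty(-3) == -3.0
    assert gap_penalty(0) == 0.0


def test_call_score_two_exons_adjacent():
    a = exon(0, 9, 100, 130, bits=30.0)
    b = exon(10, 19, 200, 230, bits=25.0)  # l = 10 - 9 = 1
    assert call_score([a, b], CFG) == pytest.approx(30 + 25 + math.log2(2),
                                                    rel=1e-9)


def test_call_score_single_exon():
    assert call_score([exon(0, 9, 100, 130, bits=30.0)], CFG) == 30.0


def test_call_score_three_exons_with_gap():
    a = exon(0, 9, 100, 130, bits=20.0)
    b = exon(10, 19, 200, 230, bits=20.0)       # l = 1
    c = exon(24, 33, 300, 330, bits=20.0)       # l = 24 - 19 = 5
    expected = 60 - 5 + math.log2(6)
    assert call_score([a, b, c], CFG) == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(57.5849625, abs=1e-6)


def test_call_score_rejects_incompatible_set():
    a = exon(0, 9, 100, 130, bits=20.0)
    bad = exon(10, 19, 135, 165, bits=20.0)  # contig gap 5 < 15
    with pytest.raises(ValueError):
        call_score([a, bad], CFG)


def test_call_evalue_closed_form():
    assert call_evalue(50.0, 2 ** 20) == pytest.approx(2.0 ** -29, rel=1e-9)
    assert call_evalue(0.0, 1) == 2.0
    assert call_evalue(30.0, 2000) == pytest.approx(
        2 * call_evalue(30.0, 1000), rel=1e-12)
    with pytest.raises(ValueError):
        call_evalue(10.0, 0)


# ------------------------------------------------------------------- DP


def test_dp_single_exon():
    call = best_exon_set([exon(0, 19, 100, 160, bits=30.0)], D=1000, cfg=CFG)
    assert call.k == 1 and call.S_set == 30.0
    assert call.e_value == pytest.approx(call_evalue(30.0, 1000))


def test_dp_picks_best_of_two_incompatible():
    a = exon(0, 9, 100, 130, bits=30.0)
    b = exon(0, 9, 105, 135, bits=40.0, eid="other")
    call = best_exon_set([a, b], D=1000, cfg=CFG)
    assert call.k == 1 and call.S_set == 40.0
    assert call.exons[0].exon_id == "other"


def test_dp_empty_group():
    assert best_exon_set([], D=1000, cfg=CFG) is None


def _random_instance(rng, strand="+", n_max=12):
    n = rng.randint(1, n_max)
    exons = []
    for i in range(n):
        st = rng.randint(0, 80)
        et = st + rng.randint(9, 30)
        width = 3 * rng.randint(10, 40)
        if strand == "+":
            sc = rng.randint(0, 4000)
            ec = sc + width
        else:
            sc = rng.randint(width, 4000 + width)
            ec = sc - width
        exons.append(
            exon(st, et, sc, ec, bits=rng.uniform(5, 60), strand=strand,
                 eid=f"x{i}")
        )
    return exons


def _indep_compatible(a, b, strand):
    """Compatibility re-derived from the printed thresholds (test-local)."""
    if not a.ST < b.ST:
        return False
    if b.ST - a.ET < -10:
        return False
    if strand == "+":
        return a.SC < b.SC and 15 <= b.SC - a.EC <= 10_000
    return a.SC > b.SC and 15 <= a.EC - b.SC <= 10_000


def brute_force_best(exons, strand):
    """Max composite score over every compatible ordered subset."""
    order = sorted(exons, key=lambda e: (e.ST, e.exon_id))
    best = [None]

    def score(chain):
        k = len(chain)
        s = sum(e.bit_score for e in chain)
        for x, y in zip(chain, chain[1:]):
            l = y.ST - x.ET
            s += 0.0 if l == 1 else -abs(l)
        return s + math.log2(math.factorial(k))

    def rec(start, chain):
        if chain:
            s = score(chain)
            if best[0] is None or s > best[0]:
                best[0] = s
        for i in range(start, len(order)):
            if not chain or _indep_compatible(chain[-1], order[i], strand):
                chain.append(order[i])
                rec(i + 1, chain)
                chain.pop()

    rec(0, [])
    return best[0]


@pytest.mark.parametrize("strand", ["+", "-"])
def test_dp_equals_brute_force_enumeration(strand):
    rng = random.Random(42 if strand == "+" else 43)
    for _ in range(250):
        exons = _random_instance(rng, strand)
        expected = brute_force_best(exons, strand)
        call = best_exon_set(exons, D=1000, cfg=CFG)
        assert call.S_set == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_dp_monotone_in_candidate_set():
    rng = random.Random(44)
    for _ in range(100):
        exons = _random_instance(rng)
        extra = _random_instance(rng, n_max=2)
        s1 = best_exon_set(exons, D=1000, cfg=CFG).S_set
        s2 = best_exon_set(exons + extra, D=1000, cfg=CFG).S_set
        assert s2 >= s1 - 1e-9


def test_returned_call_self_consistent():
    rng = random.Random(45)
    for _ in range(100):
        call = best_exon_set(_random_instance(rng), D=1000, cfg=CFG)
        for a, b in zip(call.exons, call.exons[1:]):
            assert compatible(a, b, CFG)
        assert call.S_set == pytest.approx(call_score(call.exons, CFG))
        assert call.e_value == pytest.approx(call_evalue(call.S_set, 1000))
        assert call.k == len(call.exons)


def test_mirror_symmetry_strands(bench_genome, bench_refdb):
    """Reverse-complementing contigs swaps strands but keeps call scores."""
    from splicecall import pipeline
    from splicecall.seqio import Contig
    from splicecall.translate import reverse_complement

    contigs = bench_genome.contigs[:1]
    mirrored = [Contig(id=c.id, seq=reverse_complement(c.seq)) for c in contigs]
    r1 = pipeline.predict(contigs, bench_refdb, CFG)
    r2 = pipeline.predict(mirrored, bench_refdb, CFG)
    s1 = sorted(round(c.S_set, 6) for c in r1.calls)
    s2 = sorted(round(c.S_set, 6) for c in r2.calls)
    assert s1 == s2
    assert sorted(c.strand for c in r1.calls) == sorted(
        {"+": "-", "-": "+"}[c.strand] for c in r2.calls
    )


# --------------------------------------------------------------- filter


class _T:
    def __init__(self, lengths):
        self.lengths = lengths


def _call_with(evalue, protein_len, target="T"):
    e = exon(0, protein_len - 1, 100, 100 + 3 * protein_len)
    call = best_exon_set([e], D=1, cfg=CFG)
    call.e_value = evalue
    call.target_id = target
    return call


def test_filter_calls_evalue_cutoff():
    call = _call_with(1e-3, 60)
    assert filter_calls([call], {"T": 100}, max_call_evalue=1e-4,
                        min_tcov=0.0) == []
    call2 = _call_with(1e-5, 60)
    assert filter_calls([call2], {"T": 100}, max_call_evalue=1e-4,
                        min_tcov=0.0) == [call2]


def test_filter_calls_tcov():
    short = _call_with(1e-9, 50)
    exact = _call_with(1e-9, 60)
    kept = filter_calls([short, exact], {"T": 100}, min_tcov=0.6)
    assert kept == [exact]
    assert filter_calls([short], {"T": 100}, min_tcov=0.0) == [short]
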