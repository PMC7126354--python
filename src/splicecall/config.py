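"""Run-wide configuration objects and scoring constants."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    Gap costs follow the BLAST convention: a gap of length L costs
    ``gap_open + L * gap_extend``. The default lambda/K pair is the standard
    gapped BLOSUM62 11/1 parameterisation, so raw scores convert to bits as
    ``(lambda * raw - ln K) / ln 2``.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lmbda: float = 0.267
    k_param: float = 0.041


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the pipeline, with benchmark defaults.

    ``tara`` preset raises ``min_fragment_aa`` to 40 and ``min_exon_aa``
    to 20 for large-scale runs.
    """

    min_fragment_aa: int = 20
    min_exon_aa: int = 10
    max_exon_evalue: float = 100.0
    max_call_evalue: float = 1e-4
    min_tcov: float = 0.6
    min_intron_nt: int = 15
    max_intron_nt: int = 10_000
    max_target_overlap_aa: int = 10
    genetic_code: int = 1
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    prefilter_kmer: int = 5
    exhaustive_search: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_fragment_aa < 1:
            raise ValueError("min_fragment_aa must be >= 1")
        if self.min_exon_aa < 1:
            raise ValueError("min_exon_aa must be >= 1")
        if self.max_exon_evalue <= 0 or self.max_call_evalue <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if not 0.0 <= self.min_tcov <= 1.0:
            raise ValueError("min_tcov must be in [0, 1]")
        if not 0 < self.min_intron_nt <= self.max_intron_nt:
            raise ValueError("intron bounds must satisfy 0 < min <= max")


def tara_preset(**overrides) -> RunConfig:
    """The large-scale preset: longer fragments and exons."""
    cfg = RunConfig(min_fragment_aa=40, min_exon_aa=20)
    return replace(cfg, **overrides) if overrides else cfg
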