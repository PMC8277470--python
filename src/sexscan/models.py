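"""Shared domain types: gene architecture, fixture configuration and planted truth.

All internal coordinates are 0-based, half-open. GFF3 emission converts to
1-based inclusive. Protein-domain spans are the exception: they follow the
1-based inclusive residue convention used in domain databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

Interval = Tuple[int, int]

DNA_ALPHABET = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class GeneStructure:
    """Exon/intron architecture of one gene copy.

    ``exon_spans`` and ``cds_span`` are in gene-local coordinates (0-based,
    half-open, relative to ``gene_span.start`` on the forward strand).
    ``domain_spans`` are (label, (start, end)) in 1-based inclusive protein
    residue coordinates. Intron ``i`` (1-based) is the gap between exon ``i``
    and exon ``i + 1``.
    """

    gene_id: str
    scaffold: str
    gene_span: Interval
    strand: str
    exon_spans: Tuple[Interval, ...]
    cds_span: Interval
    domain_spans: Tuple[Tuple[str, Interval], ...] = ()

    def __post_init__(self) -> None:
        _check(self.strand in {"+", "-"}, f"strand must be + or -, got {self.strand!r}")
        _check(len(self.exon_spans) > 0, "gene must have at least one exon")
        prev_end = -1
        for s, e in self.exon_spans:
            _check(0 <= s < e, f"empty or negative exon span ({s}, {e})")
            _check(s > prev_end or prev_end == -1, "exon spans must be sorted and non-overlapping")
            _check(s >= prev_end, "exon spans must be sorted and non-overlapping")
            prev_end = e
        gene_len = self.gene_span[1] - self.gene_span[0]
        _check(self.exon_spans[-1][1] <= gene_len, "exons exceed gene span")
        cs, ce = self.cds_span
        _check(cs < ce, "CDS span must be non-empty")
        _check(
            self._contained_in_exons(cs, ce),
            "CDS span must lie within the union of exon spans",
        )
        _check(self.spliced_cds_length % 3 == 0, "spliced CDS length must be divisible by 3")
        plen = self.protein_length
        for label, (ds, de) in self.domain_spans:
            _check(1 <= ds <= de <= plen, f"domain {label!r} span ({ds},{de}) outside [1,{plen}]")

    # -- derived geometry ---------------------------------------------------

    def _contained_in_exons(self, cs: int, ce: int) -> bool:
        # every CDS base must fall in some exon; endpoints must be exonic
        covered_start = any(s <= cs < e for s, e in self.exon_spans)
        covered_end = any(s < ce <= e for s, e in self.exon_spans)
        return covered_start and covered_end

    @property
    def n_exons(self) -> int:
        return len(self.exon_spans)

    @property
    def intron_spans(self) -> Tuple[Interval, ...]:
        return tuple(
            (self.exon_spans[i][1], self.exon_spans[i + 1][0])
            for i in range(self.n_exons - 1)
        )

    @property
    def exon_lengths(self) -> Tuple[int, ...]:
        return tuple(e - s for s, e in self.exon_spans)

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def spliced_cds_length(self) -> int:
        cs, ce = self.cds_span
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exon_spans)

    @property
    def protein_length(self) -> int:
        # minus the stop codon
        return self.spliced_cds_length // 3 - 1

    # -- coordinate maps ----------------------------------------------------

    def feature_at(self, pos: int) -> Tuple[str, int]:
        """Classify a gene-local position as (kind, 1-based ordinal).

        kind is one of exon/intron/upstream/downstream; upstream/downstream
        ordinals are always 1.
        """
        if pos < self.exon_spans[0][0]:
            return ("upstream", 1)
        if pos >= self.exon_spans[-1][1]:
            return ("downstream", 1)
        for i, (s, e) in enumerate(self.exon_spans, start=1):
            if s <= pos < e:
                return ("exon", i)
            if pos < s:
                return ("intron", i - 1)
        raise AssertionError("unreachable")

    def splice(self, gene_seq: str) -> str:
        """Spliced transcript sequence (forward-strand gene-local input)."""
        return "".join(gene_seq[s:e] for s, e in self.exon_spans)

    def spliced_cds(self, gene_seq: str) -> str:
        cs, ce = self.cds_span
        parts = []
        for s, e in self.exon_spans:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                parts.append(gene_seq[lo:hi])
        return "".join(parts)

    def gene_to_transcript(self, pos: int) -> int:
        """Map an exonic gene-local position to transcript coordinates."""
        off = 0
        for s, e in self.exon_spans:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        raise ValidationError(f"position {pos} is not exonic")

    def transcript_exon_ordinal(self, tpos: int) -> int:
        """1-based exon ordinal containing a transcript-coordinate position."""
        off = 0
        for i, n in enumerate(self.exon_lengths, start=1):
            if tpos < off + n:
                return i
            off += n
        raise ValidationError(f"transcript position {tpos} beyond transcript length")

    @property
    def cds_span_in_transcript(self) -> Interval:
        """Transcript-coordinate interval occupied by the CDS."""
        cs, ce = self.cds_span
        return (self.gene_to_transcript(cs), self.gene_to_transcript(ce - 1) + 1)


_DEFAULT_DIVERGENCE = (0.082, 0.050, 0.030, 0.045, 0.035, 0.050, 0.027)

# The printed sex-marker primer pair (forward / reverse, each 5'->3').
DEFAULT_PRIMER_FW = "GTAAACCAAGAACTGAGGAGGAG"
DEFAULT_PRIMER_RV = "GAGAAAAGCAGAAGTGGAATCA"


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic sexed-cohort study.

    Defaults emulate the study design: a 10M/10F resequencing cohort at
    ~30x depth, a 5 kb male-limited duplication with 131+166 bp intron-4
    insertions, a 530-residue protein, per-exon divergence spanning
    ~91.8-97.3% identity, and a 5 bp 'CAGAA' frameshift insertion in the
    last exon of the minor transcript.
    """

    seed: int = 42
    n_males: int = 10
    n_females: int = 10
    mean_depth: float = 30.0
    window_size: int = 1000
    n_scaffolds: int = 2
    scaffold_length: int = 30_000
    male_region_length: int = 5000
    insertion_lengths: Tuple[int, ...] = (131, 166)
    insertion_intron_index: int = 4
    per_exon_divergence: Tuple[float, ...] = _DEFAULT_DIVERGENCE
    cds_protein_length: int = 530
    truncating_insertion: Tuple[str, int] = ("CAGAA", 7)
    primer_fw: str = DEFAULT_PRIMER_FW
    primer_rv: str = DEFAULT_PRIMER_RV

    def __post_init__(self) -> None:
        _check(self.n_males >= 1 and self.n_females >= 1, "need at least 1 sample per sex")
        _check(self.mean_depth > 0, "mean_depth must be positive")
        _check(self.window_size >= 1, "window_size must be >= 1")
        _check(
            self.male_region_length >= self.window_size,
            "male_region_length must be >= window_size",
        )
        _check(self.n_scaffolds >= 2, "need >= 2 scaffolds (autosome + translocation target)")
        for name in ("primer_fw", "primer_rv"):
            p = getattr(self, name)
            _check(
                len(p) > 0 and set(p) <= DNA_ALPHABET,
                f"{name} must be a nonempty string over A/C/G/T",
            )
        _check(
            all(0.0 <= r < 1.0 for r in self.per_exon_divergence),
            "per-exon divergence rates must be in [0, 1)",
        )
        seq, exon = self.truncating_insertion
        _check(set(seq) <= DNA_ALPHABET and len(seq) >= 1, "truncating insertion must be DNA")
        _check(exon >= 1, "truncating insertion exon ordinal must be >= 1")


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    true_region: Tuple[str, Interval]
    sample_sexes: Dict[str, str]
    amha_id: str
    amhy_id: str
    true_insertions: List[Tuple[int, int]]  # (intron ordinal, length)
    transcript_variants: Dict[str, str]  # transcript_id -> {full, truncated}

    def __post_init__(self) -> None:
        _check(
            all(v in {"M", "F"} for v in self.sample_sexes.values()),
            "sample sexes must be M or F",
        )
        _check(
            all(v in {"full", "truncated"} for v in self.transcript_variants.values()),
            "transcript variants must be full or truncated",
        )

    @property
    def region_length(self) -> int:
        _, (s, e) = self.true_region
        return e - s
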