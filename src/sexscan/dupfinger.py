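"""Paralog fingerprinting: pairwise alignment, identity, indel localization,
translation and truncated-transcript classification.

The pairwise aligner is an in-package Gotoh affine-gap dynamic programme
(Smith-Waterman for local mode, Needleman-Wunsch for global mode) with the
scoring defaults of the classic EMBOSS tools: DNA match +5 / mismatch -4,
gap open 10, gap extend 0.5; proteins use BLOSUM62 with the same gap
penalties. Percent identity follows the EMBOSS convention: identical
columns over the full alignment length, gap columns included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from ._affine import affine_align
from .models import GeneStructure, Interval, ValidationError

# ---------------------------------------------------------------------------
# scoring

DNA_DEFAULT_SCORING = (5.0, -4.0, 10.0, 0.5)
PROTEIN_GAP_OPEN = 10.0
PROTEIN_GAP_EXTEND = 0.5

_DNA_ALPHA = "ACGTN"
_DNA_INDEX = {c: i for i, c in enumerate(_DNA_ALPHA)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_PROT_ALPHA = str(_BLOSUM62.alphabet)
_PROT_INDEX = {c: i for i, c in enumerate(_PROT_ALPHA)}
_PROT_MATRIX = np.array(_BLOSUM62, dtype=np.float64)


def _dna_submat(match: float, mismatch: float) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.float64)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches
    m[:, 4] = mismatch
    return m


def _encode(seq: str, index: dict, kind: str) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"character {exc.args[0]!r} not in {kind} alphabet") from None


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal gapped alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    a_span: Interval
    b_span: Interval

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned rows differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class InsertionCall:
    """An indel between two aligned paralogs, assigned to a gene feature."""

    carrier: str  # "A" or "B"
    position_in_carrier: int  # 0-based offset of the inserted block
    length: int
    sequence: str
    feature: Tuple[str, int]  # (kind, 1-based ordinal), in A's gene model


@dataclass
class TranscriptVariantReport:
    transcript_id: str
    insertion: Optional[Tuple[str, int, int]]  # (sequence, length, exon ordinal)
    frameshift: bool
    premature_stop: bool
    predicted_protein_length: int
    lost_domains: List[str]
    insertions: List[Tuple[str, int, int]] = field(default_factory=list)
    ambiguous: bool = False


@dataclass(frozen=True)
class Translation:
    """Translation result: protein up to (excluding) the first stop codon."""

    protein: str
    premature_stop: bool
    stop_codon_index: Optional[int]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.protein


# ---------------------------------------------------------------------------
# operations

Scoring = Union[None, Tuple[float, float, float, float], str]


def align_pair(seq_a: str, seq_b: str, mode: str = "local", scoring: Scoring = None) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment.

    Parameters
    ----------
    mode:
        "local" (Smith-Waterman) or "global" (Needleman-Wunsch).
    scoring:
        None for DNA defaults (5, -4, 10, 0.5); a (match, mismatch,
        gap_open, gap_extend) tuple for DNA; or "blosum62" for proteins.

    Traceback tie-breaking is deterministic: diagonal, then up, then left.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be nonempty")
    if mode not in {"local", "global"}:
        raise ValidationError(f"unknown mode {mode!r}")

    if scoring == "blosum62":
        a = _encode(seq_a, _PROT_INDEX, "protein")
        b = _encode(seq_b, _PROT_INDEX, "protein")
        submat = _PROT_MATRIX
        gap_open, gap_ext = PROTEIN_GAP_OPEN, PROTEIN_GAP_EXTEND
    else:
        match, mismatch, gap_open, gap_ext = scoring or DNA_DEFAULT_SCORING
        a = _encode(seq_a, _DNA_INDEX, "DNA")
        b = _encode(seq_b, _DNA_INDEX, "DNA")
        submat = _dna_submat(match, mismatch)

    score, ops, a_span, b_span = affine_align(a, b, submat, gap_open, gap_ext, mode == "local")

    ra, rb = [], []
    i, j = a_span[0], b_span[0]
    for op in ops:
        if op == "M":
            ra.append(seq_a[i])
            rb.append(seq_b[j])
            i += 1
            j += 1
        elif op == "X":
            ra.append(seq_a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(seq_b[j])
            j += 1
    return PairwiseAlignment(
        aligned_a="".join(ra),
        aligned_b="".join(rb),
        score=round(score, 6),
        mode=mode,
        a_span=a_span,
        b_span=b_span,
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identity as 100 x identical columns / alignment length (gaps count)."""
    if aln.length == 0:
        raise ValidationError("empty alignment")
    ident = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != "-" and x.upper() == y.upper()
    )
    return 100.0 * ident / aln.length


def exonwise_identity(
    gene_a: str,
    gene_b: str,
    struct_a: GeneStructure,
    struct_b: GeneStructure,
    mode: str = "local",
) -> pd.DataFrame:
    """Per-exon percent identity between two paralogs.

    Each exon pair is aligned independently (local by default; global as an
    option) and scored with :func:`percent_identity`.
    """
    if struct_a.n_exons != struct_b.n_exons:
        raise ValidationError(
            f"exon count mismatch: {struct_a.n_exons} vs {struct_b.n_exons}"
        )
    rows = []
    for i in range(struct_a.n_exons):
        sa, ea = struct_a.exon_spans[i]
        sb, eb = struct_b.exon_spans[i]
        aln = align_pair(gene_a[sa:ea], gene_b[sb:eb], mode=mode)
        rows.append({"exon": i + 1, "identity_pct": percent_identity(aln)})
    return pd.DataFrame(rows)


def localize_indels(
    aln: PairwiseAlignment,
    struct_of_a: GeneStructure,
    min_indel_length: int = 10,
) -> List[InsertionCall]:
    """Turn long gap runs of a global alignment into feature-assigned calls.

    A gap run in row A means sequence B carries an insertion (and vice
    versa). The call's feature is the gene feature of A at the projected
    insertion point (intron i lies between exons i and i+1).
    """
    calls: List[InsertionCall] = []
    a_pos, b_pos = aln.a_span[0], aln.b_span[0]
    run_row: Optional[str] = None
    run_start_a = run_start_b = 0
    run_seq: List[str] = []

    def flush() -> None:
        nonlocal run_row, run_seq
        if run_row is not None and len(run_seq) >= min_indel_length:
            seq = "".join(run_seq)
            if run_row == "a":  # gap in A => B carries the insertion
                calls.append(
                    InsertionCall(
                        carrier="B",
                        position_in_carrier=run_start_b,
                        length=len(seq),
                        sequence=seq,
                        feature=struct_of_a.feature_at(run_start_a),
                    )
                )
            else:
                calls.append(
                    InsertionCall(
                        carrier="A",
                        position_in_carrier=run_start_a,
                        length=len(seq),
                        sequence=seq,
                        feature=struct_of_a.feature_at(run_start_a),
                    )
                )
        run_row, run_seq = None, []

    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-":
            if run_row != "a":
                flush()
                run_row, run_start_a, run_start_b, run_seq = "a", a_pos, b_pos, []
            run_seq.append(y)
            b_pos += 1
        elif y == "-":
            if run_row != "b":
                flush()
                run_row, run_start_a, run_start_b, run_seq = "b", a_pos, b_pos, []
            run_seq.append(x)
            a_pos += 1
        else:
            flush()
            a_pos += 1
            b_pos += 1
    flush()
    return calls


_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_cds(spliced_cds: str, allow_internal_stop: bool = False) -> Translation:
    """Standard-code translation of a spliced CDS.

    Stops at the first stop codon. ``premature_stop`` is set when coding
    sequence remains beyond that stop. With ``allow_internal_stop`` the
    length-divisible-by-3 precondition is relaxed (frameshift analysis) and
    a trailing partial codon is ignored.
    """
    seq = spliced_cds.upper()
    if not allow_internal_stop and len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} not divisible by 3")
    n_codons = len(seq) // 3
    protein = []
    for k in range(n_codons):
        codon = seq[3 * k : 3 * k + 3]
        if codon in _STOP_CODONS:
            return Translation(
                protein="".join(protein),
                premature_stop=k < n_codons - 1,
                stop_codon_index=k,
            )
        try:
            protein.append(_CODON_TABLE[codon])
        except KeyError:
            bad = next(i for i, c in enumerate(codon) if c not in "ACGT")
            raise ValidationError(
                f"non-ACGT base {codon[bad]!r} at position {3 * k + bad}"
            ) from None
    return Translation(protein="".join(protein), premature_stop=False, stop_codon_index=None)


def domain_identity(
    prot_a: str,
    prot_b: str,
    domains: Sequence[Tuple[str, Interval]],
) -> pd.DataFrame:
    """Percent identity for the full protein pair and each annotated domain.

    Domain spans are 1-based inclusive residue coordinates and must fit
    within both proteins; each span is globally aligned on its own.
    """
    for label, (s, e) in domains:
        if not (1 <= s <= e <= len(prot_a) and e <= len(prot_b)):
            raise ValidationError(
                f"domain {label!r} span ({s},{e}) outside protein lengths "
                f"{len(prot_a)}/{len(prot_b)}"
            )
    rows = []
    full = align_pair(prot_a, prot_b, mode="global", scoring="blosum62")
    rows.append({"label": "full", "identity_pct": percent_identity(full)})
    for label, (s, e) in domains:
        aln = align_pair(prot_a[s - 1 : e], prot_b[s - 1 : e], mode="global", scoring="blosum62")
        rows.append({"label": label, "identity_pct": percent_identity(aln)})
    return pd.DataFrame(rows)


def classify_transcript_variant(
    variant_tx: str,
    reference_tx: str,
    struct: GeneStructure,
    domains: Sequence[Tuple[str, Interval]],
    transcript_id: str = "variant",
) -> TranscriptVariantReport:
    """Characterize a transcript variant against the full-length reference.

    Global alignment detects insertions in the variant; each is mapped to
    the exon it interrupts in the reference gene model. An insertion inside
    the CDS whose length is not a multiple of 3 is a frameshift; the mutant
    CDS is re-translated to find the premature stop, and any domain lying
    entirely at or beyond the truncation point is reported as lost.
    """
    aln = align_pair(variant_tx, reference_tx, mode="global")
    # gaps in the reference row = material inserted in the variant
    ins_events: List[Tuple[int, str]] = []  # (ref position of insertion point, seq)
    ref_pos = 0
    run: List[str] = []
    run_ref = 0
    for v, r in zip(aln.aligned_a, aln.aligned_b):
        if r == "-":
            if not run:
                run_ref = ref_pos
            run.append(v)
        else:
            if run:
                ins_events.append((run_ref, "".join(run)))
                run = []
            ref_pos += 1
    if run:
        ins_events.append((run_ref, "".join(run)))

    cds_lo, cds_hi = struct.cds_span_in_transcript
    ref_cds = reference_tx[cds_lo:cds_hi]
    ref_protein_len = struct.protein_length

    reported = []
    cds_insertions: List[Tuple[int, str]] = []
    for pos, seq in ins_events:
        exon = struct.transcript_exon_ordinal(min(pos, len(reference_tx) - 1))
        reported.append((seq, len(seq), exon))
        if cds_lo < pos < cds_hi:
            cds_insertions.append((pos - cds_lo, seq))

    frameshift = any(len(s) % 3 != 0 for _, s in cds_insertions)

    predicted_len = ref_protein_len
    premature = False
    if cds_insertions:
        mut = ref_cds
        for off, seq in sorted(cds_insertions, reverse=True):
            mut = mut[:off] + seq + mut[off:]
        tr = translate_cds(mut, allow_internal_stop=True)
        predicted_len = len(tr.protein)
        premature = tr.premature_stop or predicted_len < ref_protein_len

    lost = [label for label, (s, _e) in domains if premature and s > predicted_len]

    return TranscriptVariantReport(
        transcript_id=transcript_id,
        insertion=reported[0] if reported else None,
        frameshift=frameshift,
        premature_stop=premature,
        predicted_protein_length=predicted_len,
        lost_domains=lost,
        insertions=reported,
        ambiguous=len(reported) > 1,
    )
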