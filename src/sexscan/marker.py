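"""Insertion-spanning PCR sex marker: binding-site search, in-silico PCR,
gel band-pattern prediction, sex calling and primer design.

The genotype model is a template multiset: a female contributes only the
autosomal paralog, a male contributes both the autosomal and the
male-limited copy, so an assay spanning a male-limited insertion reads out
as one band in females and two in males. Band intensity is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dupfinger import InsertionCall
from .models import DNA_ALPHABET, ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2*(A+T) + 4*(G+C), in deg C."""
    p = primer.upper()
    at = p.count("A") + p.count("T")
    gc = p.count("G") + p.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair, both given 5'->3'."""

    fw: str
    rv: str

    def __post_init__(self) -> None:
        for name, p in (("fw", self.fw), ("rv", self.rv)):
            if not (15 <= len(p) <= 35):
                raise ValidationError(f"{name} primer length {len(p)} outside [15, 35]")
            if not set(p.upper()) <= DNA_ALPHABET:
                raise ValidationError(f"{name} primer has non-ACGT characters")

    @property
    def tm_fw(self) -> float:
        return wallace_tm(self.fw)

    @property
    def tm_rv(self) -> float:
        return wallace_tm(self.rv)


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # forward-strand, 0-based half-open
    end: int
    length: int


@dataclass(frozen=True)
class BandPattern:
    sample_id: str
    band_sizes: Tuple[float, ...]
    n_bands: int


def find_binding_sites(
    template: str,
    primer: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> List[Tuple[int, str, int]]:
    """All primer annealing sites on both strands of a template.

    A site qualifies when the total mismatch count is at most
    ``max_mismatch`` and the 3'-terminal ``three_prime_exact`` bases match
    exactly. Returned as (forward-strand start, strand, mismatches).
    """
    t = np.frombuffer(template.upper().encode(), dtype="S1")
    k = len(primer)
    if k >= len(template):
        raise ValidationError("primer must be shorter than the template")
    sites: List[Tuple[int, str, int]] = []
    for strand, probe in (("+", primer.upper()), ("-", revcomp(primer))):
        p = np.frombuffer(probe.encode(), dtype="S1")
        n_off = len(template) - k + 1
        mism = np.zeros(n_off, dtype=np.int64)
        for q in range(k):
            mism += t[q : q + n_off] != p[q]
        # 3' end: last bases of the probe on '+', first bases on '-'
        if three_prime_exact > 0:
            exact = np.zeros(n_off, dtype=np.int64)
            if strand == "+":
                span = range(k - three_prime_exact, k)
            else:
                span = range(0, three_prime_exact)
            for q in span:
                exact += t[q : q + n_off] != p[q]
            ok = (mism <= max_mismatch) & (exact == 0)
        else:
            ok = mism <= max_mismatch
        for pos in np.flatnonzero(ok):
            sites.append((int(pos), strand, int(mism[pos])))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def insilico_pcr(
    templates: Sequence[Tuple[str, str]],
    pair: PrimerPair,
    max_product: int = 3000,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> List[Amplicon]:
    """Predict PCR products on each template.

    Any convergent combination of the two primers (forward site on the
    plus strand with reverse site on the minus strand, in either primer
    assignment) with product length in (0, max_product] amplifies.
    """
    primer_len = {0: len(pair.fw), 1: len(pair.rv)}
    amplicons: List[Amplicon] = []
    for template_id, seq in templates:
        per_primer = []
        for p in (pair.fw, pair.rv):
            per_primer.append(
                find_binding_sites(seq, p, max_mismatch=max_mismatch, three_prime_exact=three_prime_exact)
            )
        combos = [(0, 1), (1, 0)] if pair.fw != pair.rv else [(0, 1)]
        seen = set()
        for left_idx, right_idx in combos:
            lefts = [s for s in per_primer[left_idx] if s[1] == "+"]
            rights = [s for s in per_primer[right_idx] if s[1] == "-"]
            for lpos, _, _ in lefts:
                for rpos, _, _ in rights:
                    start = lpos
                    end = rpos + primer_len[right_idx]
                    length = end - start
                    if 0 < length <= max_product and (start, end) not in seen:
                        seen.add((start, end))
                        amplicons.append(
                            Amplicon(template_id=template_id, start=start, end=end, length=length)
                        )
    amplicons.sort(key=lambda a: (a.template_id, a.start, a.end))
    return amplicons


def amplicon_sequence(templates: Sequence[Tuple[str, str]], amp: Amplicon) -> str:
    """Extract an amplicon's forward-strand sequence for verification."""
    for template_id, seq in templates:
        if template_id == amp.template_id:
            return seq[amp.start : amp.end]
    raise ValidationError(f"template {amp.template_id!r} not found")


def band_pattern(
    amplicons: Sequence[Amplicon],
    resolution: float = 50.0,
    sample_id: str = "",
) -> BandPattern:
    """Cluster amplicon lengths into distinguishable gel bands.

    Lengths are sorted ascending and chained greedily: a length within
    ``resolution`` of the previous one joins its band (single linkage on a
    line); each band is reported at the mean of its member lengths.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    lengths = sorted(a.length for a in amplicons)
    bands: List[List[int]] = []
    for ln in lengths:
        if bands and ln - bands[-1][-1] <= resolution:
            bands[-1].append(ln)
        else:
            bands.append([ln])
    sizes = tuple(float(np.mean(b)) for b in bands)
    return BandPattern(sample_id=sample_id, band_sizes=sizes, n_bands=len(sizes))


def call_sex(pattern: BandPattern) -> str:
    """Two bands -> male, one band -> female, anything else -> ambiguous."""
    if pattern.n_bands == 2:
        return "male"
    if pattern.n_bands == 1:
        return "female"
    return "ambiguous"


@dataclass(frozen=True)
class DesignConstraints:
    primer_len: Tuple[int, int] = (18, 25)
    tm_range: Tuple[float, float] = (50.0, 68.0)
    max_tm_diff: float = 5.0
    product_range: Tuple[int, int] = (100, 1000)
    resolution: float = 50.0


@dataclass
class PrimerDesign:
    pair: PrimerPair
    product_a: int
    product_b: int
    tm_diff: float


@dataclass
class NoDesign:
    """Structured failure: which constraint rejected most candidates."""

    reason: str
    rejected: Dict[str, int] = field(default_factory=dict)


def _self_complementary_3prime(primer: str, run: int = 4) -> bool:
    tail = primer[-run:]
    return tail == revcomp(tail)


def design_marker_primers(
    gene_a: str,
    gene_b: str,
    insertion: InsertionCall,
    constraints: DesignConstraints = DesignConstraints(),
    search_span: int = 300,
    max_candidates: int = 60,
) -> List[PrimerDesign] | NoDesign:
    """Design insertion-spanning primer pairs discriminating two paralogs.

    Candidate primers are drawn from sequence flanking the insertion in its
    carrier that occurs exactly once in BOTH paralogs (so both templates
    amplify); the pair must put both products in range, separated by at
    least the gel resolution, with matched Wallace Tm and no
    self-complementary 3' tetramer. Ranked by (|dTm|, distance of the
    smaller product from the product-range midpoint).
    """
    carrier_seq = gene_b if insertion.carrier == "B" else gene_a
    ins_lo = insertion.position_in_carrier
    ins_hi = ins_lo + insertion.length

    up = carrier_seq[max(0, ins_lo - search_span) : ins_lo]
    down = carrier_seq[ins_hi : ins_hi + search_span]

    rejected = {"not_shared": 0, "tm": 0, "self_complementary": 0, "product": 0, "resolution": 0, "tm_diff": 0}

    def shared_unique(sub: str) -> bool:
        return gene_a.count(sub) == 1 and gene_b.count(sub) == 1

    def candidates(flank: str, reverse: bool) -> List[str]:
        lo, hi = constraints.primer_len
        out = []
        for length in range(lo, hi + 1):
            for start in range(0, len(flank) - length + 1):
                sub = flank[start : start + length]
                primer = revcomp(sub) if reverse else sub
                if not shared_unique(sub):
                    rejected["not_shared"] += 1
                    continue
                tm = wallace_tm(primer)
                if not (constraints.tm_range[0] <= tm <= constraints.tm_range[1]):
                    rejected["tm"] += 1
                    continue
                if _self_complementary_3prime(primer):
                    rejected["self_complementary"] += 1
                    continue
                out.append(primer)
                if len(out) >= max_candidates:
                    return out
        return out

    fws = candidates(up, reverse=False)
    rvs = candidates(down, reverse=True)

    designs: List[PrimerDesign] = []
    lo_p, hi_p = constraints.product_range
    mid = 0.5 * (lo_p + hi_p)
    for fw in fws:
        a_f = gene_a.find(fw)
        b_f = gene_b.find(fw)
        for rv in rvs:
            site = revcomp(rv)
            a_r = gene_a.find(site)
            b_r = gene_b.find(site)
            prod_a = a_r + len(site) - a_f
            prod_b = b_r + len(site) - b_f
            if not (lo_p <= prod_a <= hi_p and lo_p <= prod_b <= hi_p):
                rejected["product"] += 1
                continue
            if abs(prod_b - prod_a) < constraints.resolution:
                rejected["resolution"] += 1
                continue
            dtm = abs(wallace_tm(fw) - wallace_tm(rv))
            if dtm > constraints.max_tm_diff:
                rejected["tm_diff"] += 1
                continue
            designs.append(
                PrimerDesign(pair=PrimerPair(fw=fw, rv=rv), product_a=prod_a, product_b=prod_b, tm_diff=dtm)
            )
    if not designs:
        worst = max(rejected, key=rejected.get)
        return NoDesign(reason=f"no feasible pair; most candidates failed {worst!r}", rejected=rejected)
    designs.sort(key=lambda d: (d.tm_diff, abs(min(d.product_a, d.product_b) - mid)))
    return designs


def genotype_templates(
    sex: str,
    amha: Tuple[str, str],
    amhy: Tuple[str, str],
) -> List[Tuple[str, str]]:
    """Template multiset of a diploid genotype: female {amha}, male {amha, amhy}."""
    if sex not in {"M", "F"}:
        raise ValidationError(f"sex must be M or F, got {sex!r}")
    return [amha, amhy] if sex == "M" else [amha]
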