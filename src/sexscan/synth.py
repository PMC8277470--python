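"""Synthetic sexed-cohort study generator with machine-readable planted truth.

The generator emulates the design of a duplicated-gene sex-determination
study in an XX/XY diploid: an autosomal seven-exon gene (the *amha*-like
copy) plus a male-limited duplicated, translocated copy (the *amhy*-like
copy) carrying per-exon substitutions, intron insertions of configured
lengths, primer binding sites shared by both paralogs, and a minor
transcript isoform truncated by a short frameshift insertion in the last
exon. Read depth is simulated directly per base (Poisson), not via read
simulation: the downstream pipeline consumes depth tracks, so nothing
upstream of depth is modelled.

Everything random derives from ``FixtureConfig.seed`` through fixed-order
substreams, so regeneration is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .dupfinger import translate_cds
from .expression import CountMatrix
from .marker import PrimerPair, genotype_templates, insilico_pcr, revcomp
from .models import FixtureConfig, GeneStructure, TruthTable, ValidationError

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# Seven-exon architecture (bases): 5'UTR and 3'UTR sit in the terminal
# exons; CDS length is set by the configured protein length, with the
# remainder of the coding sequence in the last exon.
_FIVE_UTR = 150
_THREE_UTR = 200
_CDS_IN_EXON = (60, 150, 160, 170, 180, 160)  # exons 1-6; exon 7 takes the rest
_INTRON_LENGTHS = (400, 350, 500, 450, 380, 420)
_N_EXONS = 7

RETRY_BUDGET = 100


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


@dataclass
class FixtureGenes:
    """The paralog pair plus its transcript isoforms."""

    amha_seq: str
    amha_struct: GeneStructure
    amhy_seq: str
    amhy_struct: GeneStructure
    transcripts: Dict[str, str]  # amha-full / amha-truncated / amhy-full / amhy-truncated
    config: FixtureConfig

    @property
    def domains(self) -> Tuple[Tuple[str, Tuple[int, int]], ...]:
        return self.amha_struct.domain_spans


def _architecture(config: FixtureConfig) -> Tuple[Tuple[int, ...], int, int]:
    """Exon lengths, CDS length and exon-7 CDS share for a protein length."""
    cds_len = 3 * (config.cds_protein_length + 1)  # incl. stop codon
    cds7 = cds_len - sum(_CDS_IN_EXON)
    if cds7 < 30:
        raise ValidationError(
            f"cds_protein_length {config.cds_protein_length} too short for the "
            "seven-exon architecture"
        )
    exon_lengths = (
        _FIVE_UTR + _CDS_IN_EXON[0],
        *_CDS_IN_EXON[1:],
        cds7 + _THREE_UTR,
    )
    return exon_lengths, cds_len, cds7


def _build_structure(
    gene_id: str,
    scaffold: str,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    domains: Sequence[Tuple[str, Tuple[int, int]]],
    cds7: int,
) -> GeneStructure:
    spans = []
    pos = 0
    for i, n in enumerate(exon_lengths):
        spans.append((pos, pos + n))
        pos += n
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    cds_start = spans[0][0] + _FIVE_UTR
    cds_end = spans[-1][0] + cds7
    return GeneStructure(
        gene_id=gene_id,
        scaffold=scaffold,
        gene_span=(0, pos),
        strand="+",
        exon_spans=tuple(spans),
        cds_span=(cds_start, cds_end),
        domain_spans=tuple(domains),
    )


def _diverge_exons(
    transcript: str,
    exon_bounds: Sequence[Tuple[int, int]],
    cds_tx: Tuple[int, int],
    rates: Sequence[float],
    rng: np.random.Generator,
) -> str:
    """Apply round(rate * len) substitutions per exon, never creating an
    in-frame stop codon (resampled within a retry budget)."""
    seq = list(transcript)
    cds_lo, cds_hi = cds_tx
    # start and stop codons are invariant (both proteins are full length)
    frozen = set(range(cds_lo, cds_lo + 3)) | set(range(cds_hi - 3, cds_hi))
    for (s, e), rate in zip(exon_bounds, rates):
        k = round(rate * (e - s))
        if k == 0:
            continue
        candidates = np.array([p for p in range(s, e) if p not in frozen])
        positions = rng.choice(candidates, size=k, replace=False)
        for pos in positions:
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            ok = False
            for _ in range(RETRY_BUDGET):
                new = choices[rng.integers(0, 3)]
                seq[pos] = new
                if cds_lo <= pos < cds_hi:
                    c0 = cds_lo + 3 * ((pos - cds_lo) // 3)
                    if "".join(seq[c0 : c0 + 3]) in _STOPS:
                        seq[pos] = old
                        continue
                ok = True
                break
            if not ok:
                raise ValidationError(
                    f"could not substitute position {pos} without creating a stop "
                    f"codon within {RETRY_BUDGET} retries"
                )
    return "".join(seq)


def _truncating_site(
    cds_full: Sequence[str],
    ins_seq: str,
    codon_range: Tuple[int, int],
    forbidden_from: int,
) -> int:
    """First codon boundary where inserting ins_seq into every CDS truncates
    the protein before ``forbidden_from`` (the first residue of the domain
    that must be lost). Returns the 0-based codon index."""
    in_frame = len(ins_seq) % 3 == 0
    lo, hi = codon_range
    if in_frame:
        return (lo + hi) // 2
    for c in range(lo, hi):
        ok = True
        for cds in cds_full:
            mut = cds[: 3 * c] + ins_seq + cds[3 * c :]
            tr = translate_cds(mut, allow_internal_stop=True)
            if not tr.premature_stop or len(tr.protein) >= forbidden_from:
                ok = False
                break
        if ok:
            return c
    raise ValidationError(
        "no insertion site yields a premature stop upstream of the terminal domain"
    )


def build_fixture_genes(config: FixtureConfig) -> FixtureGenes:
    """Construct the paralog pair and the four transcript isoforms.

    The male-limited copy is the autosomal copy with (a) per-exon
    substitutions at the configured rates, (b) the configured insertions in
    the configured intron, and (c) both primer binding sites embedded
    identically in both copies flanking the last insertion. Raises if the
    design cannot be realized within the retry budget.
    """
    if len(config.per_exon_divergence) != _N_EXONS:
        raise ValidationError(
            f"per_exon_divergence must list {_N_EXONS} rates, got "
            f"{len(config.per_exon_divergence)}"
        )
    exon_lengths, cds_len, cds7 = _architecture(config)
    plen = config.cds_protein_length
    tgf_start = plen - 92  # C-terminal receptor-binding domain
    domains = (
        ("AMH_N", (25, min(400, tgf_start - 20))),
        ("TGF-beta", (tgf_start, plen)),
    )

    intron_idx = config.insertion_intron_index  # 1-based
    if not (1 <= intron_idx <= _N_EXONS - 1):
        raise ValidationError(f"insertion_intron_index {intron_idx} outside [1, {_N_EXONS - 1}]")
    host_len = _INTRON_LENGTHS[intron_idx - 1]
    n_ins = len(config.insertion_lengths)
    offsets = [round(host_len * (j + 1) / (n_ins + 2)) for j in range(n_ins)]

    fw, rv = config.primer_fw, config.primer_rv
    rv_site = revcomp(rv)
    if n_ins:
        anchor = offsets[-1]
        fw_start = anchor - len(fw) - 60
        rv_start = anchor + 80
        prev = offsets[-2] if n_ins > 1 else 0
        if fw_start <= prev or rv_start + len(rv_site) > host_len:
            raise ValidationError("host intron too short to embed primer sites")

    for attempt in range(10):
        rng = np.random.default_rng([config.seed, 0, attempt])

        # coding sequence: ATG + random non-stop codons + TAA
        codons = ["ATG"]
        codons += [
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=plen - 1)
        ]
        codons.append("TAA")
        cds_a = "".join(codons)
        transcript_a = _random_dna(rng, _FIVE_UTR) + cds_a + _random_dna(rng, _THREE_UTR)

        introns_a = [_random_dna(rng, n) for n in _INTRON_LENGTHS]
        if n_ins:
            host = list(introns_a[intron_idx - 1])
            host[fw_start : fw_start + len(fw)] = fw
            host[rv_start : rv_start + len(rv_site)] = rv_site
            introns_a[intron_idx - 1] = "".join(host)

        # exon bounds in transcript coordinates
        bounds = []
        pos = 0
        for n in exon_lengths:
            bounds.append((pos, pos + n))
            pos += n
        cds_tx = (_FIVE_UTR, _FIVE_UTR + cds_len)

        transcript_b = _diverge_exons(
            transcript_a, bounds, cds_tx, config.per_exon_divergence, rng
        )

        ins_seqs = [_random_dna(rng, n) for n in config.insertion_lengths]
        introns_b = list(introns_a)
        host_b = introns_a[intron_idx - 1]
        parts = []
        prev_off = 0
        for off, ins in zip(offsets, ins_seqs):
            parts.append(host_b[prev_off:off])
            parts.append(ins)
            prev_off = off
        parts.append(host_b[prev_off:])
        introns_b[intron_idx - 1] = "".join(parts)

        def assemble(bounds, transcript, introns):
            pieces = []
            for i, (s, e) in enumerate(bounds):
                pieces.append(transcript[s:e])
                if i < len(introns):
                    pieces.append(introns[i])
            return "".join(pieces)

        amha_seq = assemble(bounds, transcript_a, introns_a)
        amhy_seq = assemble(bounds, transcript_b, introns_b)

        amha_struct = _build_structure("amha", "", exon_lengths, _INTRON_LENGTHS, domains, cds7)
        intron_lengths_b = list(_INTRON_LENGTHS)
        intron_lengths_b[intron_idx - 1] += sum(config.insertion_lengths)
        amhy_struct = _build_structure("amhy", "", exon_lengths, intron_lengths_b, domains, cds7)

        if n_ins and (fw not in amha_seq or fw not in amhy_seq or rv_site not in amha_seq or rv_site not in amhy_seq):
            raise ValidationError("divergence mutated a primer binding site")

        # the assay must see exactly one clean product per paralog
        if n_ins:
            pair = PrimerPair(fw=fw, rv=rv)
            amps_a = insilico_pcr([("amha", amha_seq)], pair)
            amps_b = insilico_pcr([("amhy", amhy_seq)], pair)
            clean = (
                len(amps_a) == 1
                and len(amps_b) == 1
                and amps_b[0].length - amps_a[0].length == config.insertion_lengths[-1]
            )
            if not clean:
                continue  # spurious approximate binding site; redraw

        # sanity: both proteins full length, no internal stops
        for seq, struct in ((amha_seq, amha_struct), (amhy_seq, amhy_struct)):
            tr = translate_cds(struct.spliced_cds(seq))
            if tr.premature_stop or len(tr.protein) != plen:
                raise ValidationError("generated CDS does not translate to full length")

        # transcript isoforms: minor isoform truncated by a short insertion
        ins_seq, ins_exon = config.truncating_insertion
        cds_b = amhy_struct.spliced_cds(amhy_seq)
        exon_lo = max(bounds[ins_exon - 1][0], cds_tx[0])
        exon_hi = min(bounds[ins_exon - 1][1], cds_tx[1])
        if exon_lo >= exon_hi:
            raise ValidationError(f"exon {ins_exon} has no coding sequence to interrupt")
        c_lo = (exon_lo - cds_tx[0] + 2) // 3 + 1
        c_hi = min((exon_hi - cds_tx[0]) // 3, tgf_start - 2)
        site = _truncating_site((cds_a, cds_b), ins_seq, (c_lo, c_hi), tgf_start)
        t_ins = cds_tx[0] + 3 * site  # transcript coordinate of the insertion point

        transcripts = {
            "amha-full": transcript_a,
            "amha-truncated": transcript_a[:t_ins] + ins_seq + transcript_a[t_ins:],
            "amhy-full": transcript_b,
            "amhy-truncated": transcript_b[:t_ins] + ins_seq + transcript_b[t_ins:],
        }
        return FixtureGenes(
            amha_seq=amha_seq,
            amha_struct=amha_struct,
            amhy_seq=amhy_seq,
            amhy_struct=amhy_struct,
            transcripts=transcripts,
            config=config,
        )
    raise ValidationError("could not realize a clean fixture within 10 redraws")


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SyntheticCohort:
    genome: Dict[str, str]
    structures: List[GeneStructure]
    depth: Dict[str, List[Tuple[str, np.ndarray]]]  # sample -> per-scaffold depth
    truth: TruthTable
    genes: FixtureGenes
    config: FixtureConfig


def build_cohort(
    config: FixtureConfig,
    genes: FixtureGenes,
    outdir: Optional[str] = None,
) -> SyntheticCohort:
    """Simulate the sexed diploid cohort around the paralog pair.

    The autosomal copy sits on the first scaffold; the male-limited copy is
    translocated to the second scaffold inside a region of
    ``male_region_length`` whose boundaries fall on the window grid. Depth
    per base is Poisson(mean_depth) everywhere except that region, where
    females have zero depth and males have Poisson(mean_depth / 2)
    (hemizygous single copy).
    """
    L = config.scaffold_length
    region_len = config.male_region_length
    amhy_len = len(genes.amhy_seq)
    if amhy_len > region_len:
        raise ValidationError(
            f"male-limited gene ({amhy_len} bp) exceeds male_region_length ({region_len})"
        )
    region_start = ((L - region_len) // 2 // config.window_size) * config.window_size
    if region_start <= 0 or region_start + region_len > L:
        raise ValidationError(f"scaffold_length {L} too short to host the region")

    rng = np.random.default_rng([config.seed, 1])
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    genome = {s: _random_dna(rng, L) for s in scaffolds}

    amha_pos = min(10_000, L - len(genes.amha_seq) - 1)
    if amha_pos <= 0:
        raise ValidationError(f"scaffold_length {L} too short to host the autosomal gene")
    g = genome[scaffolds[0]]
    genome[scaffolds[0]] = g[:amha_pos] + genes.amha_seq + g[amha_pos + len(genes.amha_seq) :]
    amhy_pos = region_start + (region_len - amhy_len) // 2
    g = genome[scaffolds[1]]
    genome[scaffolds[1]] = g[:amhy_pos] + genes.amhy_seq + g[amhy_pos + amhy_len :]

    def placed(struct: GeneStructure, scaffold: str, pos: int) -> GeneStructure:
        return GeneStructure(
            gene_id=struct.gene_id,
            scaffold=scaffold,
            gene_span=(pos, pos + (struct.gene_span[1] - struct.gene_span[0])),
            strand=struct.strand,
            exon_spans=struct.exon_spans,
            cds_span=struct.cds_span,
            domain_spans=struct.domain_spans,
        )

    structures = [
        placed(genes.amha_struct, scaffolds[0], amha_pos),
        placed(genes.amhy_struct, scaffolds[1], amhy_pos),
    ]

    samples = [f"M{i + 1:02d}" for i in range(config.n_males)] + [
        f"F{i + 1:02d}" for i in range(config.n_females)
    ]
    sexes = {s: s[0] for s in samples}

    depth: Dict[str, List[Tuple[str, np.ndarray]]] = {}
    for sample in samples:
        tracks = []
        for scaffold in scaffolds:
            d = rng.poisson(config.mean_depth, size=L).astype(np.int64)
            if scaffold == scaffolds[1]:
                if sexes[sample] == "F":
                    d[region_start : region_start + region_len] = 0
                else:
                    d[region_start : region_start + region_len] = rng.poisson(
                        config.mean_depth / 2.0, size=region_len
                    )
            tracks.append((scaffold, d))
        depth[sample] = tracks

    truth = TruthTable(
        true_region=(scaffolds[1], (region_start, region_start + region_len)),
        sample_sexes=sexes,
        amha_id="amha",
        amhy_id="amhy",
        true_insertions=[
            (config.insertion_intron_index, n) for n in config.insertion_lengths
        ],
        transcript_variants={
            "amha-full": "full",
            "amha-truncated": "truncated",
            "amhy-full": "full",
            "amhy-truncated": "truncated",
        },
    )
    cohort = SyntheticCohort(
        genome=genome,
        structures=structures,
        depth=depth,
        truth=truth,
        genes=genes,
        config=config,
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Emit the cohort as plain-text files (FASTA/GFF3/TSV/YAML)."""
    os.makedirs(outdir, exist_ok=True)
    depth_dir = os.path.join(outdir, "depth")
    os.makedirs(depth_dir, exist_ok=True)
    sio.write_fasta(
        os.path.join(outdir, "genome.fa"), list(cohort.genome.items())
    )
    sio.write_gff3(os.path.join(outdir, "annotation.gff3"), cohort.structures)
    sio.write_fasta(
        os.path.join(outdir, "transcripts.fa"), list(cohort.genes.transcripts.items())
    )
    sio.write_fasta(
        os.path.join(outdir, "genes.fa"),
        [("amha", cohort.genes.amha_seq), ("amhy", cohort.genes.amhy_seq)],
    )
    for sample, tracks in cohort.depth.items():
        sio.write_depth_tsv(os.path.join(depth_dir, f"{sample}.depth.tsv"), tracks)
    sio.write_sample_sheet(os.path.join(outdir, "samples.tsv"), cohort.truth.sample_sexes)
    sio.write_truth_table(os.path.join(outdir, "truth.txt"), cohort.truth)
    sio.write_domains_tsv(os.path.join(outdir, "domains.tsv"), cohort.genes.domains)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(cohort.config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# expression

_TISSUES = ("gonad", "liver", "brain", "muscle")
_REPS = 3
_N_BACKGROUND = 40

# expected counts per (transcript, tissue); the male-limited copy is forced
# to zero in every female sample
_FOCAL_MEANS = {
    "amha-full": {"gonad": 500.0, "liver": 20.0, "brain": 20.0, "muscle": 5.0},
    "amha-truncated": {"gonad": 120.0, "liver": 5.0, "brain": 5.0, "muscle": 1.0},
    "amhy-full": {"gonad": 600.0, "liver": 15.0, "brain": 10.0, "muscle": 2.0},
    "amhy-truncated": {"gonad": 150.0, "liver": 4.0, "brain": 2.0, "muscle": 0.0},
}


def build_expression_fixture(
    config: FixtureConfig, genes: Optional[FixtureGenes] = None
) -> CountMatrix:
    """Transcript counts for a sexed tissue survey.

    Four focal isoforms plus background transcripts across a tissue x sex
    grid (3 replicates per cell). Counts are Poisson around tissue means;
    the male-limited isoforms have zero counts in every female sample, and
    within each gene the full-length isoform's mean exceeds the truncated
    one's in every male tissue where the gene is expressed.
    """
    if genes is None:
        genes = build_fixture_genes(config)
    rng = np.random.default_rng([config.seed, 2])

    tx_ids = list(_FOCAL_MEANS) + [f"bg_{i + 1:02d}" for i in range(_N_BACKGROUND)]
    lengths = {tid: len(seq) for tid, seq in genes.transcripts.items()}
    bg_lengths = rng.integers(500, 3000, size=_N_BACKGROUND)
    bg_means = rng.uniform(5.0, 200.0, size=_N_BACKGROUND)
    for i in range(_N_BACKGROUND):
        lengths[f"bg_{i + 1:02d}"] = int(bg_lengths[i])

    samples, meta_rows = [], []
    for sex in ("M", "F"):
        for tissue in _TISSUES:
            for rep in range(1, _REPS + 1):
                sid = f"{sex}_{tissue}_{rep}"
                samples.append(sid)
                meta_rows.append({"sample_id": sid, "sex": sex, "tissue": tissue, "group": "survey"})

    counts = np.zeros((len(tx_ids), len(samples)), dtype=np.int64)
    for j, row in enumerate(meta_rows):
        sex, tissue = row["sex"], row["tissue"]
        for i, tid in enumerate(tx_ids):
            if tid.startswith("bg_"):
                mean = bg_means[int(tid[3:]) - 1]
            else:
                mean = _FOCAL_MEANS[tid][tissue]
                if sex == "F" and tid.startswith("amhy"):
                    mean = 0.0
            counts[i, j] = rng.poisson(mean) if mean > 0 else 0

    counts_df = pd.DataFrame(counts, index=tx_ids, columns=samples)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(
        counts=counts_df,
        lengths=pd.Series(lengths, name="length"),
        sample_meta=meta,
    )


def windowed_tracks(cohort: SyntheticCohort, window_size: Optional[int] = None):
    """Raw windowed DepthTracks straight from an in-memory cohort.

    Equivalent to dumping each sample's per-base TSV and running
    covscan.window_depth on it, but without touching disk.
    """
    from . import covscan as cov

    ws = window_size or cohort.config.window_size
    tracks = []
    for sample, per_scaffold in cohort.depth.items():
        rows = []
        for scaffold, d in per_scaffold:
            L = len(d)
            n_full = L // ws
            means = d[: n_full * ws].reshape(n_full, ws).mean(axis=1)
            starts = np.arange(n_full) * ws
            part = pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "start": starts,
                    "end": starts + ws,
                    "mean_depth": means,
                }
            )
            if L % ws:
                part = pd.concat(
                    [
                        part,
                        pd.DataFrame(
                            {
                                "scaffold": [scaffold],
                                "start": [n_full * ws],
                                "end": [L],
                                "mean_depth": [d[n_full * ws :].mean()],
                            }
                        ),
                    ],
                    ignore_index=True,
                )
            rows.append(part)
        windows = pd.concat(rows, ignore_index=True).sort_values(
            ["scaffold", "start"], kind="stable", ignore_index=True
        )
        tracks.append(
            cov.DepthTrack(
                sample_id=sample,
                sex=cohort.truth.sample_sexes[sample],
                windows=windows,
            )
        )
    return tracks


FEMALE_SIGNATURE = ("cyp19a1a", "foxl2", "figla")
MALE_SIGNATURE = ("dmrt1", "gsdf", "sox9")


def build_gonad_state_profiles(
    config: FixtureConfig,
) -> Tuple[pd.DataFrame, Dict[str, str], Tuple[Tuple[str, ...], Tuple[str, ...]]]:
    """Gonad expression profiles for signature-based state classification.

    Emulates an overexpression contrast: control ovaries (female
    programme), control testes (male programme), and ovaries driven to the
    male programme by the male-limited gene. Kept separate from the tissue
    survey because these profiles deliberately violate its female-absence
    invariant. Returns (TPM-scale table, truth labels, signature).
    """
    rng = np.random.default_rng([config.seed, 3])
    genes_f, genes_m = FEMALE_SIGNATURE, MALE_SIGNATURE
    group_means = {
        "ctrl_ovary": {"F": 400.0, "M": 4.0, "amhy": 0.0},
        "ctrl_testis": {"F": 4.0, "M": 400.0, "amhy": 300.0},
        "oe_ovary": {"F": 8.0, "M": 300.0, "amhy": 250.0},
    }
    labels = {"ctrl_ovary": "female_like", "ctrl_testis": "male_like", "oe_ovary": "male_like"}

    rows = list(genes_f) + list(genes_m) + ["amhy-full"]
    cols, truth = [], {}
    data = {}
    for group, means in group_means.items():
        for rep in range(1, 4):
            sid = f"{group}_{rep}"
            cols.append(sid)
            truth[sid] = labels[group]
            vals = []
            for g in genes_f:
                vals.append(rng.gamma(4.0, means["F"] / 4.0) if means["F"] > 0 else 0.0)
            for g in genes_m:
                vals.append(rng.gamma(4.0, means["M"] / 4.0) if means["M"] > 0 else 0.0)
            vals.append(rng.gamma(4.0, means["amhy"] / 4.0) if means["amhy"] > 0 else 0.0)
            data[sid] = vals
    tpm = pd.DataFrame(data, index=rows)
    return tpm, truth, (genes_f, genes_m)
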