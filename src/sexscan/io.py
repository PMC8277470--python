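"""Readers and writers for the standard interchange formats.

FASTA goes through Biopython; GFF3 reading goes through gffutils (in-memory
db). Coordinates convert between the internal 0-based half-open convention
and GFF3's 1-based inclusive one at this boundary only.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneStructure, Interval, TruthTable, ValidationError


def write_fasta(path: str, records: Sequence[Tuple[str, str]], width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(path: str, structures: Sequence[GeneStructure]) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in structures:
        g0 = g.gene_span[0]
        gs, ge = g.gene_span
        lines.append(
            "\t".join(
                [g.scaffold, "sexscan", "gene", str(gs + 1), str(ge), ".", g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        mrna_id = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [g.scaffold, "sexscan", "mRNA", str(gs + 1), str(ge), ".", g.strand, ".",
                 f"ID={mrna_id};Parent={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exon_spans, start=1):
            lines.append(
                "\t".join(
                    [g.scaffold, "sexscan", "exon", str(g0 + s + 1), str(g0 + e), ".", g.strand, ".",
                     f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
                )
            )
        cs, ce = g.cds_span
        for s, e in g.exon_spans:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                lines.append(
                    "\t".join(
                        [g.scaffold, "sexscan", "CDS", str(g0 + lo + 1), str(g0 + hi), ".", g.strand, "0",
                         f"ID={mrna_id}.cds;Parent={mrna_id}"]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gene_structures(
    gff3_path: str,
    domain_spans: Dict[str, Sequence[Tuple[str, Interval]]] | None = None,
) -> Dict[str, GeneStructure]:
    """Parse gene models back into GeneStructure objects.

    Domain spans are not representable in GFF3 and are supplied separately
    (gene_id -> list of (label, 1-based inclusive residue interval)).
    """
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: Dict[str, GeneStructure] = {}
    for gene in db.features_of_type("gene"):
        g0 = gene.start - 1
        exons: List[Interval] = []
        cds: List[Interval] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1 - g0, ex.end - g0))
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                cds.append((c.start - 1 - g0, c.end - g0))
            break  # one transcript per gene in this pipeline
        if not cds:
            raise ValidationError(f"gene {gene.id} has no CDS features")
        out[gene.id] = GeneStructure(
            gene_id=gene.id,
            scaffold=gene.seqid,
            gene_span=(g0, gene.end),
            strand=gene.strand,
            exon_spans=tuple(sorted(exons)),
            cds_span=(min(s for s, _ in cds), max(e for _, e in cds)),
            domain_spans=tuple((domain_spans or {}).get(gene.id, ())),
        )
    return out


def write_depth_tsv(path: str, scaffold_depths: Sequence[Tuple[str, Sequence[int]]]) -> None:
    """Per-base depth dump: scaffold, 1-based position, depth — all positions."""
    with open(path, "w") as fh:
        for scaffold, depths in scaffold_depths:
            fh.writelines(
                f"{scaffold}\t{i + 1}\t{d}\n" for i, d in enumerate(depths)
            )


def write_sample_sheet(path: str, sexes: Dict[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(sexes), "sex": list(sexes.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "sex"} <= set(df.columns):
        raise ValidationError("sample sheet needs sample_id and sex columns")
    return dict(zip(df["sample_id"], df["sex"]))


def write_truth_table(path: str, truth: TruthTable) -> None:
    scaffold, (s, e) = truth.true_region
    lines = [
        f"true_region={scaffold}:{s}-{e}",
        f"amha_id={truth.amha_id}",
        f"amhy_id={truth.amhy_id}",
    ]
    for intron, length in truth.true_insertions:
        lines.append(f"true_insertion=intron{intron}:{length}")
    for sid in sorted(truth.sample_sexes):
        lines.append(f"sample_sex.{sid}={truth.sample_sexes[sid]}")
    for tid in sorted(truth.transcript_variants):
        lines.append(f"transcript_variant.{tid}={truth.transcript_variants[tid]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_table(path: str) -> TruthTable:
    sexes: Dict[str, str] = {}
    variants: Dict[str, str] = {}
    insertions: List[Tuple[int, int]] = []
    region = None
    amha_id = amhy_id = ""
    with open(path) as fh:
        for line in fh:
            key, _, value = line.strip().partition("=")
            if key == "true_region":
                scaffold, _, span = value.partition(":")
                s, _, e = span.partition("-")
                region = (scaffold, (int(s), int(e)))
            elif key == "amha_id":
                amha_id = value
            elif key == "amhy_id":
                amhy_id = value
            elif key == "true_insertion":
                intron, _, length = value.partition(":")
                insertions.append((int(intron.removeprefix("intron")), int(length)))
            elif key.startswith("sample_sex."):
                sexes[key.removeprefix("sample_sex.")] = value
            elif key.startswith("transcript_variant."):
                variants[key.removeprefix("transcript_variant.")] = value
    if region is None:
        raise ValidationError(f"no true_region in {path}")
    return TruthTable(
        true_region=region,
        sample_sexes=sexes,
        amha_id=amha_id,
        amhy_id=amhy_id,
        true_insertions=insertions,
        transcript_variants=variants,
    )


def write_domains_tsv(path: str, domains: Sequence[Tuple[str, Interval]]) -> None:
    pd.DataFrame(
        [{"label": label, "start": s, "end": e} for label, (s, e) in domains]
    ).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path: str) -> List[Tuple[str, Interval]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.label), (int(r.start), int(r.end))) for r in df.itertuples()]
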