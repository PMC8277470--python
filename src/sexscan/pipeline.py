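"""End-to-end orchestration: simulate -> covscan -> dupfinger -> marker -> expr.

Each stage is a pure function of (inputs, parameters, seed); the report
collates the headline numbers. Logging goes to stderr with stage timers;
report files carry no timestamps so same-seed runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import covscan as cov
from . import dupfinger as dup
from . import expression as expr
from . import io as sio
from . import marker as mk
from . import synth
from .models import FixtureConfig, ValidationError

log = logging.getLogger("sexscan")


@dataclass
class RunConfig:
    """Whole-pipeline configuration (versioned YAML schema)."""

    outdir: str
    seed: int = 42
    schema_version: int = 1
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    tau_absent: float = 0.0
    min_present: Optional[float] = None
    max_gap: int = 1
    min_windows: int = 3
    max_product: int = 3000
    gel_resolution: float = 50.0
    detect_threshold: float = 0.1
    min_fraction_present: float = 0.8

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors: List[str] = []
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                errors.append(f"unknown config key {key!r}")
        if "outdir" not in raw:
            errors.append("missing required key 'outdir'")
        fixture_raw = dict(raw.get("fixture") or {})
        fixture_raw.setdefault("seed", raw.get("seed", 42))
        fx_fields = {f.name for f in dataclasses.fields(FixtureConfig)}
        for key in fixture_raw:
            if key not in fx_fields:
                errors.append(f"unknown fixture key {key!r}")
        fixture = None
        if not errors:
            try:
                for k in ("insertion_lengths", "per_exon_divergence"):
                    if k in fixture_raw:
                        fixture_raw[k] = tuple(fixture_raw[k])
                if "truncating_insertion" in fixture_raw:
                    fixture_raw["truncating_insertion"] = tuple(fixture_raw["truncating_insertion"])
                fixture = FixtureConfig(**fixture_raw)
            except ValidationError as exc:
                errors.append(str(exc))
        if errors:
            raise ValidationError("; ".join(errors))
        kwargs = {k: v for k, v in raw.items() if k in known and k != "fixture"}
        return cls(fixture=fixture, **kwargs)


@dataclass
class PipelineReport:
    regions: List[cov.SexSpecificRegion]
    exon_identity: pd.DataFrame
    insertions: List[dup.InsertionCall]
    protein_identity: pd.DataFrame
    variant_report: dup.TranscriptVariantReport
    sex_calls: pd.DataFrame
    confusion: pd.DataFrame
    expression_calls: List[expr.SexSpecificityCall]
    marker_design: object


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _T()


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute all stages in dependency order; raises on the first failure
    with a stage-named error."""
    os.makedirs(config.outdir, exist_ok=True)
    sim_dir = os.path.join(config.outdir, "sim")
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)

    try:
        with _timed("simulate"):
            genes = synth.build_fixture_genes(config.fixture)
            cohort = synth.build_cohort(config.fixture, genes, outdir=sim_dir)
            counts = synth.build_expression_fixture(config.fixture, genes)
    except Exception as exc:
        raise ValidationError(f"stage simulate failed: {exc}") from exc

    try:
        with _timed("covscan"):
            sheet = sio.read_sample_sheet(os.path.join(sim_dir, "samples.tsv"))
            raw_tracks = []
            for sample, sex in sheet.items():
                path = os.path.join(sim_dir, "depth", f"{sample}.depth.tsv")
                raw_tracks.append(
                    cov.window_depth(path, config.fixture.window_size, sample_id=sample, sex=sex)
                )
            norm_tracks = [cov.normalize_depth(t) for t in raw_tracks]
            comparisons = cov.compare_sexes(norm_tracks, raw_tracks)
            regions = cov.call_sex_specific(
                comparisons,
                tau_absent=config.tau_absent,
                min_present=config.min_present,
                max_gap=config.max_gap,
                min_windows=config.min_windows,
            )
    except Exception as exc:
        raise ValidationError(f"stage covscan failed: {exc}") from exc

    try:
        with _timed("dupfinger"):
            fasta = sio.read_fasta(os.path.join(sim_dir, "genes.fa"))
            domains = sio.read_domains_tsv(os.path.join(sim_dir, "domains.tsv"))
            amha, amhy = fasta["amha"], fasta["amhy"]
            galn = dup.align_pair(amha, amhy, mode="global")
            ins_calls = dup.localize_indels(galn, genes.amha_struct)
            exon_ident = dup.exonwise_identity(amha, amhy, genes.amha_struct, genes.amhy_struct)
            prot_a = dup.translate_cds(genes.amha_struct.spliced_cds(amha)).protein
            prot_b = dup.translate_cds(genes.amhy_struct.spliced_cds(amhy)).protein
            prot_ident = dup.domain_identity(prot_a, prot_b, domains)
            tx = sio.read_fasta(os.path.join(sim_dir, "transcripts.fa"))
            variant = dup.classify_transcript_variant(
                tx["amha-truncated"], tx["amha-full"], genes.amha_struct, domains,
                transcript_id="amha-truncated",
            )
    except Exception as exc:
        raise ValidationError(f"stage dupfinger failed: {exc}") from exc

    try:
        with _timed("marker"):
            pair = mk.PrimerPair(fw=config.fixture.primer_fw, rv=config.fixture.primer_rv)
            rows = []
            for sample, sex in cohort.truth.sample_sexes.items():
                templates = mk.genotype_templates(sex, ("amha", amha), ("amhy", amhy))
                amps = mk.insilico_pcr(templates, pair, max_product=config.max_product)
                pattern = mk.band_pattern(amps, resolution=config.gel_resolution, sample_id=sample)
                rows.append(
                    {
                        "sample_id": sample,
                        "true_sex": sex,
                        "n_bands": pattern.n_bands,
                        "band_sizes": ",".join(f"{b:.0f}" for b in pattern.band_sizes),
                        "called_sex": mk.call_sex(pattern),
                    }
                )
            sex_calls = pd.DataFrame(rows)
            confusion = pd.crosstab(sex_calls["true_sex"], sex_calls["called_sex"])
            ins_for_design = [
                c for c in ins_calls
                if c.feature[0] == "intron" and c.feature[1] == config.fixture.insertion_intron_index
            ]
            design = (
                mk.design_marker_primers(amha, amhy, max(ins_for_design, key=lambda c: c.length))
                if ins_for_design
                else mk.NoDesign(reason="no intron insertion call to span")
            )
    except Exception as exc:
        raise ValidationError(f"stage marker failed: {exc}") from exc

    try:
        with _timed("expression"):
            tpm = expr.compute_tpm(counts)
            calls = expr.call_sex_specific_expression(
                tpm,
                counts.sample_meta,
                detect_threshold=config.detect_threshold,
                min_fraction_present=config.min_fraction_present,
            )
    except Exception as exc:
        raise ValidationError(f"stage expression failed: {exc}") from exc

    with _timed("report"):
        cov.regions_to_bed(regions).to_csv(
            os.path.join(res_dir, "regions.bed"), sep="\t", index=False, header=False
        )
        pd.DataFrame(
            [
                {
                    "scaffold": r.scaffold,
                    "start_1based": r.start + 1,
                    "end": r.end,
                    "length": r.length,
                    "n_windows": r.n_windows,
                    "mean_norm_M": round(r.mean_norm_M, 4),
                    "mean_norm_F": round(r.mean_norm_F, 4),
                    "specificity": r.specificity,
                }
                for r in regions
            ]
        ).to_csv(os.path.join(res_dir, "regions.tsv"), sep="\t", index=False)
        exon_ident.to_csv(os.path.join(res_dir, "exon_identity.tsv"), sep="\t", index=False)
        prot_ident.to_csv(os.path.join(res_dir, "protein_identity.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "carrier": c.carrier,
                    "position": c.position_in_carrier,
                    "length": c.length,
                    "feature": f"{c.feature[0]}{c.feature[1]}",
                }
                for c in ins_calls
            ]
        ).to_csv(os.path.join(res_dir, "insertions.tsv"), sep="\t", index=False)
        sex_calls.to_csv(os.path.join(res_dir, "sex_calls.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "feature_id": c.feature_id,
                    "status": c.status,
                    "detect_fraction_M": c.detect_fraction_M,
                    "detect_fraction_F": c.detect_fraction_F,
                }
                for c in calls
            ]
        ).to_csv(os.path.join(res_dir, "expression_calls.tsv"), sep="\t", index=False)
        _write_summary(
            os.path.join(res_dir, "summary.txt"),
            config,
            regions,
            exon_ident,
            ins_calls,
            prot_ident,
            variant,
            confusion,
            calls,
            design,
        )

    return PipelineReport(
        regions=regions,
        exon_identity=exon_ident,
        insertions=ins_calls,
        protein_identity=prot_ident,
        variant_report=variant,
        sex_calls=sex_calls,
        confusion=confusion,
        expression_calls=calls,
        marker_design=design,
    )


def _write_summary(path, config, regions, exon_ident, ins_calls, prot_ident,
                   variant, confusion, calls, design) -> None:
    lines = ["# sexscan pipeline summary", ""]
    lines.append("## parameters")
    for k, v in sorted(dataclasses.asdict(config).items()):
        if k == "outdir":  # path, not a parameter of the analysis
            continue
        lines.append(f"  {k} = {v}")
    lines.append("")
    lines.append("## sex-specific regions")
    for r in regions:
        lines.append(
            f"  {r.scaffold}:{r.start + 1}-{r.end} length={r.length} "
            f"windows={r.n_windows} {r.specificity}"
        )
    lines.append("")
    lines.append("## paralog divergence")
    lines.append(
        f"  exon identity range: {exon_ident['identity_pct'].min():.1f}% - "
        f"{exon_ident['identity_pct'].max():.1f}%"
    )
    for _, row in prot_ident.iterrows():
        lines.append(f"  protein identity [{row['label']}]: {row['identity_pct']:.1f}%")
    for c in ins_calls:
        lines.append(
            f"  insertion: carrier {c.carrier}, {c.length} bp in {c.feature[0]} {c.feature[1]}"
        )
    lines.append("")
    lines.append("## transcript variant")
    lines.append(
        f"  {variant.transcript_id}: insertion={variant.insertion}, "
        f"frameshift={variant.frameshift}, premature_stop={variant.premature_stop}, "
        f"protein={variant.predicted_protein_length} aa, lost={variant.lost_domains}"
    )
    lines.append("")
    lines.append("## marker")
    if isinstance(design, mk.NoDesign):
        lines.append(f"  design: {design.reason}")
    else:
        top = design[0]
        lines.append(
            f"  top designed pair: fw={top.pair.fw} rv={top.pair.rv} "
            f"products {top.product_a}/{top.product_b} bp"
        )
    lines.append("  sex-call confusion matrix (rows=truth, cols=called):")
    for line in confusion.to_string().splitlines():
        lines.append(f"    {line}")
    lines.append("")
    lines.append("## expression")
    for c in calls:
        if not c.feature_id.startswith("bg_"):
            lines.append(f"  {c.feature_id}: {c.status}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
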