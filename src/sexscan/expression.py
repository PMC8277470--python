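"""TPM quantification and sex-specific expression calling.

TPM (transcripts per kilobase million) is the within-sample relative
abundance: counts are divided by transcript length in kb to give rates,
and rates are rescaled to sum to one million per sample. Sex specificity
is a detection contrast: a transcript is male-specific when it is reliably
detected in males of at least one tissue and never detected in any female
sample (and symmetrically for female-specific).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError


@dataclass
class CountMatrix:
    """Transcript x sample count table with lengths and sample metadata."""

    counts: pd.DataFrame  # rows: transcript_id, columns: sample_id
    lengths: pd.Series  # transcript_id -> length in bases
    sample_meta: pd.DataFrame  # index: sample_id; columns: sex, tissue, group

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        missing_len = self.counts.index.difference(self.lengths.index)
        if len(missing_len):
            raise ValidationError(f"transcripts without length: {list(missing_len)[:5]}")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise ValidationError("every transcript needs a positive length")
        missing_meta = self.counts.columns.difference(self.sample_meta.index)
        if len(missing_meta):
            raise ValidationError(f"samples without metadata: {list(missing_meta)[:5]}")


@dataclass(frozen=True)
class SexSpecificityCall:
    feature_id: str
    status: str  # male_specific / female_specific / shared / silent
    detect_fraction_M: float
    detect_fraction_F: float


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample TPM; every column of the result sums to 1e6.

    A sample with zero total counts yields an all-zero column (with a
    warning) rather than NaNs.
    """
    lengths_kb = counts.lengths.loc[counts.counts.index].to_numpy(dtype=float) / 1000.0
    rates = counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero total counts: {list(counts.counts.columns[zero_cols])}",
            stacklevel=2,
        )
        totals = np.where(zero_cols, 1.0, totals)
    tpm = 1e6 * rates / totals
    return pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns)


def call_sex_specific_expression(
    tpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    detect_threshold: float = 0.1,
    min_fraction_present: float = 0.8,
) -> List[SexSpecificityCall]:
    """Classify each transcript as male/female specific, shared or silent.

    Male-specific: detected (TPM >= detect_threshold) in at least
    ``min_fraction_present`` of male samples of some tissue AND in zero
    female samples; symmetric for female-specific.
    """
    meta = sample_meta.loc[tpm.columns]
    sexes = set(meta["sex"])
    if not {"M", "F"} <= sexes:
        raise ValidationError("both sexes must be represented")
    tissue = meta["tissue"] if "tissue" in meta.columns else pd.Series("all", index=meta.index)

    detected = tpm >= detect_threshold
    is_m = (meta["sex"] == "M").to_numpy()
    calls: List[SexSpecificityCall] = []
    for tx in tpm.index:
        det = detected.loc[tx].to_numpy()
        frac_m = float(det[is_m].mean())
        frac_f = float(det[~is_m].mean())
        per_tissue_m = []
        per_tissue_f = []
        for t in tissue.unique():
            in_t = (tissue == t).to_numpy()
            if (in_t & is_m).any():
                per_tissue_m.append(det[in_t & is_m].mean())
            if (in_t & ~is_m).any():
                per_tissue_f.append(det[in_t & ~is_m].mean())
        any_m, any_f = det[is_m].any(), det[~is_m].any()
        if not any_m and not any_f:
            status = "silent"
        elif max(per_tissue_m, default=0.0) >= min_fraction_present and not any_f:
            status = "male_specific"
        elif max(per_tissue_f, default=0.0) >= min_fraction_present and not any_m:
            status = "female_specific"
        else:
            status = "shared"
        calls.append(
            SexSpecificityCall(
                feature_id=str(tx),
                status=status,
                detect_fraction_M=frac_m,
                detect_fraction_F=frac_f,
            )
        )
    return calls


def dominant_transcript(
    tpm: pd.DataFrame,
    gene_map: Dict[str, str],
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per gene and sample, the transcript with the highest TPM.

    Genes need at least two transcripts; exact ties are reported as "tie".
    """
    cols = list(samples) if samples is not None else list(tpm.columns)
    rows = []
    genes: Dict[str, List[str]] = {}
    for tx, gene in gene_map.items():
        genes.setdefault(gene, []).append(tx)
    for gene, txs in sorted(genes.items()):
        if len(txs) < 2:
            raise ValidationError(f"gene {gene!r} has fewer than 2 transcripts")
        sub = tpm.loc[txs, cols]
        for sample in cols:
            vals = sub[sample]
            top = vals.max()
            winners = list(vals.index[vals == top])
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "dominant": winners[0] if len(winners) == 1 else "tie",
                }
            )
    return pd.DataFrame(rows)


def classify_gonad_state(
    tpm_sample: pd.Series,
    signature: Tuple[Sequence[str], Sequence[str]],
    dead_zone: float = 0.5,
) -> Tuple[float, str]:
    """Summarize a gonad expression profile as male-like or female-like.

    score = mean(log2(TPM+1) over male signature genes)
          - mean(log2(TPM+1) over female signature genes);
    |score| below ``dead_zone`` is called intermediate.
    """
    female_genes, male_genes = signature
    missing = [g for g in list(female_genes) + list(male_genes) if g not in tpm_sample.index]
    if missing:
        raise ValidationError(f"signature genes missing from table: {missing}")
    m = np.log2(tpm_sample.loc[list(male_genes)].to_numpy(dtype=float) + 1.0).mean()
    f = np.log2(tpm_sample.loc[list(female_genes)].to_numpy(dtype=float) + 1.0).mean()
    score = float(m - f)
    if score >= dead_zone:
        state = "male_like"
    elif score <= -dead_zone:
        state = "female_like"
    else:
        state = "intermediate"
    return score, state


def sex_group_test(tpm: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t-test of log2(TPM+1) between sexes, per transcript.

    Plain plumbing for exploratory contrasts; this is not a differential
    expression model.
    """
    meta = sample_meta.loc[tpm.columns]
    is_m = (meta["sex"] == "M").to_numpy()
    x = np.log2(tpm.to_numpy(dtype=float) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(x[:, is_m], x[:, ~is_m], axis=1, equal_var=False)
    return pd.DataFrame({"transcript_id": tpm.index, "t_stat": t, "p_value": p})
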