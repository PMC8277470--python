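#!/usr/bin/env python
"""Quantify and classify sex-specific expression.

Computes TPM from the transcript-count survey, calls sex-specific
transcripts, identifies the dominant isoform per gene in male gonads, and
classifies gonad expression profiles with a male/female signature score.
Finding: both male-limited isoforms are male-specific (never detected in
any female sample), the full-length isoform dominates in every male gonad
sample, and ovaries driven by the male-limited gene classify as male-like.
"""

import os
import sys

import pandas as pd

from sexscan import expression as ex
from sexscan import synth
from sexscan.models import FixtureConfig

SIM = "scratch/sim"
RESULTS = "results"


def main() -> int:
    counts = pd.read_csv(os.path.join(SIM, "counts.tsv"), sep="\t", index_col=0)
    lengths = pd.read_csv(os.path.join(SIM, "lengths.tsv"), sep="\t", index_col=0).iloc[:, 0]
    meta = pd.read_csv(os.path.join(SIM, "expr_samples.tsv"), sep="\t", index_col=0)
    cm = ex.CountMatrix(counts=counts, lengths=lengths, sample_meta=meta)

    tpm = ex.compute_tpm(cm)
    calls = ex.call_sex_specific_expression(tpm, meta)

    os.makedirs(RESULTS, exist_ok=True)
    pd.DataFrame(
        [
            {"feature_id": c.feature_id, "status": c.status,
             "detect_fraction_M": round(c.detect_fraction_M, 3),
             "detect_fraction_F": round(c.detect_fraction_F, 3)}
            for c in calls
        ]
    ).to_csv(os.path.join(RESULTS, "expression_calls.tsv"), sep="\t", index=False)

    for c in calls:
        if not c.feature_id.startswith("bg_"):
            print(
                f"{c.feature_id}: {c.status} "
                f"(detected M {c.detect_fraction_M:.2f}, F {c.detect_fraction_F:.2f})"
            )

    males = [s for s, r in meta.iterrows() if r["sex"] == "M" and r["tissue"] == "gonad"]
    gene_map = {
        "amha-full": "amha", "amha-truncated": "amha",
        "amhy-full": "amhy", "amhy-truncated": "amhy",
    }
    dom = ex.dominant_transcript(tpm, gene_map, samples=males)
    summary = dom.groupby("gene")["dominant"].agg(lambda s: s.value_counts().idxmax())
    for gene, winner in summary.items():
        print(f"dominant isoform in male gonads, {gene}: {winner}")

    profiles, labels, signature = synth.build_gonad_state_profiles(FixtureConfig())
    rows = []
    for sample in profiles.columns:
        score, state = ex.classify_gonad_state(profiles[sample], signature)
        rows.append({"sample": sample, "score": round(score, 3),
                     "state": state, "truth": labels[sample]})
    states = pd.DataFrame(rows)
    states.to_csv(os.path.join(RESULTS, "gonad_states.tsv"), sep="\t", index=False)
    n_ok = int((states["state"] == states["truth"]).sum())
    print(f"gonad-state classification: {n_ok}/{len(states)} profiles match their generating label")
    return 0


if __name__ == "__main__":
    sys.exit(main())
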