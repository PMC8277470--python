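#!/usr/bin/env python
"""Generate the default synthetic study: a 10M/10F sexed cohort carrying an
autosomal gene plus a male-limited, translocated duplicate with intron-4
insertions, plus the transcript-count survey.

Large raw files (genome, per-sample depth tracks) go to scratch/sim; the
downstream analyses read them back through the same file interfaces a real
study would use.
"""

import os
import sys

from sexscan import synth
from sexscan.models import FixtureConfig

OUTDIR = "scratch/sim"


def main() -> int:
    config = FixtureConfig()  # seed 42, the default study conditions
    genes = synth.build_fixture_genes(config)
    cohort = synth.build_cohort(config, genes, outdir=OUTDIR)
    counts = synth.build_expression_fixture(config, genes)
    counts.counts.rename_axis("transcript_id").to_csv(
        os.path.join(OUTDIR, "counts.tsv"), sep="\t"
    )
    counts.lengths.rename_axis("transcript_id").to_csv(
        os.path.join(OUTDIR, "lengths.tsv"), sep="\t"
    )
    counts.sample_meta.to_csv(os.path.join(OUTDIR, "expr_samples.tsv"), sep="\t")

    scaffold, (s, e) = cohort.truth.true_region
    print(f"cohort: {config.n_males}M/{config.n_females}F, depth {config.mean_depth}x")
    print(f"planted male-limited region: {scaffold}:{s}-{e} ({e - s} bp)")
    print(f"gene lengths: amha {len(genes.amha_seq)} bp, amhy {len(genes.amhy_seq)} bp")
    print(f"wrote raw study files under {OUTDIR}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
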