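# Methods

## Study model

The pipeline targets XX/XY systems where the master sex-determining gene
is a young male-limited duplication of an autosomal gene. Three signals
identify such a gene from cohort data:

1. a genomic interval covered by reads in every male but in no female
   (Y-limited sequence; hemizygous, so male depth is ~half autosomal);
2. a paralog pair with high but imperfect nucleotide identity and large
   male-copy-specific intron insertions (raw material for a length-based
   PCR assay);
3. transcripts of the duplicate detected exclusively in males.

All module defaults encode one default study design: a 10-male/10-female
resequencing cohort at 30x depth, 1000 bp analysis windows, a 5 kb
male-limited region, two intron-4 insertions of 131 and 166 bp, a
530-residue protein whose C-terminal 93 residues form the TGF-beta
domain, and a 5 bp "CAGAA" insertion truncating the minor transcript
isoform in the last exon.

## Coverage scan

Per-base depth (3-column TSV, as produced by `samtools depth`) is
aggregated into **tumbling** windows (step = size; a step parameter allows
overlap). Positions absent from the input count as depth 0; a trailing
partial window keeps its true span. Window values are normalized as
`log2(d + 1)`.

Seeding deliberately tests **raw** female depth (`max_raw_F <= tau_absent`,
default 0) rather than the normalized mean: the defining observation is
that no female read maps there at all, and a mean-based test would also
fire on regions that are merely depleted. The male presence floor defaults
to `log2(0.25 * cohort median raw depth + 1)`: half for hemizygosity, half
again as slack, so regions dead in both sexes (assembly gaps) are not
called. `max_gap = 1` tolerates one noisy window inside a region;
`min_windows = 3` suppresses isolated false seeds. Regions are emitted
in BED (0-based half-open) and as a 1-based table.

No mappability mask is applied; with real data, low-mappability windows
should be filtered before calling.

## Pairwise alignment

The affine-gap aligner is a three-state Gotoh dynamic programme (match,
vertical gap, horizontal gap), jit-compiled, with Smith-Waterman (local)
and Needleman-Wunsch (global, end gaps penalized) modes. A gap of length
L costs `gap_open + L * gap_extend`; DNA defaults (match 5, mismatch -4,
open 10, extend 0.5) and the protein default (BLOSUM62, 10/0.5) follow
the classic EMBOSS tools so identity values are comparable with numbers
produced by them. Traceback tie-breaking is fixed (diagonal, then up,
then left) so alignments are deterministic; ties still mean gap *placement*
within repeats is one of several optimal choices, which is why downstream
consumers (insertion calls, variant reports) are written to be
placement-tolerant.

**Percent identity** is identical columns over the full alignment length
including gap columns (the EMBOSS convention; stated explicitly because
"identity" is ambiguous). Per-exon identities use an independent local
alignment per exon pair (a sliced-global option exists); the printed
91.8-97.3% range in comparable studies is ambiguous between the two, and
local per-exon is the more faithful reading of a per-exon tool run.

**Insertion localization** turns maximal gap runs >= `min_indel_length`
(default 10 bp — separates structural insertions from alignment noise) in
a global alignment into calls assigned to the feature of the companion
gene at the projected position. Intron ordinals follow the convention
that intron *i* lies between exons *i* and *i+1* (1-based).

**Transcript variants** are aligned globally against the full-length
reference; insertions of any length (down to 1 bp) are mapped to exon
ordinals, CDS insertions with length not divisible by 3 set the
frameshift flag, and the mutant CDS is re-translated to locate the
premature stop. A domain is reported lost only when its span lies
entirely at or beyond the truncation point.

## PCR marker

Genotypes are template multisets — female `{amha}`, male `{amha, amhy}` —
because the assay reads band presence only; copy number and intensity are
ignored. Binding requires <= 2 total mismatches with the 3'-terminal
3 bases exact (typical PCR practice), products up to 3 kb. Both
convergent primer orientations are paired, making amplicon lengths
invariant under template reverse-complementation. Gel bands merge when
lengths differ by less than the resolution (default 50 bp at ~1.5%
agarose — an explicit, overridable assumption; resolvability is never
exactly quantified). Sex calling: 2 bands = male, 1 = female, anything
else = ambiguous (assay failure or off-target products).

Primer design enumerates candidate primers from flanking sequence that
occurs exactly once in *both* paralogs, scores them with the Wallace rule
(`2(A+T) + 4(G+C)`; deterministic and dependency-free — adequate for
ranking, not a thermodynamic model), rejects self-complementary 3'
tetramers, and ranks feasible pairs by Tm balance then product-size
centring. Failures return the constraint that rejected most candidates.

## Expression

TPM is used because it is a within-sample relative measure whose columns
sum to 1e6, making detection thresholds comparable across samples. The
detection threshold (TPM >= 0.1) operationalizes "detected / not
detected"; it is a stated choice, not an estimate. Sex specificity
requires reliable detection (>= 80% of samples of one sex in at least one
tissue) together with **zero** detections in the other sex — an absolute
criterion chosen to mirror the coverage scan's logic. Group significance
testing is out of scope; a Welch t-test helper is provided as plumbing
only and is not a differential-expression method.

The gonad-state score is the difference of mean `log2(TPM+1)` between a
male and a female signature gene set, with a +/-0.5 dead zone for
"intermediate". It is a summary heuristic for overexpression-style
contrasts, not a classifier fit to data.

## Synthetic data generator

The generator emulates the study design, not the sequencing process:

- **Depth is simulated directly** per base — Poisson(30) on autosomes,
  Poisson(15) for males over the male-limited region (one copy in a
  diploid), exactly 0 for females — rather than via read simulation and
  alignment. Consequences: no mappability structure, no GC bias, no
  multi-mapping noise. Passing tests therefore demonstrate the calling
  logic, not robustness to alignment artifacts.
- Depth files list **every** position including zeros (`samtools depth -a`
  convention) so all samples share one window grid.
- The planted region's boundaries fall on the window grid, so the
  window-resolution caller can recover its length exactly; with real
  data, called boundaries are accurate only to +/- one window.
- The seven-exon gene carries its 5' UTR (150 bp) and 3' UTR (200 bp) in
  the terminal exons; intron lengths are fixed (400/350/500/450/380/420 bp).
  The coding sequence is random non-stop codons between ATG and TAA.
- **Divergence** is applied per exon as an exact substitution count
  `round(rate * exon_length)` at uniformly drawn positions (start and
  stop codons excluded), so per-exon identity is deterministic given the
  architecture. Default rates (0.082, 0.050, 0.030, 0.045, 0.035, 0.050,
  0.027) put per-exon identities at ~91.9-97.3% and, with ~3/4 of random
  coding substitutions being nonsynonymous, full-protein identity near
  ~92%. Substitutions that would create an in-frame stop are resampled
  (budget 100 per site); introns are not diverged beyond the insertions,
  which keeps the two-gene length difference equal to the summed
  insertion lengths.
- **Primer sites** (defaults: the 23-mer/22-mer assay pair) are embedded
  identically in both paralogs inside the host intron, between the two
  insertion points and downstream of the last insertion, so both genes
  amplify and the product difference equals the last insertion's length.
  After generation the whole construct is verified by in-silico PCR
  (exactly one product per paralog); a spurious approximate binding site
  triggers a redraw (budget 10).
- The **truncating insertion** site is searched deterministically along
  the last exon's codon boundaries until inserting the 5-mer yields a
  premature stop upstream of the TGF-beta domain in *both* paralogs'
  transcripts (whether the real counterpart insertion sits in CDS or
  3' UTR is not determinable from sequence identity alone; placing it in
  CDS makes the truncation mechanistic).
- **Expression counts** are Poisson around per-tissue means (4 tissues x
  2 sexes x 3 replicates, 4 focal isoforms + 40 background transcripts);
  no overdispersion, so real RNA-seq variability is understated. The
  male-limited isoforms have structural zero counts in every female
  sample. Profiles for gonad-state classification are generated
  separately (gamma-noised TPM-scale values) because the overexpression
  design — phenotypic females expressing the male programme — would
  violate the survey's female-absence invariant.
- All randomness flows from one seed through fixed-order substreams;
  regeneration is byte-identical.

## Numerical and implementation choices

- DP matrices are float32 (scores are exact multiples of 0.5 well inside
  float32 range); scores are rounded to 1e-6 on output.
- Local alignments with no positive-scoring cell return an empty
  alignment rather than an error.
- Band clustering is greedy single-linkage on sorted lengths; band size
  is the cluster mean.
- TPM of an all-zero sample is all-zero with a warning (not NaN).
- Ties in per-gene dominant-isoform selection are reported as `tie`.
- Test-suite aligner verification: exhaustive path enumeration is
  exponential, so full enumeration runs on all two-letter-alphabet pairs
  up to length 4, with longer pairs checked against an independent
  memoized recursion and Biopython's C aligner.

## Problem sizes

Default analyses run on 2 scaffolds x 30 kb, 20 samples (1.2 M depth
values), ~4.4-4.7 kb gene pairs (one global alignment of ~21 M DP cells)
and a 44 x 24 count matrix. The 20-seed region-recovery property
regenerates the cohort in memory per seed. These sizes exercise every
code path at full realism of the design while keeping the whole suite in
tens of seconds.

## Known limitations

- Depth-only simulation cannot expose mapping-induced false positives
  (collapsed repeats, cross-mapping between paralogs) that real scans
  must contend with.
- The aligner is quadratic in sequence length; it is meant for gene-scale
  (kb) comparisons, not chromosome-scale alignment.
- Wallace Tm ignores salt and nearest-neighbour effects; designed primers
  should be re-checked with a thermodynamic tool before wet-lab use.
- The expression module classifies detection patterns; it is not a
  substitute for differential-expression inference.
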