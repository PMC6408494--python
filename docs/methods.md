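# Methods

## Read preprocessing

`quality_clip` applies, in order: removal of leading bases with Phred
quality < 3, removal of trailing bases with quality < 3, and a 5′→3′
sliding-window scan that truncates the read at the start of the first
4-base window whose mean quality falls below 15 (the Trimmomatic
LEADING/TRAILING/SLIDINGWINDOW convention). After the window cut we apply
one more trailing-quality pass: the cut can expose a terminal base that is
individually below the trailing threshold, and without removing it the
operation would not be idempotent. With it, `quality_clip` is a projection
(applying it twice equals applying it once), which makes pipeline re-entry
safe. Reads shorter than 18 nt after trimming are discarded; an 18-mer is
retained (the floor is "below 18 is discarded").

Adapter removal is a deliberate simplification: the leftmost position
where the read matches an adapter — either the full adapter anywhere, or a
read 3′-suffix matching an adapter prefix of ≥ 5 bases — with at most 1
mismatch is cut, together with everything downstream. This is a
suffix-overlap matcher, not a seed-and-extend scorer with palindrome mode;
it captures ordinary 3′ read-through, which is the only adapter structure
the simulator produces (and the dominant one in real small-RNA data).

## Two-pass weighted quantification

The annotation is the miRBase dialect of GFF3: `miRNA_primary_transcript`
(precursor) and `miRNA` (mature) features, the mature linked to its
precursor by `Derives_from` and required to lie within it on the same
chromosome and strand. Alignments arrive as SAM with multimappers encoded
as one primary plus secondary (0x100) records sharing a read name; the
reference span comes from the CIGAR, the strand from the reverse flag.
Reads reporting more than `position_cap` (default 100) positions are
dropped entirely, mirroring an aligner invoked with `-k 100 -m 101`, which
suppresses all output for reads with more than 100 hits.

Assignment is strand-aware interval overlap (≥ 1 shared bp; both
switchable via `--ignore-strand` and `--min-overlap`). Pass 1 enumerates
all (position, mature) pairs over a read's retained positions; only when
there are none does pass 2 enumerate (position, precursor) pairs. The k
resulting pairs each receive weight 1/k. Weights are distributed at the
(position, miRNA) **pair** level, so a miRNA overlapped at two retained
positions of the same read receives 2/k rather than being collapsed to one
candidate — the read's ambiguity between genomic copies is part of what
the weighting expresses. The alternative (collapsing per distinct miRNA)
changes only reads that hit the same miRNA at several positions and is not
implemented as a switch in v1.

Internally all coordinates are 0-based half-open; GFF3 and SAM are 1-based
inclusive and converted only at I/O boundaries.

`build_count_table` sums weights per (miRNA, sample); by default the
library size is the number of distinct assigned reads, and callers can
supply total mapped reads instead (the two differ by reads overlapping no
annotation — on real data we recommend passing mapped totals, and the
pipeline records which was used). CPM normalization multiplies each column
by 10⁶ / library size.

## Differential display filter

Size factors are the literal median-of-ratios: for sample j, the median
over features with all-positive counts of count_ij divided by the
feature's geometric mean across samples. (The exp-of-median-of-log-ratios
variant differs only when the middle two ratios are averaged for an even
feature count; the literal ratio median is what the brute-force oracle
checks.) baseMean is the grand mean of normalized counts over all samples;
log2FC = log2((mean_coculture + 0.5) / (mean_control + 0.5)), the
pseudocount guarding zero-count groups. The filter is
|log2FC| > log2 1.5 ≈ 0.585 AND baseMean > 5 — "fold change > 1.5" read on
the linear scale, the common convention. The filter is monotone in both
thresholds. No NB dispersion estimation, Wald/LRT testing, or LFC
shrinkage is performed: the package's claim is limited to the selection
surface (which miRNAs appear in a heatmap/MA plot), not to p-values.

## Ago-RIP targetome scoring

RPKM = count / (length/10³) / (mapped_total/10⁶) per condition. A
transcript is expressed if its RPKM reaches 1.0 in **at least one** of the
four conditions, with the boundary inclusive (1.0 passes). The enrichment
score is the double difference (Ago.mimic − IgG.mimic) − (Ago.control −
IgG.control) computed on log2(RPKM + 1): because the target rule is
phrased as a log2 fold change, we take the differences on the log scale,
which makes the score itself a log2 fold-change of IgG- and
control-corrected abundance. The pseudocount 1.0 keeps the transform
defined at RPKM 0 and bounded under rescaling. A `scale="linear"` mode
computes the same double difference on raw RPKM for sensitivity analysis.
Targets are expressed transcripts with score strictly > 0; a score of
exactly 0 is never a target. Genes failing the expressed filter are
retained in the output with `expressed=False` for auditability rather than
dropped.

The strict score > 0 rule, by construction, admits roughly half of all
null genes under noise (a null score is symmetric around 0); the score's
value is in ranking, which the tests measure as AUC of planted targets
versus nulls.

## qPCR and assay analytics

ΔΔCt assumes amplification efficiency exactly 2; relative expression is
2^(−ΔΔCt) with ΔΔCt = (Ct − Ct_ref)_treated − (Ct − Ct_ref)_control.
Spike-in correction multiplies a relative quantity by
2^(Ct_spike,sample − Ct_spike,reference): a spike-in recovered one cycle
later means half the material survived purification, so the quantity is
doubled. The standard curve is OLS of Ct on log10 copies (≥ 3 points
spanning ≥ 2 decades, slope must be negative); efficiency is
10^(−1/slope) − 1, and absolute copies invert the line exactly.

Half-life fitting defaults to log-linear OLS of ln(percent) on time:
"exponential regression" is ambiguous between log-linear and true
nonlinear least squares, and the log-linear form is closed-form, exactly
invertible on noiseless exponentials, and maximum-likelihood under the
multiplicative lognormal noise the generator produces. An `nls` mode
(Levenberg–Marquardt on the linear scale) is provided for sensitivity
checks. Non-decaying fits (k ≤ 0) are returned flagged with the half-life
undefined rather than raising.

Tumor volume is 0.5·L·W² (mm³); gap closure is (1 − A₂₄/A₀)·100 with
optional subtraction of the untreated control's closure so the control
maps to 0%.

## What the simulator emulates, and what it does not

`generate_reference` packs 90–120 bp precursors, each containing one or
two 18–24 nt mature arms placed 2–6 bp inside the hairpin ends, into a
random genome (default 2 × 20 kb), strands random. Multimapping is created
only by **exact sequence duplication**: for a configurable fraction of
mature features, the mature sequence is copied verbatim into the mature
region of a partner precursor (the partner's span resized to match). Both
loci are annotated, so a read from the shared sequence has exactly two
occurrences and an unambiguous truth of ½ + ½ — position-based assignment
needs exact truth more than it needs a mismatch model. Reads are exact
copies of mature sequences (or of a mature-free hairpin window, to
exercise pass 2), with every genomic occurrence enumerated by exhaustive
substring search on both strands; the SAM records are exactly that
occurrence set, and per-read truth weights apply the two-pass rule to it.

Count matrices are Gamma–Poisson (negative binomial, var = μ + αμ²) around
lognormal per-feature means scaled to the configured depth, with coculture
means multiplied by 2^planted_log2fc. RIP tables plant target enrichment
**on the log2(RPKM + pseudocount) scale** — the expected Ago.mimic RPKM is
set to 2^e·(base + 1) − 1 — so the noiseless score equals the planted e
exactly; planting on raw RPKM would let the pseudocount bend the noiseless
score away from the planted value. Decay series are 100·2^(−t/t½) with
mean-1 multiplicative lognormal noise of CV `noise_cv`, renormalized so
t = 0 reads exactly 100 (the convention of actinomycin-D time courses).

Not emulated: sequencing errors and quality-score structure, adapter
read-through and chimeras, isomiRs, near-identical (mismatched) paralogs,
ligation and GC bias, donor-to-donor biological variability beyond the NB
dispersion, and RIP library chemistry. Passing tests therefore demonstrate
correctness of the computational procedures under their stated model, not
robustness to artifacts real libraries contain.

## Parameters and study conditions

One RNG stream per artifact (reference, reads, counts, RIP, decay) is
derived from the master seed by stable sub-seeding, so generating one
output never perturbs another. Identical configs give byte-identical
outputs.

Key defaults: position cap 100; trim thresholds leading/trailing 3, window
4 × mean 15, min length 18; FC 1.5 and baseMean 5; RPKM threshold 1.0;
pseudocounts 0.5 (DE) and 1.0 (RIP); decay scenario t½ = 3.07 h with 5%
CV noise over 0–8 h, 5 timepoints. `nb_dispersion` defaults to 0.01, a
near-technical-replicate regime: the display filter carries no statistical
test, so planted-truth recovery (sensitivity with zero false positives,
and RIP ranking at +1.5 log2 with ≥ 30 expected reads per gene) is a
meaningful property only where count noise in log2FC stays well inside
the 0.585 threshold; at bulk biological dispersions (α ≈ 0.1) a
fold-change cutoff alone cannot separate planted from null features and no
implementation could make it do so. RIP base abundances are lognormal
(median ≈ 30 RPKM) floored at 7.5 RPKM, which with 500–5000 bp genes and
8–12 M mapped reads per condition keeps every gene at ≥ 30 expected reads.

Problem sizes used by the test suite and acceptance script — 100-instance
assigner oracle sweeps at ≤ 200 reads × ≤ 50 annotations, 5 000–20 000
reads per simulated sample, 100-feature × 6-sample DE matrices at 10⁵
reads/sample over 20 seeds, 100-gene RIP experiments over 100 seeds, and
200-replicate decay Monte-Carlo — were chosen so the full suite exercises
every recovery property at tight tolerances while remaining quick on one
CPU.

## Known limitations

* Adapter clipping is intentionally simpler than production trimmers; on
  real FASTQs with dimer/chimera structure use a dedicated trimmer first.
* The DE stage is a display filter; effect-size testing requires a count
  model this package deliberately does not re-implement.
* The RIP caller's strict score > 0 rule is as permissive as its source;
  consumers should rank by score or impose their own margin.
* Multimapping truth covers exact duplicates only; mismatch-tolerant
  multimapping would require a different assignment granularity and is out
  of scope for v1.
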