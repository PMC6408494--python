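# mirflux

Weighted miRNA quantification from multimapping small-RNA reads, with the
companion analytics used in tumor-associated-macrophage miRNA studies:
differential-miRNA filtering, Ago-RIP-Seq targetome scoring, and qPCR assay
computations (ΔΔCt, standard-curve absolute quantification, mRNA half-life
regression, simple morphometrics). Everything runs on synthetic data with
recorded ground truth, so each stage is testable end to end without any
external download.

## Who this is for

Groups profiling small RNAs in immune cells — for example macrophages
cocultured with breast-cancer cells, where a tumor-derived miRNA such as
miR-375 accumulates without de novo transcription — face three recurring
computational steps:

1. **Quantifying miRNAs when reads multimap.** Mature miRNAs are ~22 nt,
   often duplicated or near-duplicated in the genome, and always nested
   inside their precursor hairpin, so naive unique-read counting discards
   or double-counts a large fraction of the signal.
2. **Calling the targetome from an Ago-RIP experiment.** Transcripts bound
   by Argonaute after transfecting a miRNA mimic must be separated from
   nonspecific pulldown using a matched IgG control and a scrambled-mimic
   control.
3. **Quantitative assay arithmetic** — relative expression by ΔΔCt,
   absolute copies from a dilution standard curve, and mRNA half-life from
   actinomycin-D time courses.

## The core methods

**Two-pass weighted assignment.** Every retained mapping position of every
read (up to a cap of 100 positions per read, mirroring `bowtie -k 100
-m 101`) is intersected with the annotation, strand-aware, ≥1 bp overlap.
Pass 1 considers mature miRNAs only; if a read overlaps no mature miRNA at
any position, pass 2 considers precursor hairpins. If the read yields k
(position, miRNA) overlap pairs, each pair receives weight 1/k, so the
weight across all assignments of a read sums to 1 and each read contributes
exactly one count to the table. Depth normalization is counts per million.

**Differential display filter.** Counts are normalized by median-of-ratios
size factors (for sample j, the median over all-positive features i of
count_ij / geometric-mean_i). baseMean is the grand mean of normalized
counts; log2FC is the log-ratio of group means (pseudocount 0.5). A miRNA
is reported as differential when |FC| > 1.5 and baseMean > 5. No dispersion
estimation or hypothesis testing is performed — this is the display filter,
not a test.

**Ago-RIP double difference.** With x\* = log2(RPKM\* + 1) over the four
conditions of the 2×2 (mimic × antibody) design,

    score = (x_Ago.mimic − x_IgG.mimic) − (x_Ago.control − x_IgG.control)

Transcripts with RPKM ≥ 1 in at least one condition are "expressed"; a
target is an expressed transcript with score > 0 (strict).

**qPCR analytics.** Relative expression 2^(−ΔΔCt); spike-in recovery
correction by 2^(ΔCt_spike); standard curve Ct = slope·log10(copies) +
intercept with efficiency 10^(−1/slope) − 1; half-life t½ = ln2/k from
log-linear regression of percent-remaining on time; tumor volume
V = 0.5·L·W²; scratch gap closure (1 − A₂₄/A₀)·100, optionally
control-subtracted.

The synthetic-data module generates all inputs — a toy genome with nested
mature/precursor annotation and exact sequence duplications (true
multimappers with unambiguous fractional truth), exact-copy reads with
full-occurrence SAM records, negative-binomial count matrices with planted
fold changes, RIP tables with planted double-difference targets, and noisy
exponential decay series.

## Worked example

```
$ python analysis/01_simulate_inputs.py      # writes scratch/simulated/
$ python analysis/02_quantify_mirs.py
60 miRNAs quantified from 20000 assigned reads
max |built - truth| = 0 (4 features carry fractional multimapper counts)
1000 reads were assigned in pass 2 (precursor-only)

$ python analysis/03_differential_mirs.py
10/100 miRNAs pass |FC|>1.5 & baseMean>5
planted recovery: 10/10; false positives: none

$ python analysis/04_rip_targetome.py
112/200 genes called targets (expressed AND score > 0)
ranking AUC (planted vs null): 1.000

$ python analysis/05_qpcr_halflife.py
decay fit: t1/2 = 3.21 h (planted 3.07 h; R^2 = 0.9960)
standard curve: slope -3.3219 cycles/log10, efficiency 1.000
```

The quantifier reproduces the simulator's weighted truth exactly, including
fractional counts for duplicated mature sequences; the planted threefold
miRNAs are recovered by the display filter with no false positives; planted
RIP targets rank perfectly above nulls (the strict score > 0 call, by
design, also admits about half of the null genes — ranking, not calling, is
where the information is); and the fitted half-life recovers the planted
3.07 h within the 5% multiplicative noise of the series.

The same stages are available as a CLI (`mirflux simulate|trim|quantify|
de|rip-score|qpcr|run`); `mirflux run --config cfg.yaml --outdir out` runs
everything from one strictly-validated YAML config and writes a manifest
with SHA-256 digests of every output, byte-identical across runs with the
same seed.

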