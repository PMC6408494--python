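"""Synthetic-data generation with recorded ground truth.

Emulates the structures the downstream stages consume, at toy-genome scale:

* a random genome with miRBase-style precursor/mature annotation, where a
  configurable fraction of mature sequences is duplicated verbatim into the
  mature region of a partner precursor — the duplicated sequence then truly
  occurs at two annotated loci, creating multimapping reads with an
  unambiguous fractional assignment truth;
* small-RNA reads copied exactly from mature (and optionally precursor-only)
  subsequences, with SAM records enumerating every genomic occurrence;
* negative-binomial miRNA count matrices for a control vs coculture design
  with planted log2 fold changes;
* four-condition Ago-RIP experiments with targets planted as an exact
  double-difference on the log2(RPKM + pseudocount) scale;
* exponential mRNA-decay time courses with multiplicative lognormal noise.

Every output is a pure function of the configuration; one RNG stream per
artifact is derived from the master seed, so adding an output never perturbs
the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import KIND_MATURE, KIND_PRECURSOR, MirAnnotation, write_annotation
from .qpcr import DecaySeries
from .quant import CountTable
from .rip import CONDITIONS, DEFAULT_PSEUDOCOUNT, RipExperiment
from .trim import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# named RNG streams, one per artifact
_STREAMS = {"reference": 0, "reads": 1, "counts": 2, "rip": 3, "decay": 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all synthetic inputs."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 20_000
    n_precursors: int = 20
    mature_per_precursor: int = 1  # 1 or 2
    frac_multimapping: float = 0.2
    frac_precursor_reads: float = 0.05
    reads_per_sample: int = 20_000
    n_features: int = 100  # count-matrix features
    n_samples_per_group: int = 4
    nb_dispersion: float = 0.01
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)
    n_genes: int = 200  # RIP genes
    planted_rip_targets: Mapping[str, float] = field(default_factory=dict)
    rip_pseudocount: float = DEFAULT_PSEUDOCOUNT
    decay_halflife_h: float = 3.07
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_precursors",
                     "reads_per_sample", "n_features", "n_samples_per_group",
                     "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mature_per_precursor not in (1, 2):
            raise ValueError("mature_per_precursor must be 1 or 2")
        for name in ("frac_multimapping", "frac_precursor_reads", "noise_cv"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.decay_halflife_h <= 0:
            raise ValueError("decay_halflife_h must be positive")


@dataclass
class GroundTruth:
    """Recorded truth for downstream recovery checks."""

    true_weighted_counts: pd.DataFrame | None = None  # feature x sample
    true_de_set: set[str] = field(default_factory=set)
    true_target_set: set[str] = field(default_factory=set)
    true_halflife_h: float | None = None
    # per read: {(mir_id, position_index): weight} under the two-pass rule
    read_assignments: dict[str, dict[tuple[str, int], float]] | None = None


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    seq = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(seq)


# -- reference genome + annotation -------------------------------------------

def generate_reference(config: SimConfig) -> tuple[dict[str, str], list[MirAnnotation]]:
    """Random genome plus miRBase-style precursor/mature annotation.

    Precursors (90-120 bp) each contain 1-2 mature arms (18-24 nt) placed a
    few bases inside the hairpin ends, on a randomly assigned strand. For a
    ``frac_multimapping`` fraction of mature features, the mature sequence is
    copied verbatim into a partner precursor's mature region (adjusting the
    partner's mature span to the source length), so the sequence occurs at
    exactly two annotated loci.

    Raises ValueError when the requested precursors cannot be packed into the
    genome with non-pathological spacing.
    """
    rng = _rng(config, "reference")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = [config.n_precursors // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_precursors % config.n_chromosomes):
        per_chrom[i] += 1
    slot_min = 200  # precursor <=120 bp plus spacing
    for k in per_chrom:
        if k and config.chrom_length // k < slot_min:
            raise ValueError(
                f"infeasible packing: {k} precursors need "
                f">= {k * slot_min} bp, chromosome has {config.chrom_length}"
            )

    genome = {
        c: rng.choice(list("ACGT"), size=config.chrom_length)
        for c in chroms
    }
    annotations: list[MirAnnotation] = []
    matures: list[MirAnnotation] = []
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = config.chrom_length // k
        for j in range(k):
            idx += 1
            plen = int(rng.integers(90, 121))
            start0 = slot * j + int(rng.integers(0, slot - plen))  # 0-based
            strand = "+" if rng.random() < 0.5 else "-"
            pre_id = f"pre{idx:03d}"
            annotations.append(MirAnnotation(
                id=pre_id, name=f"hsa-mir-{idx}", kind=KIND_PRECURSOR,
                chrom=chrom, start=start0 + 1, end=start0 + plen, strand=strand,
            ))
            arms = ["5p"] if config.mature_per_precursor == 1 else ["5p", "3p"]
            for arm in arms:
                mlen = int(rng.integers(18, 25))
                off = int(rng.integers(2, 7))
                if arm == "5p":
                    m_start0 = start0 + off
                else:
                    m_start0 = start0 + plen - off - mlen
                mat = MirAnnotation(
                    id=f"mat{idx:03d}{arm}", name=f"hsa-miR-{idx}-{arm}",
                    kind=KIND_MATURE, chrom=chrom, start=m_start0 + 1,
                    end=m_start0 + mlen, strand=strand, derives_from=pre_id,
                )
                annotations.append(mat)
                matures.append(mat)

    # plant exact duplicates: source mature sequence copied into partner's arm
    n_dup = int(round(config.frac_multimapping * len(matures)))
    n_dup = min(n_dup, len(matures) // 2)
    if n_dup:
        order = rng.permutation(len(matures))
        for p in range(n_dup):
            src = matures[order[2 * p]]
            dst = matures[order[2 * p + 1]]
            src_seq = _annotated_seq(genome, src)
            # resize dst's span to the source length, anchored away from the
            # hairpin end so the arm stays inside its precursor
            if dst.id.endswith("3p"):
                new_start, new_end = dst.end - len(src_seq) + 1, dst.end
            else:
                new_start, new_end = dst.start, dst.start + len(src_seq) - 1
            dup = MirAnnotation(
                id=dst.id, name=dst.name, kind=KIND_MATURE, chrom=dst.chrom,
                start=new_start, end=new_end, strand=dst.strand,
                derives_from=dst.derives_from,
            )
            planted = src_seq if dup.strand == "+" else revcomp(src_seq)
            genome[dup.chrom][dup.start - 1: dup.end] = list(planted)
            annotations[annotations.index(dst)] = dup
            matures[matures.index(dst)] = dup

    genome_str = {c: "".join(s) for c, s in genome.items()}
    return genome_str, annotations


def _annotated_seq(genome: Mapping[str, Sequence[str] | str], a: MirAnnotation) -> str:
    raw = genome[a.chrom][a.start - 1: a.end]
    seq = raw if isinstance(raw, str) else "".join(raw)
    return seq if a.strand == "+" else revcomp(seq)


def find_occurrences(genome: Mapping[str, str], seq: str) -> list[tuple[str, int, int, str]]:
    """All genomic occurrences of ``seq`` on either strand.

    Returns (chrom, start, end, strand) with 1-based inclusive coordinates,
    sorted by (chrom, start, strand). Exhaustive substring search; the
    independent truth for where a read can map.
    """
    hits = []
    rc = revcomp(seq)
    for chrom in sorted(genome):
        text = genome[chrom]
        for query, strand in ((seq, "+"), (rc, "-")):
            at = text.find(query)
            while at != -1:
                hits.append((chrom, at + 1, at + len(query), strand))
                at = text.find(query, at + 1)
    # a palindromic sequence matches both strands at one locus; keep both
    return sorted(set(hits))


# -- read simulation ---------------------------------------------------------

@dataclass(frozen=True)
class SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 1-based leftmost
    seq: str


def _truth_assignments(
    occurrences: Sequence[tuple[str, int, int, str]],
    annotations: Sequence[MirAnnotation],
) -> dict[tuple[str, int], float]:
    """Two-pass weighted assignment truth by brute-force overlap."""
    for kind in (KIND_MATURE, KIND_PRECURSOR):
        pairs = [
            (a.id, i)
            for i, (chrom, start, end, strand) in enumerate(occurrences)
            for a in annotations
            if a.kind == kind and a.chrom == chrom and a.strand == strand
            and min(a.end, end) - max(a.start, start) + 1 >= 1
        ]
        if pairs:
            w = 1.0 / len(pairs)
            return {(mir, i): w for mir, i in pairs}
    return {}


def simulate_reads(
    config: SimConfig,
    genome: Mapping[str, str],
    annotations: Sequence[MirAnnotation],
    abundance: Mapping[str, float],
    sample: str = "sample",
) -> tuple[list[Read], list[SamRecord], GroundTruth]:
    """Exact-copy reads from annotated features, with full occurrence SAM.

    ``abundance`` maps feature ids (mature or precursor) to expected read
    counts; counts are materialized deterministically by rounding. Mature
    reads are exact copies of the annotated mature sequence; precursor reads
    are drawn from a hairpin subsequence that avoids the mature arm(s), so
    they exercise the second assignment pass. Each read's SAM records list
    every genomic occurrence (first occurrence primary, rest secondary with
    flag 0x100), and the recorded truth applies the two-pass 1/k weighting
    rule to those occurrences.
    """
    by_id = {a.id: a for a in annotations}
    unknown = [f for f in abundance if f not in by_id]
    if unknown:
        raise ValueError(f"abundance references unknown feature(s): {sorted(unknown)}")

    reads: list[Read] = []
    sam: list[SamRecord] = []
    read_truth: dict[str, dict[tuple[str, int], float]] = {}
    counts_acc: dict[str, float] = {}
    occ_cache: dict[str, list[tuple[str, int, int, str]]] = {}

    serial = 0
    for feature_id in sorted(abundance):
        n = int(round(abundance[feature_id]))
        if n <= 0:
            continue
        feat = by_id[feature_id]
        seq = _feature_read_seq(genome, feat, by_id)
        if seq not in occ_cache:
            occ_cache[seq] = find_occurrences(genome, seq)
        occurrences = occ_cache[seq]
        truth = _truth_assignments(occurrences, annotations)
        for _ in range(n):
            serial += 1
            rid = f"{sample}.r{serial:06d}.{feature_id}"
            reads.append(Read(id=rid, bases=seq, quals=(40,) * len(seq)))
            for i, (chrom, start, _end, strand) in enumerate(occurrences):
                flag = (0x10 if strand == "-" else 0) | (0x100 if i > 0 else 0)
                record_seq = seq if strand == "+" else revcomp(seq)
                sam.append(SamRecord(qname=rid, flag=flag, chrom=chrom,
                                     pos=start, seq=record_seq))
            read_truth[rid] = dict(truth)
            for (mir, _i), w in truth.items():
                counts_acc[mir] = counts_acc.get(mir, 0.0) + w

    table = pd.DataFrame({sample: pd.Series(counts_acc, dtype=float)}).sort_index()
    truth_obj = GroundTruth(true_weighted_counts=table, read_assignments=read_truth)
    return reads, sam, truth_obj


def _feature_read_seq(genome: Mapping[str, str], feat: MirAnnotation,
                      by_id: Mapping[str, MirAnnotation]) -> str:
    if feat.kind == KIND_MATURE:
        return _annotated_seq(genome, feat)
    # precursor-only read: a hairpin window clear of the mature arm(s)
    arms = [a for a in by_id.values()
            if a.kind == KIND_MATURE and a.derives_from == feat.id]
    lo = max((a.end for a in arms if a.start - feat.start < feat.end - a.end),
             default=feat.start - 1) + 1
    hi = min((a.start for a in arms if a.start - feat.start >= feat.end - a.end),
             default=feat.end + 1) - 1
    if hi - lo + 1 < 18:
        raise ValueError(f"precursor {feat.id}: no mature-free window >= 18 bp")
    length = min(20, hi - lo + 1)
    window = MirAnnotation(id="_w", name="_w", kind=KIND_PRECURSOR,
                           chrom=feat.chrom, start=lo, end=lo + length - 1,
                           strand=feat.strand)
    return _annotated_seq(genome, window)


def default_mature_abundance(config: SimConfig,
                             annotations: Sequence[MirAnnotation]) -> dict[str, float]:
    """Lognormal expected read counts summing to ``reads_per_sample``.

    A ``frac_precursor_reads`` share of the depth is assigned to precursor-
    only reads, spread uniformly over precursors, to exercise pass 2.
    """
    rng = _rng(config, "reads")
    matures = sorted(a.id for a in annotations if a.kind == KIND_MATURE)
    precursors = sorted(a.id for a in annotations if a.kind == KIND_PRECURSOR)
    weights = np.exp(rng.normal(0.0, 1.0, size=len(matures)))
    mature_depth = config.reads_per_sample * (1.0 - config.frac_precursor_reads)
    abundance = {m: float(w) * mature_depth / weights.sum()
                 for m, w in zip(matures, weights)}
    pre_depth = config.reads_per_sample * config.frac_precursor_reads
    for p in precursors:
        abundance[p] = pre_depth / len(precursors)
    return abundance


# -- count matrix ------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_count_matrix(config: SimConfig) -> tuple[CountTable, GroundTruth]:
    """Negative-binomial miRNA counts for a control vs coculture design.

    Per-feature control means follow a lognormal abundance profile scaled to
    ``reads_per_sample``; coculture means are multiplied by 2^planted_log2fc.
    Features planted at |fold change| > 1.5 form the true differential set.
    """
    rng = _rng(config, "counts")
    features = [f"miR-{i + 1:03d}" for i in range(config.n_features)]
    unknown = [f for f in config.planted_log2fc if f not in features]
    if unknown:
        raise ValueError(f"planted_log2fc references unknown feature(s): {unknown}")
    weights = np.exp(rng.normal(0.0, 0.8, size=config.n_features))
    control_mean = weights / weights.sum() * config.reads_per_sample
    lfc = np.array([config.planted_log2fc.get(f, 0.0) for f in features])
    coculture_mean = control_mean * np.exp2(lfc)

    n = config.n_samples_per_group
    samples = [f"control_{i + 1}" for i in range(n)] + \
              [f"coculture_{i + 1}" for i in range(n)]
    columns = {}
    for i, s in enumerate(samples):
        mean = control_mean if i < n else coculture_mean
        columns[s] = _nb_draw(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(columns, index=features)
    table = CountTable(counts=counts, library_sizes=counts.sum(axis=0))
    true_de = {f for f, v in config.planted_log2fc.items()
               if abs(v) > math.log2(1.5)}
    return table, GroundTruth(true_weighted_counts=counts, true_de_set=true_de)


# -- RIP experiment ----------------------------------------------------------

def simulate_rip_experiment(
    config: SimConfig, noiseless: bool = False
) -> tuple[RipExperiment, GroundTruth]:
    """Four-condition RIP counts with planted double-difference targets.

    Non-target genes have identical expected RPKM in all four conditions
    (expected score 0). For a planted target with enrichment e (log2 units),
    the expected Ago.mimic RPKM is set to 2^e * (base + p) - p with p the
    scorer's pseudocount, so the noiseless score equals e exactly. Gene
    lengths and per-condition mapped totals vary; with ``noiseless=False``
    counts are negative-binomial around their expectations.
    """
    rng = _rng(config, "rip")
    genes = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    unknown = [g for g in config.planted_rip_targets if g not in genes]
    if unknown:
        raise ValueError(f"planted_rip_targets references unknown gene(s): {unknown}")
    lengths = pd.Series(rng.integers(500, 5001, size=config.n_genes).astype(float),
                        index=genes)
    mapped_totals = pd.Series(rng.uniform(8e6, 12e6, size=4), index=list(CONDITIONS))
    # base RPKM floored so every gene has >= ~30 expected reads per condition
    base_rpkm = np.maximum(np.exp(rng.normal(math.log(30.0), 0.7, size=config.n_genes)),
                           7.5)
    p = config.rip_pseudocount
    expected_rpkm = pd.DataFrame(
        {c: base_rpkm.copy() for c in CONDITIONS}, index=genes)
    for gene, enrich in config.planted_rip_targets.items():
        base = expected_rpkm.at[gene, "ago_mir375"]
        expected_rpkm.at[gene, "ago_mir375"] = 2.0**enrich * (base + p) - p
    expected_counts = expected_rpkm.mul(lengths / 1e3, axis=0).mul(
        mapped_totals / 1e6, axis=1)
    if noiseless:
        counts = expected_counts
    else:
        counts = expected_counts.copy()
        for c in CONDITIONS:
            counts[c] = _nb_draw(rng, expected_counts[c].values, config.nb_dispersion)
    experiment = RipExperiment(counts=counts[list(CONDITIONS)], lengths=lengths,
                               mapped_totals=mapped_totals)
    true_targets = {g for g, e in config.planted_rip_targets.items() if e > 0}
    return experiment, GroundTruth(true_target_set=true_targets)


# -- decay series ------------------------------------------------------------

def simulate_decay_series(config: SimConfig,
                          timepoints_h: Sequence[float]) -> DecaySeries:
    """Exponential decay time course, renormalized to 100% at t = 0.

    Values follow 100 * 2^(-t / halflife) perturbed by mean-1 multiplicative
    lognormal noise with coefficient of variation ``noise_cv``, then divided
    by the (noisy) t=0 value so the series starts at exactly 100.
    """
    if any(t < 0 for t in timepoints_h):
        raise ValueError("negative timepoint")
    if 0.0 not in timepoints_h:
        raise ValueError("timepoints must include 0")
    rng = _rng(config, "decay")
    t = np.asarray(timepoints_h, dtype=float)
    ideal = 100.0 * np.exp2(-t / config.decay_halflife_h)
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=t.size)
        values = ideal * noise
    else:
        values = ideal
    values = values / values[list(timepoints_h).index(0.0)] * 100.0
    return DecaySeries(timepoints_h=tuple(float(x) for x in t),
                       percent_remaining=tuple(float(v) for v in values))


def random_assignment_instance(
    seed: int,
    max_reads: int = 200,
    max_annotations: int = 50,
) -> tuple[list["ReadAlignmentSet"], list[MirAnnotation]]:
    """A random small assigner instance for oracle cross-checks.

    Draws random mature/precursor annotations and random per-read position
    sets over a toy coordinate space, with no constraint that positions hit
    any annotation, so all assigner branches (pass 1, pass 2, no overlap)
    occur.
    """
    from .quant import AlignedPosition, ReadAlignmentSet

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    chroms = ["chr1", "chr2"]
    span = 2_000
    annotations = []
    n_ann = int(rng.integers(1, max_annotations + 1))
    for i in range(n_ann):
        kind = KIND_MATURE if rng.random() < 0.6 else KIND_PRECURSOR
        length = int(rng.integers(18, 25)) if kind == KIND_MATURE \
            else int(rng.integers(60, 121))
        start = int(rng.integers(1, span - length))
        annotations.append(MirAnnotation(
            id=f"ann{i:03d}", name=f"ann{i:03d}", kind=kind,
            chrom=chroms[int(rng.integers(0, 2))], start=start,
            end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
        ))
    alignments = []
    n_reads = int(rng.integers(1, max_reads + 1))
    for r in range(n_reads):
        n_pos = int(rng.integers(1, 5))
        positions = set()
        while len(positions) < n_pos:
            length = int(rng.integers(18, 25))
            start = int(rng.integers(1, span - length))
            positions.add(AlignedPosition(
                chrom=chroms[int(rng.integers(0, 2))], start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            ))
        alignments.append(ReadAlignmentSet(
            read_id=f"read{r:04d}", positions=tuple(sorted(
                positions, key=lambda p: (p.chrom, p.start, p.strand)))))
    return alignments, annotations


# -- file output -------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom in genome:
            handle.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                handle.write(seq[i:i + 80] + "\n")


def write_sam(genome: Mapping[str, str], records: Iterable[SamRecord],
              path: str | Path) -> None:
    """Plain-text SAM with @SQ header lines; exact-match CIGAR."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in genome:
            handle.write(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}\n")
        for r in records:
            handle.write(
                f"{r.qname}\t{r.flag}\t{r.chrom}\t{r.pos}\t255\t{len(r.seq)}M"
                f"\t*\t0\t0\t{r.seq}\t{'I' * len(r.seq)}\n"
            )


def write_reference(genome: Mapping[str, str], annotations: Sequence[MirAnnotation],
                    outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    gff = outdir / "annotation.gff3"
    write_genome_fasta(genome, fasta)
    with open(gff, "w") as handle:
        write_annotation(annotations, handle)
    return fasta, gff
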