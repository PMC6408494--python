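"""Two-pass weighted miRNA quantification from multimapping alignments.

Every retained mapping position of every read is compared against the
mature/precursor miRNA annotation. Pass 1 considers mature features only;
only if a read overlaps no mature feature at any of its positions does
pass 2 consider precursor hairpins. A read overlapping k (position, miRNA)
pairs distributes unit weight 1/k over them, so each read contributes
exactly one count to the table regardless of how ambiguously it maps.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import KIND_MATURE, KIND_PRECURSOR, MirAnnotation

DEFAULT_POSITION_CAP = 100  # mirrors bowtie -k 100 -m 101


@dataclass(frozen=True)
class AlignedPosition:
    """One genomic mapping position, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ReadAlignmentSet:
    """All retained mapping positions of one read."""

    read_id: str
    positions: tuple[AlignedPosition, ...]
    n_reported: int = 0

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"read {self.read_id!r}: empty position set")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError(f"read {self.read_id!r}: duplicate positions")


@dataclass(frozen=True)
class Assignment:
    """A weighted read-to-miRNA assignment from pass 1 or pass 2."""

    read_id: str
    mir_id: str
    position_index: int
    weight: float
    pass_no: int  # 1 = mature, 2 = precursor


def load_alignments(
    sam_path: str,
    position_cap: int = DEFAULT_POSITION_CAP,
) -> Iterator[ReadAlignmentSet]:
    """Collect per-read mapping positions from a SAM/BAM file.

    Multimappers are expected as one primary plus secondary (0x100) records
    sharing a QNAME. Unmapped records are ignored. Reads reporting more than
    ``position_cap`` positions are discarded entirely, mirroring an aligner
    run with ``-k 100 -m 101``. The end coordinate comes from the CIGAR
    reference span and the strand from the reverse flag.
    """
    per_read: dict[str, list[AlignedPosition]] = defaultdict(list)
    order: list[str] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"record {rec.query_name!r}: missing/unparsable CIGAR")
            pos = AlignedPosition(
                chrom=rec.reference_name,
                start=rec.reference_start + 1,
                end=rec.reference_end,  # pysam reference_end is exclusive == 1-based inclusive end
                strand="-" if rec.is_reverse else "+",
            )
            if rec.query_name not in per_read:
                order.append(rec.query_name)
            if pos not in per_read[rec.query_name]:
                per_read[rec.query_name].append(pos)
    for read_id in order:
        positions = per_read[read_id]
        if len(positions) > position_cap:
            continue
        yield ReadAlignmentSet(read_id=read_id, positions=tuple(positions),
                               n_reported=len(positions))


class _AnnotationIndex:
    """Strand-aware interval index over mature and precursor features."""

    def __init__(self, annotations: Iterable[MirAnnotation], ignore_strand: bool = False):
        self.ignore_strand = ignore_strand
        self._trees: dict[tuple[str, str, str], IntervalTree] = defaultdict(IntervalTree)
        for a in annotations:
            strand = "." if ignore_strand else a.strand
            # store as 0-based half-open for interval arithmetic
            self._trees[(a.chrom, strand, a.kind)][a.start - 1: a.end] = a

    def overlapping(self, pos: AlignedPosition, kind: str, min_overlap: int = 1
                    ) -> list[MirAnnotation]:
        strand = "." if self.ignore_strand else pos.strand
        tree = self._trees.get((pos.chrom, strand, kind))
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(pos.start - 1, pos.end):
            overlap = min(iv.end, pos.end) - max(iv.begin, pos.start - 1)
            if overlap >= min_overlap:
                hits.append(iv.data)
        return sorted(hits, key=lambda a: a.id)


def assign_reads(
    alignments: Iterable[ReadAlignmentSet],
    annotations: Sequence[MirAnnotation],
    min_overlap: int = 1,
    ignore_strand: bool = False,
) -> Iterator[Assignment]:
    """Distribute unit weight per read over (position, miRNA) overlap pairs.

    Pass 1 enumerates all (position, mature) pairs over the read's retained
    positions; if and only if none exist, pass 2 enumerates (position,
    precursor) pairs. Each of the k resulting pairs receives weight 1/k.
    Reads with no overlap in either pass yield nothing. Overlap requires at
    least ``min_overlap`` shared bases on the same chromosome and (unless
    ``ignore_strand``) the same strand.
    """
    index = _AnnotationIndex(annotations, ignore_strand=ignore_strand)
    for aln in alignments:
        for pass_no, kind in ((1, KIND_MATURE), (2, KIND_PRECURSOR)):
            pairs = [
                (i, a)
                for i, pos in enumerate(aln.positions)
                for a in index.overlapping(pos, kind, min_overlap)
            ]
            if pairs:
                w = 1.0 / len(pairs)
                for i, a in pairs:
                    yield Assignment(read_id=aln.read_id, mir_id=a.id,
                                     position_index=i, weight=w, pass_no=pass_no)
                break


@dataclass
class CountTable:
    """Weighted feature x sample counts with per-sample library sizes."""

    counts: pd.DataFrame  # features x samples, non-negative reals
    library_sizes: pd.Series  # per-sample totals of assigned (or mapped) reads

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")


def build_count_table(
    assignments_per_sample: Mapping[str, Iterable[Assignment]],
    library_sizes: Mapping[str, float] | None = None,
) -> CountTable:
    """Aggregate assignment weights into a miRNA x sample count table.

    count(miR, sample) is the summed weight of that miRNA's assignments in
    that sample. Library sizes default to the number of distinct assigned
    reads per sample; pass ``library_sizes`` (e.g. total mapped reads) to
    override the normalization denominator.

    Raises on a duplicated (read, miR, position) assignment, which signals
    an upstream bug rather than a data property.
    """
    if len(set(assignments_per_sample)) != len(assignments_per_sample):
        raise ValueError("duplicate sample ids")
    columns: dict[str, dict[str, float]] = {}
    sizes: dict[str, float] = {}
    for sample, assignments in assignments_per_sample.items():
        acc: dict[str, float] = defaultdict(float)
        reads: set[str] = set()
        seen: set[tuple[str, str, int]] = set()
        for a in assignments:
            key = (a.read_id, a.mir_id, a.position_index)
            if key in seen:
                raise ValueError(f"sample {sample!r}: duplicate assignment {key}")
            seen.add(key)
            acc[a.mir_id] += a.weight
            reads.add(a.read_id)
        columns[sample] = dict(acc)
        sizes[sample] = float(len(reads))
    counts = pd.DataFrame(columns).fillna(0.0).sort_index()
    counts = counts[list(assignments_per_sample)]
    if library_sizes is not None:
        sizes = {s: float(library_sizes[s]) for s in counts.columns}
    return CountTable(counts=counts, library_sizes=pd.Series(sizes, dtype=float))


def depth_normalize(table: CountTable) -> CountTable:
    """Scale each sample to counts per million of its library size."""
    if (table.library_sizes <= 0).any():
        bad = table.library_sizes[table.library_sizes <= 0].index.tolist()
        raise ValueError(f"non-positive library size for sample(s) {bad}")
    cpm = table.counts * (1e6 / table.library_sizes)
    return CountTable(counts=cpm, library_sizes=table.library_sizes.copy())


# -- TSV I/O -----------------------------------------------------------------

def write_count_table(table: CountTable, handle: TextIO) -> None:
    """TSV with one ``#library_size=sample:value`` header line per sample."""
    for sample in table.counts.columns:
        handle.write(f"#library_size={sample}:{table.library_sizes[sample]:g}\n")
    table.counts.rename_axis("mir_id").to_csv(handle, sep="\t")


def read_count_table(handle: TextIO) -> CountTable:
    sizes: dict[str, float] = {}
    lines = []
    for line in handle:
        if line.startswith("#library_size="):
            sample, _, value = line.strip().removeprefix("#library_size=").partition(":")
            sizes[sample] = float(value)
        elif not line.startswith("#"):
            lines.append(line)
    from io import StringIO

    counts = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col="mir_id")
    if not sizes:
        sizes = counts.sum(axis=0).to_dict()
    return CountTable(counts=counts, library_sizes=pd.Series(sizes, dtype=float))
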