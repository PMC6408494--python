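"""Small-RNA read preprocessing: quality clipping, adapter removal, length filter.

The defaults reproduce a common Trimmomatic-style recipe for TruSeq small-RNA
libraries: clip leading/trailing bases below Q3, truncate at the first
4-base window whose mean quality drops below 15, remove 3' adapter
read-through, and discard reads shorter than 18 nt. Adapter removal here is
a simple suffix-overlap matcher, not a seed-and-extend scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, TextIO

# TruSeq small RNA 3' adapter, the usual read-through contaminant
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class Read:
    """A single read with per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimPolicy:
    """Thresholds for quality/adapter trimming.

    ``leading_q``/``trailing_q``: terminal bases strictly below these Phred
    values are clipped. ``window_len``/``window_meanq``: the read is truncated
    at the start of the first sliding window whose mean quality is strictly
    below ``window_meanq``. ``min_len``: shorter reads are discarded.
    """

    leading_q: int = 3
    trailing_q: int = 3
    window_len: int = 4
    window_meanq: float = 15.0
    min_len: int = 18
    adapters: tuple[str, ...] = (TRUSEQ_SMALL_RNA_ADAPTER,)
    adapter_min_overlap: int = 5
    adapter_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        for name in ("leading_q", "trailing_q", "window_meanq", "min_len",
                     "adapter_min_overlap", "adapter_max_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _truncate(read: Read, start: int, stop: int) -> Read:
    return replace(read, bases=read.bases[start:stop], quals=read.quals[start:stop])


def quality_clip(read: Read, policy: TrimPolicy = TrimPolicy()) -> Read:
    """Clip low-quality leading/trailing bases, then sliding-window truncate.

    The scan runs 5'->3' and cuts at the start of the first length-
    ``window_len`` window whose mean quality falls below ``window_meanq``.
    A final trailing-quality pass removes any low-quality base the window cut
    exposes at the new 3' end, which makes the operation idempotent.
    Returns a new read; the input is not modified.
    """
    lo, hi = 0, len(read)
    while lo < hi and read.quals[lo] < policy.leading_q:
        lo += 1
    while hi > lo and read.quals[hi - 1] < policy.trailing_q:
        hi -= 1
    quals = read.quals[lo:hi]
    n, w = len(quals), policy.window_len
    cut = n
    if n >= w:
        window_sum = sum(quals[:w])
        for i in range(n - w + 1):
            if i > 0:
                window_sum += quals[i + w - 1] - quals[i - 1]
            if window_sum / w < policy.window_meanq:
                cut = i
                break
    while cut > 0 and quals[cut - 1] < policy.trailing_q:
        cut -= 1
    return _truncate(read, lo, lo + cut)


def _adapter_match_at(bases: str, i: int, adapter: str, policy: TrimPolicy) -> bool:
    overlap = min(len(adapter), len(bases) - i)
    if overlap < min(len(adapter), policy.adapter_min_overlap):
        return False
    mismatches = sum(1 for k in range(overlap) if bases[i + k] != adapter[k])
    return mismatches <= policy.adapter_max_mismatch


def adapter_clip(read: Read, policy: TrimPolicy = TrimPolicy()) -> Read:
    """Remove the leftmost 3' adapter occurrence and everything downstream.

    An occurrence is either the full adapter anywhere in the read, or a read
    3'-suffix matching an adapter prefix of at least ``adapter_min_overlap``
    bases, allowing up to ``adapter_max_mismatch`` mismatches.
    """
    if not policy.adapters:
        return read
    for i in range(len(read.bases)):
        for adapter in policy.adapters:
            if _adapter_match_at(read.bases, i, adapter, policy):
                return _truncate(read, 0, i)
    return read


def length_filter(reads: Iterable[Read], policy: TrimPolicy = TrimPolicy()) -> Iterator[Read]:
    """Yield only reads of length >= ``min_len``, preserving order."""
    for read in reads:
        if len(read) >= policy.min_len:
            yield read


def trim_read(read: Read, policy: TrimPolicy = TrimPolicy()) -> Read:
    """Full per-read recipe: quality clip then adapter clip."""
    return adapter_clip(quality_clip(read, policy), policy)


def trim_reads(reads: Iterable[Read], policy: TrimPolicy = TrimPolicy()) -> Iterator[Read]:
    """Trim a stream of reads and drop those below the length floor."""
    return length_filter((trim_read(r, policy) for r in reads), policy)


# -- FASTQ I/O (Phred+33) ----------------------------------------------------

def read_fastq(handle: TextIO) -> Iterator[Read]:
    """Parse a Phred+33 FASTQ stream into Read records."""
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header line: {header!r}")
        bases = handle.readline().rstrip("\n")
        plus = handle.readline()
        qline = handle.readline().rstrip("\n")
        if not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ separator for read {header!r}")
        yield Read(id=header[1:].split()[0], bases=bases,
                   quals=tuple(ord(c) - 33 for c in qline))


def write_fastq(reads: Iterable[Read], handle: TextIO) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    for read in reads:
        handle.write(f"@{read.id}\n{read.bases}\n+\n")
        handle.write("".join(chr(q + 33) for q in read.quals) + "\n")
        n += 1
    return n
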