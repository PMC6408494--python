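"""miRBase-dialect GFF3 parsing into mature/precursor annotation records.

miRBase genome annotations use two feature types: ``miRNA_primary_transcript``
(the precursor hairpin) and ``miRNA`` (the mature form), linked by a
``Derives_from`` attribute. Coordinates are 1-based inclusive, as in GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

KIND_MATURE = "mature"
KIND_PRECURSOR = "precursor"

_FEATURE_KINDS = {
    "miRNA": KIND_MATURE,
    "miRNA_primary_transcript": KIND_PRECURSOR,
}


@dataclass(frozen=True)
class MirAnnotation:
    """One annotated miRNA feature (mature or precursor hairpin)."""

    id: str
    name: str
    kind: str  # "mature" | "precursor"
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" | "-"
    derives_from: str | None = None  # precursor id, mature features only

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")
        if self.kind not in (KIND_MATURE, KIND_PRECURSOR):
            raise ValueError(f"{self.id}: invalid kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def parse_annotation(source: str | TextIO) -> list[MirAnnotation]:
    """Parse a miRBase-style GFF3 file into MirAnnotation records.

    ``miRNA`` records become mature annotations, ``miRNA_primary_transcript``
    records precursors; other feature types are skipped with a warning.
    Derives_from links are checked: a mature feature naming a precursor must
    lie within that precursor's span on the same chromosome and strand.

    Raises ValueError naming the offending line on malformed coordinates or
    a broken Derives_from containment.
    """
    if isinstance(source, str):
        with open(source) as handle:
            return parse_annotation(handle)

    annotations: list[MirAnnotation] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feature = feature_from_line(line)
        except Exception as exc:  # noqa: BLE001 - rewrap with line context
            raise ValueError(f"GFF3 line {lineno}: unparsable record ({exc})") from exc
        kind = _FEATURE_KINDS.get(feature.featuretype)
        if kind is None:
            logger.warning("GFF3 line %d: skipping feature type %r",
                           lineno, feature.featuretype)
            continue
        if feature.start > feature.end:
            raise ValueError(
                f"GFF3 line {lineno}: start {feature.start} > end {feature.end}"
            )
        attrs = feature.attributes
        feat_id = (attrs.get("ID") or [f"feature_{lineno}"])[0]
        name = (attrs.get("Name") or [feat_id])[0]
        derives = (attrs.get("Derives_from") or [None])[0]
        annotations.append(
            MirAnnotation(
                id=feat_id,
                name=name,
                kind=kind,
                chrom=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand,
                derives_from=derives if kind == KIND_MATURE else None,
            )
        )

    _check_links(annotations)
    return annotations


def _check_links(annotations: Iterable[MirAnnotation]) -> None:
    precursors = {a.id: a for a in annotations if a.kind == KIND_PRECURSOR}
    for mature in annotations:
        if mature.kind != KIND_MATURE or mature.derives_from is None:
            continue
        parent = precursors.get(mature.derives_from)
        if parent is None:
            logger.warning("mature %s Derives_from unknown precursor %s",
                           mature.id, mature.derives_from)
            continue
        contained = (
            parent.chrom == mature.chrom
            and parent.strand == mature.strand
            and parent.start <= mature.start
            and mature.end <= parent.end
        )
        if not contained:
            raise ValueError(
                f"mature {mature.id} not contained in precursor {parent.id}"
            )


def write_annotation(annotations: Iterable[MirAnnotation], handle: TextIO) -> None:
    """Write annotations as miRBase-dialect GFF3 (1-based inclusive)."""
    handle.write("##gff-version 3\n")
    for a in annotations:
        ftype = "miRNA" if a.kind == KIND_MATURE else "miRNA_primary_transcript"
        attrs = f"ID={a.id};Name={a.name}"
        if a.kind == KIND_MATURE and a.derives_from:
            attrs += f";Derives_from={a.derives_from}"
        handle.write(
            f"{a.chrom}\t.\t{ftype}\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t{attrs}\n"
        )
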