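"""Ago-RIP-Seq targetome scoring.

An Ago-RIP experiment measures transcripts co-precipitating with Argonaute
after transfection with a specific miRNA mimic versus a nonspecific control,
each with a matched IgG isotype pulldown. The four conditions are
RPKM-normalized; transcripts expressed at RPKM >= 1 in at least one
condition are scored with the double difference

    score = (Ago.mimic - IgG.mimic) - (Ago.control - IgG.control)

computed on log2(RPKM + pseudocount), so the score is itself a log2 fold
change; targets are expressed transcripts with score strictly > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("ago_mir375", "igg_mir375", "ago_control", "igg_control")

DEFAULT_RPKM_THRESHOLD = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class RipExperiment:
    """Gene-level counts and lengths for the 2x2 (mimic x antibody) design."""

    counts: pd.DataFrame  # genes x CONDITIONS
    lengths: pd.Series  # per-gene exonic length, bp
    mapped_totals: pd.Series  # per-condition total mapped reads

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CONDITIONS:
            raise ValueError(f"count columns must be {CONDITIONS}")
        self.lengths = self.lengths.reindex(self.counts.index)
        self.mapped_totals = self.mapped_totals.reindex(list(CONDITIONS))
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class RipScore:
    gene: str
    rpkm: dict[str, float]
    expressed: bool
    score: float
    is_target: bool


def rpkm(experiment: RipExperiment) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads."""
    if (experiment.lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (experiment.mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    per_kb = experiment.counts.div(experiment.lengths / 1e3, axis=0)
    return per_kb.div(experiment.mapped_totals / 1e6, axis=1)


def expressed_filter(rpkm_matrix: pd.DataFrame,
                     threshold: float = DEFAULT_RPKM_THRESHOLD) -> set[str]:
    """Genes reaching RPKM >= threshold in at least one condition (inclusive)."""
    if rpkm_matrix.empty:
        return set()
    return set(rpkm_matrix.index[rpkm_matrix.max(axis=1) >= threshold])


def enrichment_score(rpkm_row, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     scale: str = "log2") -> float:
    """Double-difference enrichment of one gene's four RPKM values.

    ``scale="log2"`` (default) takes differences of log2(RPKM + pseudocount);
    ``scale="linear"`` takes them on raw RPKM (units: RPKM).
    """
    values = np.asarray([rpkm_row[c] for c in CONDITIONS], dtype=float)
    if (values < 0).any():
        raise ValueError("negative RPKM")
    if scale == "log2":
        values = np.log2(values + pseudocount)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    ago_mir, igg_mir, ago_ctl, igg_ctl = values
    return float((ago_mir - igg_mir) - (ago_ctl - igg_ctl))


def call_targets(
    experiment: RipExperiment,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale: str = "log2",
) -> list[RipScore]:
    """Full scoring pipeline: RPKM -> expressed filter -> score -> call.

    A gene is a target iff it passes the expressed filter and its score is
    strictly positive. Genes failing the filter are retained in the output
    (expressed=False, is_target=False) for auditability. Results sorted by
    descending score, ties broken by gene id.
    """
    matrix = rpkm(experiment)
    expressed = expressed_filter(matrix, rpkm_threshold)
    results = []
    for gene in experiment.genes:
        row = matrix.loc[gene]
        score = enrichment_score(row, pseudocount=pseudocount, scale=scale)
        is_expr = gene in expressed
        results.append(
            RipScore(
                gene=gene,
                rpkm={c: float(row[c]) for c in CONDITIONS},
                expressed=is_expr,
                score=score,
                is_target=bool(is_expr and score > 0.0),
            )
        )
    return sorted(results, key=lambda r: (-r.score, r.gene))


def rip_results_frame(results: list[RipScore]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"gene_id": r.gene}
        row.update({f"rpkm_{c}": r.rpkm[c] for c in CONDITIONS})
        row.update({"expressed": r.expressed, "score": r.score,
                    "is_target": r.is_target})
        rows.append(row)
    cols = ["gene_id"] + [f"rpkm_{c}" for c in CONDITIONS] + [
        "expressed", "score", "is_target"]
    return pd.DataFrame(rows, columns=cols)


def read_rip_table(path: str) -> RipExperiment:
    """Read the gene-level TSV (gene_id, length_bp, four count columns).

    Mapped totals come from ``#mapped_total=<condition>:<value>`` header
    lines; if absent, per-condition count sums are used.
    """
    totals: dict[str, float] = {}
    body: list[str] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#mapped_total="):
                cond, _, value = line.strip().removeprefix("#mapped_total=").partition(":")
                totals[cond] = float(value)
            elif not line.startswith("#"):
                body.append(line)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="gene_id")
    counts = frame[[f"count_{c}" for c in CONDITIONS]]
    counts.columns = list(CONDITIONS)
    if not totals:
        totals = counts.sum(axis=0).to_dict()
    return RipExperiment(counts=counts, lengths=frame["length_bp"].astype(float),
                         mapped_totals=pd.Series(totals, dtype=float))


def write_rip_table(experiment: RipExperiment, handle) -> None:
    for cond in CONDITIONS:
        handle.write(f"#mapped_total={cond}:{experiment.mapped_totals[cond]:g}\n")
    out = experiment.counts.copy()
    out.columns = [f"count_{c}" for c in CONDITIONS]
    out.insert(0, "length_bp", experiment.lengths)
    out.rename_axis("gene_id").to_csv(handle, sep="\t")
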