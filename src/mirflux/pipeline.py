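"""End-to-end orchestration: simulate -> trim -> quantify -> DE filter,
plus the RIP-scoring and qPCR-analytics branches, from one YAML config.

The config is validated strictly (unknown keys rejected) before any stage
runs. Every output file is recorded in a run manifest with a SHA-256
digest and row count, so end-to-end determinism can be audited by
comparing manifests from two runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .annotation import parse_annotation
from .de import de_results_frame, de_table, ma_data
from .qpcr import fit_decay
from .quant import (assign_reads, build_count_table, depth_normalize,
                    load_alignments, write_count_table)
from .rip import call_targets, rip_results_frame, write_rip_table
from .sim import (GroundTruth, SimConfig, default_mature_abundance,
                  generate_reference, simulate_count_matrix, simulate_decay_series,
                  simulate_reads, simulate_rip_experiment, write_reference, write_sam)
from .trim import TrimPolicy, trim_reads, write_fastq

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"seed"}
_SCHEMA: dict[str, set[str]] = {
    "seed": set(),
    "simulate": _SIM_KEYS | {"rip_noiseless"},
    "trim": {"leading_q", "trailing_q", "window_len", "window_meanq",
             "min_len", "adapters", "adapter_min_overlap", "adapter_max_mismatch"},
    "quantify": {"position_cap", "min_overlap", "ignore_strand", "cpm"},
    "de": {"fc_threshold", "basemean_threshold", "pseudocount"},
    "rip": {"rpkm_threshold", "pseudocount", "scale"},
    "qpcr": {"timepoints_h", "decay_method"},
}


@dataclass
class RunManifest:
    """Reproducibility metadata for one pipeline run."""

    config_digest: str
    version: str
    seed: int
    started: str
    finished: str = ""
    outputs: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, name: str, path: Path, rows: int | None = None) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entry: dict[str, Any] = {"path": str(path), "sha256": digest}
        if rows is not None:
            entry["rows"] = rows
        self.outputs[name] = entry

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def validate_config(config: Mapping[str, Any]) -> None:
    """Strict schema check; raises on any unknown section or key."""
    for section, value in config.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config key: {section!r}")
        if section == "seed":
            if not isinstance(value, int):
                raise ValueError("seed must be an integer")
            continue
        if value is None:
            continue
        if not isinstance(value, Mapping):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key in value:
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config key: {section}.{key}")


def _sim_config(config: Mapping[str, Any]) -> SimConfig:
    section = dict(config.get("simulate") or {})
    section.pop("rip_noiseless", None)
    return SimConfig(seed=int(config.get("seed", 0)), **section)


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> RunManifest:
    """Execute all stages in dependency order and write a run manifest.

    Stage outputs land under ``outdir``. Any stage failure aborts the run
    with the stage name in the exception message; the manifest is written
    last, only on success.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_digest=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        version=__version__,
        seed=int(config.get("seed", 0)),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    sim = _sim_config(config)
    stage = "simulate"
    try:
        truths = _stage_simulate(config, sim, outdir, manifest)
        stage = "trim"
        _stage_trim(config, outdir, manifest)
        stage = "quantify"
        _stage_quantify(config, outdir, manifest)
        stage = "de"
        _stage_de(config, outdir, manifest)
        stage = "rip"
        _stage_rip(config, outdir, manifest)
        stage = "qpcr"
        _stage_qpcr(config, outdir, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _stage_simulate(config: Mapping[str, Any], sim: SimConfig, outdir: Path,
                    manifest: RunManifest) -> dict[str, GroundTruth]:
    genome, annotations = generate_reference(sim)
    fasta, gff = write_reference(genome, annotations, outdir)
    manifest.record("genome_fasta", fasta)
    manifest.record("annotation_gff3", gff, rows=len(annotations))

    abundance = default_mature_abundance(sim, annotations)
    reads, sam, read_truth = simulate_reads(sim, genome, annotations, abundance,
                                            sample="s1")
    fastq_path = outdir / "reads_s1.fastq"
    with open(fastq_path, "w") as handle:
        write_fastq(reads, handle)
    manifest.record("reads_fastq", fastq_path, rows=len(reads))
    sam_path = outdir / "alignments_s1.sam"
    write_sam(genome, sam, sam_path)
    manifest.record("alignments_sam", sam_path, rows=len(sam))
    truth_path = outdir / "truth_counts_s1.tsv"
    read_truth.true_weighted_counts.rename_axis("mir_id").to_csv(
        truth_path, sep="\t")
    manifest.record("truth_counts", truth_path,
                    rows=len(read_truth.true_weighted_counts))

    table, de_truth = simulate_count_matrix(sim)
    matrix_path = outdir / "counts_matrix.tsv"
    with open(matrix_path, "w") as handle:
        write_count_table(table, handle)
    manifest.record("counts_matrix", matrix_path, rows=len(table.counts))
    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as handle:
        handle.write("sample\tgroup\n")
        for s in table.counts.columns:
            handle.write(f"{s}\t{s.rsplit('_', 1)[0]}\n")
    manifest.record("sample_sheet", sheet_path, rows=table.counts.shape[1])

    noiseless = bool((config.get("simulate") or {}).get("rip_noiseless", False))
    experiment, rip_truth = simulate_rip_experiment(sim, noiseless=noiseless)
    rip_path = outdir / "rip_counts.tsv"
    with open(rip_path, "w") as handle:
        write_rip_table(experiment, handle)
    manifest.record("rip_counts", rip_path, rows=len(experiment.genes))

    timepoints = (config.get("qpcr") or {}).get("timepoints_h",
                                                [0.0, 2.0, 4.0, 6.0, 8.0])
    series = simulate_decay_series(sim, timepoints)
    decay_path = outdir / "decay.tsv"
    pd.DataFrame({"time_h": series.timepoints_h,
                  "percent_remaining": series.percent_remaining}
                 ).to_csv(decay_path, sep="\t", index=False)
    manifest.record("decay_series", decay_path, rows=len(series.timepoints_h))
    return {"reads": read_truth, "de": de_truth, "rip": rip_truth}


def _stage_trim(config: Mapping[str, Any], outdir: Path,
                manifest: RunManifest) -> None:
    from .trim import read_fastq

    section = dict(config.get("trim") or {})
    if "adapters" in section:
        section["adapters"] = tuple(section["adapters"])
    policy = TrimPolicy(**section)
    out_path = outdir / "trimmed_s1.fastq"
    with open(outdir / "reads_s1.fastq") as src, open(out_path, "w") as dst:
        n = write_fastq(trim_reads(read_fastq(src), policy), dst)
    manifest.record("trimmed_fastq", out_path, rows=n)


def _stage_quantify(config: Mapping[str, Any], outdir: Path,
                    manifest: RunManifest) -> None:
    section = dict(config.get("quantify") or {})
    annotations = parse_annotation(str(outdir / "annotation.gff3"))
    alignments = load_alignments(str(outdir / "alignments_s1.sam"),
                                 position_cap=section.get("position_cap", 100))
    assignments = assign_reads(alignments, annotations,
                               min_overlap=section.get("min_overlap", 1),
                               ignore_strand=section.get("ignore_strand", False))
    table = build_count_table({"s1": assignments})
    if section.get("cpm", False):
        table = depth_normalize(table)
    out_path = outdir / "mir_counts.tsv"
    with open(out_path, "w") as handle:
        write_count_table(table, handle)
    manifest.record("mir_counts", out_path, rows=len(table.counts))


def _stage_de(config: Mapping[str, Any], outdir: Path,
              manifest: RunManifest) -> None:
    from .quant import read_count_table

    section = dict(config.get("de") or {})
    with open(outdir / "counts_matrix.tsv") as handle:
        table = read_count_table(handle)
    sheet = pd.read_csv(outdir / "samples.tsv", sep="\t")
    groups = dict(zip(sheet["sample"], sheet["group"]))
    results = de_table(table, groups,
                       pseudocount=section.get("pseudocount", 0.5),
                       fc_threshold=section.get("fc_threshold", 1.5),
                       basemean_threshold=section.get("basemean_threshold", 5.0))
    de_path = outdir / "de.tsv"
    de_results_frame(results).to_csv(de_path, sep="\t", index=False)
    manifest.record("de_table", de_path, rows=len(results))
    ma_path = outdir / "ma.tsv"
    ma_data(results).to_csv(ma_path, sep="\t", index=False)
    manifest.record("ma_table", ma_path)


def _stage_rip(config: Mapping[str, Any], outdir: Path,
               manifest: RunManifest) -> None:
    from .rip import read_rip_table

    section = dict(config.get("rip") or {})
    experiment = read_rip_table(str(outdir / "rip_counts.tsv"))
    results = call_targets(experiment,
                           rpkm_threshold=section.get("rpkm_threshold", 1.0),
                           pseudocount=section.get("pseudocount", 1.0),
                           scale=section.get("scale", "log2"))
    out_path = outdir / "rip_targets.tsv"
    rip_results_frame(results).to_csv(out_path, sep="\t", index=False)
    manifest.record("rip_targets", out_path, rows=len(results))


def _stage_qpcr(config: Mapping[str, Any], outdir: Path,
                manifest: RunManifest) -> None:
    from .qpcr import DecaySeries

    section = dict(config.get("qpcr") or {})
    frame = pd.read_csv(outdir / "decay.tsv", sep="\t")
    series = DecaySeries(timepoints_h=tuple(frame["time_h"]),
                         percent_remaining=tuple(frame["percent_remaining"]))
    fit = fit_decay(series, method=section.get("decay_method", "loglinear"))
    out_path = outdir / "decay_fit.tsv"
    pd.DataFrame([{"k_per_h": fit.k, "halflife_h": fit.halflife_h,
                   "r_squared": fit.r_squared, "decaying": fit.decaying}]
                 ).to_csv(out_path, sep="\t", index=False)
    manifest.record("decay_fit", out_path, rows=1)
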