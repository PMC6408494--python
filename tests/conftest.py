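"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import pytest

from mirflux.annotation import KIND_MATURE, KIND_PRECURSOR
from mirflux.quant import Assignment
from mirflux.sim import SimConfig, default_mature_abundance, generate_reference, simulate_reads


def brute_force_assign(alignments, annotations):
    """O(reads x annotations x positions) reference assigner.

    Independent of the interval-indexed implementation: plain nested loops,
    the two passes written out literally.
    """
    out: list[Assignment] = []
    for aln in alignments:
        for pass_no, kind in ((1, KIND_MATURE), (2, KIND_PRECURSOR)):
            pairs = []
            for i, pos in enumerate(aln.positions):
                for a in annotations:
                    if a.kind != kind:
                        continue
                    if a.chrom != pos.chrom or a.strand != pos.strand:
                        continue
                    if min(a.end, pos.end) - max(a.start, pos.start) + 1 >= 1:
                        pairs.append((i, a.id))
            if pairs:
                for i, mir in pairs:
                    out.append(Assignment(read_id=aln.read_id, mir_id=mir,
                                          position_index=i,
                                          weight=1.0 / len(pairs),
                                          pass_no=pass_no))
                break
    return out


def assignment_multiset(assignments):
    """Hashable multiset view for comparing assigner outputs."""
    return sorted(
        (a.read_id, a.mir_id, a.position_index, round(a.weight, 12), a.pass_no)
        for a in assignments
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, reads_per_sample=2_000, n_precursors=12,
                     mature_per_precursor=2, frac_multimapping=0.25)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_readset(small_config, small_reference):
    genome, annotations = small_reference
    abundance = default_mature_abundance(small_config, annotations)
    return simulate_reads(small_config, genome, annotations, abundance,
                          sample="s1")
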