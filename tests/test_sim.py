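"""Synthetic-data generator: determinism, geometry, and truth consistency."""

from __future__ import annotations

import collections
import math

import numpy as np
import pytest

from mirflux.annotation import KIND_MATURE, KIND_PRECURSOR
from mirflux.sim import (SimConfig, default_mature_abundance, find_occurrences,
                         generate_reference, revcomp, simulate_count_matrix,
                         simulate_decay_series, simulate_reads,
                         simulate_rip_experiment)


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError, match="nb_dispersion"):
            SimConfig(nb_dispersion=0.0)
        with pytest.raises(ValueError, match="frac_multimapping"):
            SimConfig(frac_multimapping=1.5)
        with pytest.raises(ValueError, match="mature_per_precursor"):
            SimConfig(mature_per_precursor=3)
        with pytest.raises(ValueError, match="decay_halflife_h"):
            SimConfig(decay_halflife_h=-1.0)


class TestGenerateReference:
    def test_every_mature_contained_in_its_precursor(self, small_reference):
        _genome, annotations = small_reference
        precursors = {a.id: a for a in annotations if a.kind == KIND_PRECURSOR}
        matures = [a for a in annotations if a.kind == KIND_MATURE]
        assert matures
        for m in matures:
            p = precursors[m.derives_from]
            assert p.chrom == m.chrom and p.strand == m.strand
            assert p.start <= m.start <= m.end <= p.end

    def test_no_multimapping_means_unique_mature_sequences(self):
        config = SimConfig(seed=3, frac_multimapping=0.0, n_precursors=10)
        genome, annotations = generate_reference(config)
        for a in annotations:
            if a.kind != KIND_MATURE:
                continue
            seq = genome[a.chrom][a.start - 1:a.end]
            if a.strand == "-":
                seq = revcomp(seq)
            assert len(find_occurrences(genome, seq)) == 1

    def test_requested_fraction_of_matures_duplicated(self):
        config = SimConfig(seed=3, frac_multimapping=0.4, n_precursors=20)
        genome, annotations = generate_reference(config)
        n_multi = 0
        for a in annotations:
            if a.kind != KIND_MATURE:
                continue
            seq = genome[a.chrom][a.start - 1:a.end]
            if a.strand == "-":
                seq = revcomp(seq)
            if len(find_occurrences(genome, seq)) == 2:
                n_multi += 1
        # each planted pair makes both members multimapping
        assert n_multi == 2 * round(0.4 * 20)

    def test_same_seed_reproduces_identical_reference(self):
        config = SimConfig(seed=11)
        assert generate_reference(config) == generate_reference(config)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_reference(SimConfig(chrom_length=1000, n_precursors=50,
                                         n_chromosomes=1))


class TestSimulateReads:
    def test_unique_mature_read_has_one_sam_record(self):
        config = SimConfig(seed=3, frac_multimapping=0.0, n_precursors=6)
        genome, annotations = generate_reference(config)
        mature = next(a for a in annotations if a.kind == KIND_MATURE)
        reads, sam, truth = simulate_reads(config, genome, annotations,
                                           {mature.id: 1})
        assert len(reads) == 1 and len(sam) == 1
        assert truth.read_assignments[reads[0].id] == {(mature.id, 0): 1.0}

    def test_duplicated_mature_read_splits_weight_half_half(self):
        config = SimConfig(seed=3, frac_multimapping=0.5, n_precursors=8)
        genome, annotations = generate_reference(config)
        # find a mature whose sequence occurs twice
        for a in annotations:
            if a.kind != KIND_MATURE:
                continue
            seq = genome[a.chrom][a.start - 1:a.end]
            if a.strand == "-":
                seq = revcomp(seq)
            if len(find_occurrences(genome, seq)) == 2:
                break
        else:
            pytest.fail("no duplicated mature found")
        reads, sam, truth = simulate_reads(config, genome, annotations, {a.id: 1})
        assert len(sam) == 2
        weights = truth.read_assignments[reads[0].id]
        assert len(weights) == 2
        assert all(w == 0.5 for w in weights.values())
        # the two assignments name two different annotated loci
        assert len({mir for mir, _i in weights}) == 2

    def test_sam_records_equal_exhaustive_occurrence_search(self, small_reference,
                                                            small_readset):
        genome, _annotations = small_reference
        reads, sam, _truth = small_readset
        by_read = collections.defaultdict(set)
        for rec in sam:
            strand = "-" if rec.flag & 0x10 else "+"
            by_read[rec.qname].add((rec.chrom, rec.pos, strand))
        for read in reads[::97]:  # spot-check a deterministic subsample
            expected = {(c, s, st) for c, s, _e, st
                        in find_occurrences(genome, read.bases)}
            assert by_read[read.id] == expected

    def test_truth_weights_sum_to_one_per_read(self, small_readset):
        _reads, _sam, truth = small_readset
        for read_id, weights in truth.read_assignments.items():
            assert abs(sum(weights.values()) - 1.0) < 1e-9

    def test_zero_requested_reads_yield_empty_outputs(self, small_reference):
        genome, annotations = small_reference
        config = SimConfig(seed=7)
        reads, sam, truth = simulate_reads(config, genome, annotations, {})
        assert reads == [] and sam == []
        assert truth.true_weighted_counts.empty

    def test_unknown_feature_in_abundance_rejected(self, small_reference):
        genome, annotations = small_reference
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_reads(SimConfig(seed=7), genome, annotations, {"nope": 5})

    def test_precursor_reads_overlap_no_mature(self, small_reference):
        config = SimConfig(seed=7, n_precursors=12, mature_per_precursor=2)
        genome, annotations = generate_reference(config)
        pre = next(a for a in annotations if a.kind == KIND_PRECURSOR)
        reads, _sam, truth = simulate_reads(config, genome, annotations,
                                            {pre.id: 3})
        for read in reads:
            weights = truth.read_assignments[read.id]
            assert weights == {(pre.id, 0): 1.0}


class TestSimulateCountMatrix:
    def test_same_seed_identical_matrices(self):
        config = SimConfig(seed=5, planted_log2fc={"miR-001": 2.0})
        t1, _ = simulate_count_matrix(config)
        t2, _ = simulate_count_matrix(config)
        assert t1.counts.equals(t2.counts)

    def test_planted_fold_change_recovered_in_expectation(self):
        # Monte-Carlo over seeds: empirical group ratio near 2^3 = 8
        ratios = []
        for seed in range(200):
            config = SimConfig(seed=seed, n_features=20,
                               reads_per_sample=50_000,
                               planted_log2fc={"miR-001": 3.0})
            table, _ = simulate_count_matrix(config)
            control = table.counts.loc["miR-001",
                                       [c for c in table.counts if "control" in c]]
            coculture = table.counts.loc["miR-001",
                                         [c for c in table.counts if "coculture" in c]]
            ratios.append(coculture.mean() / control.mean())
        assert np.mean(ratios) == pytest.approx(8.0, rel=0.05)

    def test_true_de_set_is_planted_features_above_fc_threshold(self):
        config = SimConfig(seed=5, planted_log2fc={
            "miR-001": 2.0, "miR-002": -2.0, "miR-003": 0.3})
        _, truth = simulate_count_matrix(config)
        assert truth.true_de_set == {"miR-001", "miR-002"}

    def test_null_config_means_no_true_differential_features(self):
        _, truth = simulate_count_matrix(SimConfig(seed=5))
        assert truth.true_de_set == set()


class TestSimulateRip:
    def test_same_seed_identical_tables(self):
        config = SimConfig(seed=9, planted_rip_targets={"gene0001": 2.0})
        e1, _ = simulate_rip_experiment(config)
        e2, _ = simulate_rip_experiment(config)
        assert e1.counts.equals(e2.counts)
        assert e1.mapped_totals.equals(e2.mapped_totals)

    def test_noiseless_null_gene_scores_zero_and_planted_scores_exact(self):
        from mirflux.rip import call_targets

        config = SimConfig(seed=9, planted_rip_targets={"gene0001": 2.0})
        experiment, truth = simulate_rip_experiment(config, noiseless=True)
        scores = {r.gene: r for r in call_targets(experiment)}
        assert scores["gene0001"].score == pytest.approx(2.0, abs=1e-9)
        assert scores["gene0001"].is_target
        assert truth.true_target_set == {"gene0001"}
        null_scores = [abs(r.score) for g, r in scores.items() if g != "gene0001"]
        assert max(null_scores) < 1e-9

    def test_expected_reads_floor_respected(self):
        config = SimConfig(seed=9)
        experiment, _ = simulate_rip_experiment(config, noiseless=True)
        assert experiment.counts.values.min() >= 30.0


class TestSimulateDecay:
    def test_noiseless_closed_form(self):
        config = SimConfig(seed=1, decay_halflife_h=2.0, noise_cv=0.0)
        series = simulate_decay_series(config, [0.0, 2.0, 4.0])
        assert series.percent_remaining[0] == 100.0
        assert series.percent_remaining[1] == pytest.approx(50.0)
        assert series.percent_remaining[2] == pytest.approx(25.0)

    def test_t0_renormalized_to_100_with_noise(self):
        config = SimConfig(seed=1, noise_cv=0.1)
        series = simulate_decay_series(config, [0.0, 2.0, 4.0, 6.0, 8.0])
        assert series.percent_remaining[0] == 100.0

    def test_loglinear_slope_matches_planted_halflife(self):
        config = SimConfig(seed=1, decay_halflife_h=3.07, noise_cv=0.05)
        series = simulate_decay_series(config, [0.0, 2.0, 4.0, 6.0, 8.0])
        slope = np.polyfit(series.timepoints_h,
                           np.log(series.percent_remaining), 1)[0]
        assert -slope == pytest.approx(math.log(2) / 3.07, rel=0.2)

    def test_negative_timepoint_rejected(self):
        with pytest.raises(ValueError, match="negative timepoint"):
            simulate_decay_series(SimConfig(seed=1), [-1.0, 0.0, 2.0])


def test_streams_are_independent():
    """Consuming one artifact's stream must not perturb another's output."""
    config = SimConfig(seed=21)
    series_alone = simulate_decay_series(config, [0.0, 4.0, 8.0])
    generate_reference(config)
    simulate_count_matrix(config)
    series_after = simulate_decay_series(config, [0.0, 4.0, 8.0])
    assert series_alone == series_after


def test_abundance_scales_to_requested_depth(small_config, small_reference):
    _genome, annotations = small_reference
    abundance = default_mature_abundance(small_config, annotations)
    assert sum(abundance.values()) == pytest.approx(small_config.reads_per_sample)
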