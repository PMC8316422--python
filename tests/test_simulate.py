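import numpy as np
import pytest

from intratad.caller import CallerParams, call_tads
from intratad.intervals import GenomicInterval
from intratad.io import gc_fraction
from intratad.matching import match_summary, match_tads
from intratad.simulate import (
    add_noise,
    make_genome,
    make_hic_reference,
    make_patient,
    make_spike_counts,
    plant_loops,
    score_recovery,
    write_truth,
)


class TestMakeGenome:
    SIZES = {"chr1": 1_000_000}

    def test_background_gc_concentrates(self):
        seqs, islands = make_genome(self.SIZES, base_gc=0.40, island_gc=0.75, seed=1)
        genome = seqs
        mask = np.zeros(self.SIZES["chr1"], dtype=bool)
        for isl in islands:
            mask[isl.start : isl.end] = True
        seq = np.frombuffer(seqs["chr1"].encode(), dtype="S1")
        is_gc = np.isin(seq, [b"G", b"C"])
        bg_gc = is_gc[~mask].mean()
        assert abs(bg_gc - 0.40) < 0.01  # binomial concentration at n ~ 1e6

    def test_islands_classify_gc_over_60(self):
        seqs, islands = make_genome(self.SIZES, island_gc=0.75, seed=2)
        assert islands  # ~10 per Mb
        classified = [
            gc_fraction(isl, seqs) > 0.60 for isl in islands if isl.length >= 500
        ]
        assert np.mean(classified) >= 0.99

    def test_seed_reproducibility(self):
        a, ia = make_genome({"chr1": 50_000}, seed=7)
        b, ib = make_genome({"chr1": 50_000}, seed=7)
        assert a == b and ia == ib

    def test_invalid_gc_ordering_rejected(self):
        with pytest.raises(ValueError):
            make_genome(self.SIZES, base_gc=0.8, island_gc=0.7)

    def test_infeasible_island_packing_errors(self):
        with pytest.raises(RuntimeError):
            make_genome(
                {"chr1": 3000},
                island_density=2000.0,
                island_length_range=(1500, 2000),
                seed=0,
                max_retries_per_island=5,
            )


class TestPlantLoops:
    def test_noise_free_recovery_is_exact(self):
        truth = plant_loops(n_loops=5, seed=3)
        tads = call_tads(truth.cohesin_peaks, truth.ctcf_peaks, truth.motifs)
        assert len(tads) == 5
        res = match_tads(tads, [(pl.loop_id, pl.span) for pl in truth.planted_loops])
        assert match_summary(res)["category_fractions"]["complete"] == 1.0

    def test_zero_loops_empty_everything(self):
        truth = plant_loops(n_loops=0, seed=0)
        assert truth.cohesin_peaks == [] and truth.planted_loops == []
        assert call_tads([], [], truth.motifs) == []

    def test_unbalanced_config_rejected(self):
        with pytest.raises(ValueError, match="min_balance"):
            plant_loops(n_loops=2, min_balance=0.2, seed=0)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            plant_loops(n_loops=100, chrom_sizes={"chr1": 10_000_000}, seed=0)

    def test_seed_reproducibility(self, small_truth):
        again = plant_loops(n_loops=20, seed=42)
        assert [p.interval for p in again.cohesin_peaks] == [
            p.interval for p in small_truth.cohesin_peaks
        ]
        assert [p.score for p in again.cohesin_peaks] == [
            p.score for p in small_truth.cohesin_peaks
        ]

    def test_planted_loops_pass_minimum_proportion(self, small_truth):
        for pl in small_truth.planted_loops:
            lo, hi = sorted([pl.fwd_score, pl.rev_score])
            assert lo >= 0.4 * hi


class TestAddNoise:
    def test_zero_noise_is_identity(self, small_truth):
        quiet = add_noise(small_truth, 0.0, 0.0, 0.0, seed=5)
        assert [p.interval for p in quiet.cohesin_peaks] == [
            p.interval for p in small_truth.cohesin_peaks
        ]
        assert [m.interval.strand for m in quiet.motifs] == [
            m.interval.strand for m in small_truth.motifs
        ]
        assert quiet.destroyed_loops == {}

    def test_full_flip_destroys_all_planted_loops(self, small_truth):
        # flip rate ~1: use 0.999 (rate must be < 1); with rounding every
        # planted motif row flips, so no planted loop stays convergent
        noisy = add_noise(small_truth, 0.0, 0.0, 0.999, seed=6)
        tads = call_tads(noisy.cohesin_peaks, noisy.ctcf_peaks, noisy.motifs)
        rec = score_recovery(tads, noisy, require_intact=False)
        assert rec["recall_all_planted"] == 0.0
        assert len(noisy.destroyed_loops) == len(noisy.planted_loops)

    def test_seed_reproducibility(self, small_truth):
        a = add_noise(small_truth, seed=9)
        b = add_noise(small_truth, seed=9)
        assert [p.score for p in a.cohesin_peaks] == [p.score for p in b.cohesin_peaks]
        assert [m.interval.strand for m in a.motifs] == [
            m.interval.strand for m in b.motifs
        ]

    def test_decoys_recorded_and_not_cobound(self, small_truth):
        noisy = add_noise(small_truth, decoy_peak_density=0.2,
                          score_jitter_sd=0.0, orientation_flip_rate=0.0, seed=4)
        n_extra = len(noisy.cohesin_peaks) + len(noisy.ctcf_peaks) - (
            len(small_truth.cohesin_peaks) + len(small_truth.ctcf_peaks)
        )
        assert n_extra == len(noisy.noise_peaks) > 0
        # decoys alone never create loops: recovery stays exact
        tads = call_tads(noisy.cohesin_peaks, noisy.ctcf_peaks, noisy.motifs)
        rec = score_recovery(tads, noisy)
        assert rec["recall"] == 1.0 and rec["precision"] == 1.0


class TestMakePatient:
    def test_zero_redistribution_matches_control_completely(self, small_truth):
        patient = make_patient(small_truth, nipbl_loss_fraction=0.0,
                               redistribution_fraction=0.0, seed=1)
        control_tads = call_tads(
            small_truth.cohesin_peaks, small_truth.ctcf_peaks, small_truth.motifs
        )
        patient_tads = call_tads(
            patient.cohesin_peaks, patient.ctcf_peaks, patient.motifs
        )
        res = match_tads(patient_tads, control_tads)
        assert match_summary(res)["category_fractions"]["complete"] == 1.0

    def test_full_redistribution_empties_patient(self, small_truth):
        patient = make_patient(small_truth, redistribution_fraction=1.0, seed=1)
        patient_tads = call_tads(
            patient.cohesin_peaks, patient.ctcf_peaks, patient.motifs
        )
        assert patient_tads == []
        from intratad.matching import compare_conditions

        control_tads = call_tads(
            small_truth.cohesin_peaks, small_truth.ctcf_peaks, small_truth.motifs
        )
        # control-centric view against the (empty) patient reference
        res = compare_conditions(patient_tads, control_tads)
        assert res["fraction_different"] == 1.0

    def test_affected_sets_nested_across_fractions(self, small_truth):
        destroyed = [
            set(
                make_patient(small_truth, redistribution_fraction=f, seed=3)
                .destroyed_loops
            )
            for f in (0.1, 0.3, 0.6)
        ]
        assert destroyed[0] <= destroyed[1] <= destroyed[2]

    def test_nipbl_loss_fraction_applied(self, small_truth):
        patient = make_patient(small_truth, nipbl_loss_fraction=0.5,
                               redistribution_fraction=0.0, seed=2)
        assert len(patient.nipbl_peaks) == round(0.5 * len(small_truth.nipbl_peaks))


class TestMakeHicReference:
    def test_clean_reference_matches_completely(self, small_truth):
        tads = call_tads(
            small_truth.cohesin_peaks, small_truth.ctcf_peaks, small_truth.motifs
        )
        hic = make_hic_reference(small_truth, seed=1)
        s = match_summary(match_tads(tads, hic))
        assert s["category_fractions"]["complete"] == 1.0

    def test_boundary_jitter_creates_partials(self, small_truth):
        tads = call_tads(
            small_truth.cohesin_peaks, small_truth.ctcf_peaks, small_truth.motifs
        )
        hic = make_hic_reference(small_truth, boundary_jitter_frac=0.02, seed=2)
        s = match_summary(match_tads(tads, hic))
        assert s["category_fractions"]["complete"] < 1.0
        assert s["category_fractions"]["partial"] > 0.0

    def test_all_dropped_means_unmatched(self, small_truth):
        tads = call_tads(
            small_truth.cohesin_peaks, small_truth.ctcf_peaks, small_truth.motifs
        )
        hic = make_hic_reference(small_truth, fn_rate=0.999, seed=3)
        s = match_summary(match_tads(tads, hic))
        assert s["category_fractions"]["unmatched"] == 1.0

    def test_false_positives_added(self, small_truth):
        hic = make_hic_reference(small_truth, fp_rate=0.5, seed=4)
        n_fp = sum(1 for lp in hic if lp.source_id.startswith("hic_fp"))
        assert n_fp == round(0.5 * len(small_truth.planted_loops))


class TestMakeSpikeCounts:
    def test_spike_close_to_nominal_fraction(self):
        samples, _ = make_spike_counts(
            n_samples=4, depth_range=(100_000, 100_000), spike_fraction=0.05, seed=5
        )
        for s in samples:
            depth = s.host_reads + s.spike_reads
            se = np.sqrt(depth * 0.05 * 0.95)
            assert abs(s.spike_reads - 0.05 * depth) < 4 * se

    def test_equal_depths_give_near_unity_factors(self):
        from intratad.calibration import spike_scale_factors

        samples, _ = make_spike_counts(
            n_samples=3, depth_range=(100_000, 100_000), spike_fraction=0.05, seed=6
        )
        out = spike_scale_factors(samples)
        # binomial spread of spike counts: factors near 1 within 3 SE
        target = min(s.spike_reads for s in samples)
        for s in out:
            se = np.sqrt(s.spike_reads * 0.95) / s.spike_reads
            assert s.downsample_factor > 1 - 4 * se

    def test_seed_reproducibility(self):
        a, _ = make_spike_counts(seed=7)
        b, _ = make_spike_counts(seed=7)
        assert [(s.host_reads, s.spike_reads) for s in a] == [
            (s.host_reads, s.spike_reads) for s in b
        ]

    def test_reads_materialized_on_request(self):
        samples, reads = make_spike_counts(
            n_samples=2, depth_range=(1000, 1000), seed=8, make_reads=True
        )
        for s in samples:
            assert len(reads[s.sample_id]) == s.host_reads


class TestWriteTruth:
    def test_outputs_readable_by_io_module(self, small_truth, tmp_path):
        from intratad.io import read_fimo_tsv, read_loops_bedpe, read_narrowpeak

        paths = write_truth(small_truth, tmp_path / "out")
        cohesin = read_narrowpeak(paths["cohesin"])
        assert [p.interval for p in cohesin] == [
            p.interval for p in small_truth.cohesin_peaks
        ]
        motifs = read_fimo_tsv(paths["motifs"])
        assert [m.interval for m in motifs] == [
            m.interval for m in small_truth.motifs
        ]
        loops = read_loops_bedpe(paths["loops"])
        assert len(loops) == len(small_truth.planted_loops)
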