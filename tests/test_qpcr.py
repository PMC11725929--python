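"""qPCR enrichment arithmetic and DRIP coverage-signal operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimox as fx
from flimox.qpcr import CtRecord


def rec(ct, role="IP", dilution=10.0, target="nd6", sample="s1", **kwargs):
    cts = [ct] if np.isscalar(ct) else list(ct)
    return CtRecord(sample=sample, target=target, role=role, dilution=dilution,
                    ct_replicates=cts, **kwargs)


class TestMeanCt:
    def test_triplicate_mean(self):
        result = fx.mean_ct(rec([24.0, 24.2, 24.1]))
        assert result.value == pytest.approx(24.1)
        assert not result.any_outlier

    def test_single_replicate(self):
        assert fx.mean_ct(rec(25.5)).value == 25.5

    def test_outlier_flagged_not_dropped(self):
        result = fx.mean_ct(rec([24.0, 24.1, 30.0]))
        assert result.value == pytest.approx((24.0 + 24.1 + 30.0) / 3)
        assert result.outlier_flags == [False, False, True]

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            rec([])


class TestDripEnrichment:
    def test_worked_example(self):
        """Ct_IP=28 at 10x vs Ct_input=24 at 100x -> (10*2^-28)/(100*2^-24)."""
        enr = fx.drip_enrichment(rec(28.0, "IP", 10.0), rec(24.0, "input", 100.0))
        assert enr.ip_over_input == pytest.approx(0.00625)
        assert not enr.input_fraction_corrected

    def test_equal_ct_equal_dilution_unity(self):
        enr = fx.drip_enrichment(rec(25.0, "IP", 10.0), rec(25.0, "input", 10.0))
        assert enr.ip_over_input == pytest.approx(1.0)

    def test_input_fraction_correction(self):
        enr = fx.drip_enrichment(rec(28.0, "IP", 10.0),
                                 rec(24.0, "input", 100.0, input_fraction=0.02),
                                 correct_input_fraction=True)
        assert enr.ip_over_input == pytest.approx(0.00625 * 0.02)
        assert enr.input_fraction_corrected

    def test_role_and_target_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fx.drip_enrichment(rec(28.0, "input", 10.0), rec(24.0, "input", 100.0))
        with pytest.raises(ValueError):
            fx.drip_enrichment(rec(28.0, "IP", target="a"),
                               rec(24.0, "input", target="b"))

    @given(shift=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_common_ct_shift(self, shift):
        base = fx.drip_enrichment(rec(28.0, "IP", 10.0), rec(24.0, "input", 100.0))
        shifted = fx.drip_enrichment(rec(28.0 + shift, "IP", 10.0),
                                     rec(24.0 + shift, "input", 100.0))
        assert shifted.ip_over_input == pytest.approx(base.ip_over_input, rel=1e-9)


class TestRnaseHNormalize:
    def test_worked_example(self):
        enr = fx.drip_enrichment(rec(28.0, "IP", 10.0), rec(24.0, "input", 100.0))
        ctrl = fx.drip_enrichment(rec(30.3219281, "RNaseH-IP", 10.0),
                                  rec(24.0, "input", 100.0))
        assert ctrl.ip_over_input == pytest.approx(0.00125, rel=1e-6)
        out = fx.rnaseh_normalize(enr, ctrl)
        assert out.rnaseh_normalized == pytest.approx(5.0, rel=1e-6)

    def test_identical_enrichments_unity(self):
        enr = fx.drip_enrichment(rec(28.0, "IP", 10.0), rec(24.0, "input", 100.0))
        assert fx.rnaseh_normalize(enr, enr).rnaseh_normalized == pytest.approx(1.0)

    def test_zero_control_rejected(self):
        enr = fx.drip_enrichment(rec(28.0, "IP", 10.0), rec(24.0, "input", 100.0))
        bad = fx.EnrichmentResult(sample="s1", target="nd6", ip_over_input=0.0)
        with pytest.raises(ValueError):
            fx.rnaseh_normalize(enr, bad)


class TestMtdnaCopyNumber:
    def test_seven_cycle_difference(self):
        ratio = fx.mtdna_copy_number(rec(15.0, target="nd4"),
                                     rec(22.0, target="mTert"))
        assert ratio == pytest.approx(128.0)

    def test_equal_ct_unity_and_self_ratio(self):
        r = rec(20.0, target="nd4")
        assert fx.mtdna_copy_number(r, r) == pytest.approx(1.0)

    def test_non_doubling_efficiency(self):
        ratio = fx.mtdna_copy_number(rec(20.0, target="nd4"),
                                     rec(22.0, target="mTert"), efficiency=1.9)
        assert ratio == pytest.approx(3.61)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            fx.mtdna_copy_number(rec(20.0), rec(22.0), efficiency=2.5)


class TestBinnedRpkm:
    def test_toy_rpkm_value(self):
        """10 reads in one 20 bp bin out of 1e6 total -> 500 RPKM."""
        import pandas as pd
        starts = np.concatenate([np.full(10, 100), np.arange(1_000_000 - 10) % 15000 + 200])
        reads = pd.DataFrame({"start": starts, "end": starts + 50,
                              "strand": ["+"] * starts.size})
        signal = fx.binned_rpkm(reads, 16000, bin_size=20)
        assert signal.total_reads == 1_000_000
        assert signal.values[100 // 20] == pytest.approx(500.0)

    def test_count_conservation(self):
        reads = fx.generate_reads(16300, 20000, 75, seed=1)
        signal = fx.binned_rpkm(reads, 16300, bin_size=20)
        counts = signal.values * (20 / 1000.0) * (signal.total_reads / 1e6)
        assert counts.sum() == pytest.approx(signal.total_reads)

    def test_minus_strand_uses_five_prime_end(self):
        import pandas as pd
        reads = pd.DataFrame({"start": [0], "end": [75], "strand": ["-"]})
        signal = fx.binned_rpkm(reads, 1000, bin_size=20)
        assert signal.values[74 // 20] > 0
        assert signal.values[0] == 0

    def test_empty_reads_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            fx.binned_rpkm(pd.DataFrame(columns=["start", "end", "strand"]), 1000, 20)


class TestSmoothSignal:
    def _signal(self, values, bin_size=15):
        values = np.asarray(values, dtype=float)
        return fx.BinnedSignal(genome_length=len(values) * bin_size,
                               bin_size=bin_size, values=values, total_reads=1000)

    def test_constant_signal_unchanged(self):
        signal = self._signal(np.full(100, 7.0))
        out = fx.smooth_signal(signal, smooth_length=45)
        np.testing.assert_allclose(out.values, 7.0)
        assert out.smoothed

    def test_spike_spreads_over_window(self):
        values = np.zeros(30)
        values[10] = 9.0
        out = fx.smooth_signal(self._signal(values), smooth_length=45)
        np.testing.assert_allclose(out.values[9:12], 3.0)
        assert out.values.sum() == pytest.approx(9.0)

    def test_circular_mean_preserved(self):
        rng = np.random.default_rng(8)
        signal = self._signal(rng.exponential(size=200))
        out = fx.smooth_signal(signal, smooth_length=45)
        assert out.values.mean() == pytest.approx(signal.values.mean(), abs=1e-12)

    def test_wraparound_at_origin(self):
        values = np.zeros(30)
        values[0] = 6.0
        out = fx.smooth_signal(self._signal(values), smooth_length=45)
        assert out.values[-1] == pytest.approx(2.0)
        assert out.values[1] == pytest.approx(2.0)

    def test_window_exceeding_genome_rejected(self):
        with pytest.raises(ValueError):
            fx.smooth_signal(self._signal(np.zeros(2)), smooth_length=1000)


class TestNormalizeTracks:
    def _signal(self, values):
        values = np.asarray(values, dtype=float)
        return fx.BinnedSignal(genome_length=len(values) * 20, bin_size=20,
                               values=values, total_reads=1000)

    def test_identical_tracks_unity_without_pseudocount(self):
        track = self._signal(np.full(50, 3.0))
        out = fx.normalize_tracks(track, track, pseudocount=0.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_doubled_track_ratio_two(self):
        ref = self._signal(np.full(50, 5.0))
        ip = self._signal(np.full(50, 10.0))
        out = fx.normalize_tracks(ip, ref, pseudocount=0.0)
        np.testing.assert_allclose(out.values, 2.0)

    def test_simulated_peak_stands_out_after_normalization(self):
        ip_reads = fx.generate_reads(16300, 50000, 75,
                                     peaks=[(8000.0, 100.0, 20.0)], seed=3)
        input_reads = fx.generate_reads(16300, 50000, 75, seed=4)
        ip = fx.smooth_signal(fx.binned_rpkm(ip_reads, 16300, 20), 45)
        ref = fx.smooth_signal(fx.binned_rpkm(input_reads, 16300, 20), 45)
        out = fx.normalize_tracks(ip, ref, mode="input")
        assert out.values[8000 // 20] > 5 * np.median(out.values)
        assert out.norm_mode == "input"

    def test_binning_mismatch_rejected(self):
        a = self._signal(np.zeros(50))
        b = fx.BinnedSignal(genome_length=1000, bin_size=10,
                            values=np.zeros(100), total_reads=10)
        with pytest.raises(ValueError):
            fx.normalize_tracks(a, b)


class TestBedgraph:
    def test_roundtrippable_text_track(self, tmp_path):
        signal = fx.BinnedSignal(genome_length=95, bin_size=20,
                                 values=np.array([1.0, 0.0, 2.5, 0.25, 4.0]),
                                 total_reads=10)
        path = tmp_path / "track.bedGraph"
        fx.write_bedgraph(signal, path, chrom="chrM")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 5
        assert lines[0].split("\t") == ["chrM", "0", "20", "1"]
        # final bin is truncated at the circular genome end
        assert lines[-1].split("\t") == ["chrM", "80", "95", "4"]
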