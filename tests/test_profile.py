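import logging

import numpy as np
import pandas as pd
import pytest

from nucleoprof import profile as prof


def signal_table(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "mnase", "gdna", "replicate_id", "sample_id"]
    )


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "mnase,gdna,expected",
        [(500.0, 500.0, 0.0), (800.0, 400.0, 1.0), (300.0, 1200.0, -2.0)],
    )
    def test_closed_form(self, mnase, gdna, expected):
        out = prof.compute_log2_ratio(signal_table([("p1", mnase, gdna, "r1", "s")]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(expected)

    def test_nonpositive_names_probe(self):
        with pytest.raises(ValueError, match="pBad"):
            prof.compute_log2_ratio(signal_table([("pBad", -1.0, 5.0, "r1", "s")]))


class TestAverageReplicates:
    @pytest.mark.parametrize(
        "values,expected",
        [((0.4, 0.6), 0.5), ((0.7,), 0.7), ((-1.0, 0.0, 1.0), 0.0)],
    )
    def test_mean_across_replicates(self, values, expected):
        rows = [
            {"probe_id": "p1", "replicate_id": f"r{i}", "sample_id": "s", "log2_ratio": v}
            for i, v in enumerate(values)
        ]
        out = prof.average_replicates(pd.DataFrame(rows))
        assert out["log2_ratio"].iloc[0] == pytest.approx(expected)

    def test_partial_probe_warns_and_averages_available(self, caplog):
        rows = [
            {"probe_id": "p1", "replicate_id": "r1", "sample_id": "s", "log2_ratio": 0.2},
            {"probe_id": "p1", "replicate_id": "r2", "sample_id": "s", "log2_ratio": 0.4},
            {"probe_id": "p2", "replicate_id": "r1", "sample_id": "s", "log2_ratio": 0.9},
        ]
        with caplog.at_level(logging.WARNING, logger="nucleoprof.profile"):
            out = prof.average_replicates(pd.DataFrame(rows)).set_index("probe_id")
        assert out.loc["p2", "log2_ratio"] == pytest.approx(0.9)
        assert any("missing" in r.message for r in caplog.records)


class TestReplicateConcordance:
    def test_self_and_affine_concordance_is_one(self):
        rng = np.random.default_rng(42)
        rep1 = pd.Series(rng.normal(size=50), index=[f"p{i}" for i in range(50)])
        assert prof.replicate_concordance(rep1, rep1) == pytest.approx(1.0)
        assert prof.replicate_concordance(rep1, 2 * rep1 + 3) == pytest.approx(1.0)

    def test_independent_replicates_near_zero(self):
        rng = np.random.default_rng(7)
        idx = [f"p{i}" for i in range(1000)]
        a = pd.Series(rng.normal(size=1000), index=idx)
        b = pd.Series(rng.normal(size=1000), index=idx)
        assert prof.replicate_concordance(a, b) < 0.05

    def test_zero_variance_is_missing(self):
        idx = ["p1", "p2", "p3"]
        flat = pd.Series([1.0, 1.0, 1.0], index=idx)
        other = pd.Series([0.0, 1.0, 2.0], index=idx)
        assert np.isnan(prof.replicate_concordance(flat, other))

    def test_too_few_common_probes(self):
        a = pd.Series([1.0, 2.0], index=["p1", "p2"])
        with pytest.raises(ValueError, match="3"):
            prof.replicate_concordance(a, a)


class TestMapProbesToTss:
    @staticmethod
    def setup_tables():
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [5075, 5675, 5075],
                "end": [5125, 5725, 5125],
            }
        )
        probes["center"] = (probes["start"] + probes["end"]) / 2.0
        signal = pd.Series([0.5, 0.6, 0.7], index=["a", "b", "c"])
        return probes, signal

    def test_strand_adjustment_and_flank(self):
        probes, signal = self.setup_tables()
        tss = pd.DataFrame(
            {
                "gene_id": ["gp", "gm"],
                "chrom": ["chr1", "chr1"],
                "tss": [5000, 5000],
                "strand": ["+", "-"],
            }
        )
        rel = prof.map_probes_to_tss(probes, signal, tss)
        by = rel.set_index(["gene_id", "probe_id"])["rel_pos"]
        assert by[("gp", "a")] == pytest.approx(100.0)
        assert by[("gm", "a")] == pytest.approx(-100.0)
        # probe at +700 is beyond the 600 bp flank
        assert ("gp", "b") not in by.index

    def test_probe_contributes_to_multiple_genes(self):
        probes, signal = self.setup_tables()
        tss = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "tss": [5000, 5200],
                "strand": ["+", "+"],
            }
        )
        rel = prof.map_probes_to_tss(probes, signal, tss)
        assert (rel["probe_id"] == "a").sum() == 2

    def test_chromosome_mismatch_excluded(self):
        probes, signal = self.setup_tables()
        tss = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr2"], "tss": [5000], "strand": ["+"]}
        )
        rel = prof.map_probes_to_tss(probes, signal, tss)
        assert set(rel["probe_id"]) == {"c"}


class TestAggregateWindows:
    def test_grid_and_constant_signal(self, rel_signals_factory):
        rel = rel_signals_factory([("g", p, 0.3) for p in range(-598, 599, 20)])
        track = prof.aggregate_windows(rel)
        assert len(track.window_centers) == 121
        assert track.window_centers[0] == -600 and track.window_centers[-1] == 600
        covered = track.n_points > 0
        assert np.allclose(track.mean_signal[covered], 0.3)

    def test_half_open_window_membership(self, rel_signals_factory):
        rel = rel_signals_factory([("g", -14.0, 1.0), ("g", 14.0, 0.0)])
        track = prof.aggregate_windows(rel)
        i = np.where(track.window_centers == 0)[0][0]
        assert track.mean_signal[i] == pytest.approx(0.5)
        assert track.n_points[i] == 2
        # a record exactly on the upper edge belongs to the next window
        rel2 = rel_signals_factory([("g", 15.0, 1.0)])
        track2 = prof.aggregate_windows(rel2)
        assert track2.n_points[np.where(track2.window_centers == 0)[0][0]] == 0
        assert track2.n_points[np.where(track2.window_centers == 10)[0][0]] == 1

    def test_missing_iff_empty(self, rel_signals_factory):
        rel = rel_signals_factory([("g", 2.0, 1.0)])
        track = prof.aggregate_windows(rel)
        assert np.all(np.isnan(track.mean_signal) == (track.n_points == 0))

    def test_empty_gene_set_rejected(self, rel_signals_factory):
        rel = rel_signals_factory([("g", 0.0, 1.0)])
        with pytest.raises(ValueError, match="empty gene set"):
            prof.aggregate_windows(rel, genes=set())

    def test_union_is_weighted_mean_of_parts(self, rel_signals_factory):
        rng = np.random.default_rng(3)
        entries = [("gA", p, v) for p, v in zip(rng.integers(-590, 590, 40), rng.normal(size=40))]
        entries += [("gB", p, v) for p, v in zip(rng.integers(-590, 590, 25), rng.normal(size=25))]
        rel = rel_signals_factory(entries)
        both = prof.aggregate_windows(rel, {"gA", "gB"})
        ta = prof.aggregate_windows(rel, {"gA"})
        tb = prof.aggregate_windows(rel, {"gB"})
        num = np.nansum(
            [ta.mean_signal * ta.n_points, tb.mean_signal * tb.n_points], axis=0
        )
        den = ta.n_points + tb.n_points
        expect = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        np.testing.assert_allclose(both.mean_signal, expect, equal_nan=True)
        np.testing.assert_array_equal(both.n_points, den)

    def test_strand_flip_mirrors_track(self, rel_signals_factory):
        # rel positions avoid the half-open window boundaries (±5 mod 10)
        rng = np.random.default_rng(5)
        pos = rng.integers(-59, 60, 60) * 10 + 2
        vals = rng.normal(size=60)
        rel = rel_signals_factory([("g", p, v) for p, v in zip(pos, vals)])
        mirrored = rel_signals_factory([("g", -p, v) for p, v in zip(pos, vals)])
        t = prof.aggregate_windows(rel)
        tm = prof.aggregate_windows(mirrored)
        np.testing.assert_allclose(
            t.mean_signal, tm.mean_signal[::-1], equal_nan=True
        )
        np.testing.assert_array_equal(t.n_points, tm.n_points[::-1])

    def test_determinism(self, rel_signals_factory):
        rng = np.random.default_rng(9)
        entries = [("g", p, v) for p, v in zip(rng.integers(-600, 601, 50), rng.normal(size=50))]
        a = prof.aggregate_windows(rel_signals_factory(entries))
        b = prof.aggregate_windows(rel_signals_factory(entries))
        assert np.array_equal(a.mean_signal, b.mean_signal, equal_nan=True)


class TestSmoothLowess:
    def test_reproduces_line_exactly(self):
        x = np.arange(-600.0, 601.0, 10.0)
        track = prof.WindowTrack(x, 2 * x + 1, np.ones(len(x)))
        for span in (0.05, 0.3, 0.8):
            smooth = prof.smooth_lowess(track, span_f=span)
            np.testing.assert_allclose(smooth.values, 2 * x + 1, atol=1e-6)

    def test_constant_input(self):
        x = np.arange(-600.0, 601.0, 10.0)
        track = prof.WindowTrack(x, np.full(len(x), 0.7), np.ones(len(x)))
        smooth = prof.smooth_lowess(track)
        np.testing.assert_allclose(smooth.values, 0.7, atol=1e-9)

    def test_noise_reduction_on_sinusoid(self):
        rng = np.random.default_rng(11)
        x = np.arange(-600.0, 601.0, 10.0)
        truth = np.sin(x / 300.0)
        noisy = truth + rng.normal(0, 0.1, len(x))
        track = prof.WindowTrack(x, noisy, np.ones(len(x)))
        smooth = prof.smooth_lowess(track, span_f=0.3)
        rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        rmse_smooth = np.sqrt(np.mean((smooth.values - truth) ** 2))
        assert rmse_smooth < rmse_raw

    def test_skips_missing_windows(self):
        x = np.arange(-600.0, 601.0, 10.0)
        y = np.sin(x / 200.0)
        y[3:6] = np.nan
        track = prof.WindowTrack(x, y, np.where(np.isnan(y), 0, 1))
        smooth = prof.smooth_lowess(track, span_f=0.3)
        assert len(smooth.positions) == len(x) - 3
        assert not np.isnan(smooth.values).any()

    def test_too_few_points(self):
        track = prof.WindowTrack([0.0, 10.0], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="span"):
            prof.smooth_lowess(track)


class TestEndToEndInvariants:
    def test_mnase_scaling_shifts_profile_by_log2_k(self, ordered_sim):
        import nucleoprof as npf

        k = 3.0
        scaled = ordered_sim.signals.copy()
        scaled["mnase"] = scaled["mnase"] * k
        base = npf.NucleosomeProfile.from_tables(
            ordered_sim.probes, ordered_sim.signals, ordered_sim.tss
        )
        shifted = npf.NucleosomeProfile.from_tables(
            ordered_sim.probes, scaled, ordered_sim.tss
        )
        rb = base.fit()
        rs = shifted.fit()
        np.testing.assert_allclose(
            rs.window_track.mean_signal - rb.window_track.mean_signal,
            np.log2(k),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            rs.smooth_track.values - rb.smooth_track.values, np.log2(k), atol=1e-8
        )

    def test_median_center_removes_sample_offset(self):
        df = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c"],
                "sample_id": "s",
                "replicate_id": "r1",
                "log2_ratio": [1.0, 2.0, 4.0],
            }
        )
        out = prof.median_center(df)
        assert list(out["log2_ratio"]) == [-1.0, 0.0, 2.0]


class TestTrackSerialization:
    def test_window_track_round_trip(self, tmp_path):
        x = np.arange(-600.0, 601.0, 10.0)
        y = np.sin(x / 100.0)
        y[5] = np.nan
        n = np.where(np.isnan(y), 0, 3)
        track = prof.WindowTrack(x, y, n)
        path = tmp_path / "track.tsv"
        track.to_tsv(path)
        back = prof.WindowTrack.from_tsv(path)
        np.testing.assert_allclose(back.mean_signal, y, equal_nan=True)
        np.testing.assert_array_equal(back.n_points, n)
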