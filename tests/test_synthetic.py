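"""Generator-level checks: protocol layout, Poisson calibration,
behaviour state algebra, LFP kernel identities, cluster geometry and
determinism of every component."""

import numpy as np
import pytest

from fearpeth import synthetic as syn
from fearpeth.core import ValidationError
from fearpeth.peth import bin_spikes, zscore_peth
from fearpeth.classify import detect_response
from fearpeth.specs import BehaviorSpec, ClusterSpec, LfpSpec, ProtocolSpec, UnitSpec


class TestProtocol:
    def test_delay_paradigm_places_footshock_at_tone_offset(self):
        ev = syn.make_protocol(ProtocolSpec(), seed=1)
        acq = ev.select("acquisition")
        assert len(acq) == 7
        assert np.allclose(acq.us_on_s, acq.tone_on_s + 10.0)
        assert np.allclose(acq.us_off_s - acq.us_on_s, 0.5)

    def test_trace_paradigm_delays_footshock_by_trace_interval(self):
        spec = ProtocolSpec(paradigm="trace", trace_interval_s=1.0)
        acq = syn.make_protocol(spec, seed=1).select("acquisition")
        assert np.allclose(acq.us_on_s, acq.tone_off_s + 1.0)

    def test_extinction_blocks_and_phase_labels(self):
        ev = syn.make_protocol(ProtocolSpec(), seed=3)
        ext = ev.select("extinction")
        assert len(ext) == 35
        assert list(ext.block.unique()) == [1, 2, 3, 4, 5]
        assert list(ev.select("extinction", "EE").trial_index) == list(range(1, 15))
        assert list(ev.select("extinction", "LE").trial_index) == list(range(21, 36))

    def test_itis_lie_in_configured_range(self):
        ev = syn.make_protocol(ProtocolSpec(), seed=4)
        df = ev.df
        gaps = df.tone_on_s.to_numpy()[1:] - df[["tone_off_s", "us_off_s"]].max(axis=1).to_numpy()[:-1]
        assert np.all((gaps >= 60.0) & (gaps <= 120.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            ProtocolSpec(n_extinction_trials=33)  # not a whole number of blocks
        with pytest.raises(ValidationError):
            ProtocolSpec(iti_range_s=(120.0, 60.0))


class TestUnits:
    def test_type2_mean_rate_matches_baseline_within_poisson_error(self, short_events):
        spec = UnitSpec(template="type2", baseline_rate_hz=5.0)
        train = syn.simulate_unit(spec, short_events, seed=11)
        T = short_events.duration_s
        se = np.sqrt(5.0 / T)
        assert abs(train.n_spikes / T - 5.0) < 3 * se

    def test_type2_fano_factor_near_one(self, short_events):
        counts = []
        for seed in range(60):
            train = syn.simulate_unit(UnitSpec(template="type2"), short_events, seed=seed)
            counts.append(np.histogram(train.times_s, bins=np.arange(0, 200, 1.0))[0])
        counts = np.concatenate(counts)
        fano = counts.var() / counts.mean()
        assert 0.9 < fano < 1.1

    def test_high_snr_type1_both_detected_at_onset_and_offset(self, short_events):
        hits = 0
        n_rep = 40
        # latency inside the first bin so the excitatory run is the
        # earliest crossing; a later latency can let a spurious -2 SD dip
        # in the pre-response bin claim the direction (floor effect of
        # near-zero Poisson baselines), which is a property of the
        # first-run rule rather than a detection failure
        spec = UnitSpec(template="type1_both", onset_gain=6.0, offset_gain=6.0,
                        response_latency_s=0.02, latency_jitter_sd_s=0.0,
                        extinction_decay_per_block=0.0)
        for seed in range(n_rep):
            train = syn.simulate_unit(spec, short_events, seed=seed)
            z_on = zscore_peth(bin_spikes(train, short_events, align="tone_onset"))
            stats = (z_on.baseline_mean, z_on.baseline_sd)
            z_off = zscore_peth(
                bin_spikes(train, short_events, align="tone_offset"), stats=stats
            )
            det_on, det_off = detect_response(z_on), detect_response(z_off)
            if (det_on.responsive and det_on.direction == "increase"
                    and det_off.responsive and det_off.direction == "increase"):
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_suppressive_template_lowers_rate_in_window(self, short_events):
        spec = UnitSpec(template="type4_onset_dec", baseline_rate_hz=20.0, onset_gain=0.1,
                        response_width_s=0.5, extinction_decay_per_block=0.0)
        train = syn.simulate_unit(spec, short_events, seed=5)
        ext = short_events.select("extinction")
        in_win = sum(
            np.sum((train.times_s >= row.tone_on_s + 0.04) & (train.times_s < row.tone_on_s + 0.54))
            for row in ext.itertuples()
        )
        expected_suppressed = 20.0 * 0.1 * 0.5 * len(ext)
        expected_baseline = 20.0 * 0.5 * len(ext)
        assert in_win < 0.5 * expected_baseline
        assert in_win < 3 * expected_suppressed + 3 * np.sqrt(expected_suppressed)

    def test_unit_determinism(self, short_events):
        spec = UnitSpec()
        a = syn.simulate_unit(spec, short_events, seed=42)
        b = syn.simulate_unit(spec, short_events, seed=42)
        assert np.array_equal(a.times_s, b.times_s)

    def test_detection_rate_monotone_in_onset_gain(self, short_events):
        rates = []
        for gain in (0.5, 2.0, 8.0):
            spec = UnitSpec(template="type1_onset", onset_gain=gain,
                            extinction_decay_per_block=0.0)
            hits = 0
            for seed in range(25):
                train = syn.simulate_unit(spec, short_events, seed=seed)
                zp = zscore_peth(bin_spikes(train, short_events))
                if not zp.degenerate and detect_response(zp).responsive:
                    hits += 1
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]


class TestBehavior:
    def test_intervals_tile_session(self, short_events):
        ann = syn.simulate_behavior(BehaviorSpec(), short_events, seed=2)
        st = ann.states
        assert st.start_s.iloc[0] == 0.0
        assert np.allclose(st.start_s.to_numpy()[1:], st.end_s.to_numpy()[:-1])
        assert st.end_s.iloc[-1] == pytest.approx(short_events.duration_s)

    def test_infinite_modulation_freezes_whole_tone(self, short_events):
        from fearpeth.behavior import percent_freezing

        spec = BehaviorSpec(cs_freeze_modulation=np.inf, modulation_decay_per_block=0.0)
        ann = syn.simulate_behavior(spec, short_events, seed=3)
        for row in short_events.select("extinction").itertuples():
            assert percent_freezing(ann, (row.tone_on_s, row.tone_off_s)) == pytest.approx(100.0)

    def test_equal_hazards_give_half_time_frozen(self):
        # no trials → no modulation anywhere; stationary split is 1/2
        ev = syn.make_protocol(
            ProtocolSpec(n_acquisition_trials=0, n_extinction_trials=7, block_size=7,
                         iti_range_s=(4000.0, 5000.0)),
            seed=9,
        )
        spec = BehaviorSpec(freeze_hazard_baseline=0.2, move_hazard_baseline=0.2,
                            cs_freeze_modulation=1.0)
        fractions = []
        for seed in range(8):
            ann = syn.simulate_behavior(spec, ev, seed=seed)
            frozen = ann.intervals("freeze")
            fractions.append((frozen[:, 1] - frozen[:, 0]).sum() / ev.duration_s)
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.05)

    def test_point_events_confined_to_move_intervals(self, short_events):
        spec = BehaviorSpec(rear_rate_hz=0.2, usv_rate_hz=0.2)
        ann = syn.simulate_behavior(spec, short_events, seed=7)
        move = ann.intervals("move")
        for t in ann.events.time_s:
            assert np.any((move[:, 0] <= t) & (t < move[:, 1] + 1e-9))

    def test_behavior_determinism(self, short_events):
        a = syn.simulate_behavior(BehaviorSpec(), short_events, seed=12)
        b = syn.simulate_behavior(BehaviorSpec(), short_events, seed=12)
        assert a == b


class TestLfp:
    def test_noiseless_kernel_peak_to_peak_and_length(self, short_events):
        spec = LfpSpec(noise_sd_uV=0.0, n_channels=1, kernel_decay_per_block=0.0,
                       onset_kernel=(0.006, 0.056, 400.0), offset_kernel=(0.0, 0.05, 0.0))
        (trace,) = syn.simulate_lfp(spec, short_events, seed=1)
        assert trace.samples_uV.size == int(np.ceil(short_events.duration_s * 1000))
        # single-cycle sine of p2p 400 → global max-min = 400 (grid-aligned peak)
        assert trace.samples_uV.max() - trace.samples_uV.min() == pytest.approx(400.0, rel=1e-3)

    def test_lfp_determinism(self, short_events):
        a = syn.simulate_lfp(LfpSpec(n_channels=2), short_events, seed=5)
        b = syn.simulate_lfp(LfpSpec(n_channels=2), short_events, seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.samples_uV, tb.samples_uV)


class TestClusters:
    def test_labels_and_sizes_preserved(self):
        spec = ClusterSpec(cluster_means=((0.0, 0.0), (50.0, 0.0)), cluster_sizes=(40, 60),
                           n_noise_spikes=30)
        cf = syn.simulate_cluster_features(spec, seed=1)
        assert cf.features.shape == (130, 2)
        assert np.sum(cf.labels == 1) == 40
        assert np.sum(cf.labels == 2) == 60
        assert np.sum(cf.labels == 0) == 30

    def test_cluster_determinism(self):
        spec = ClusterSpec(cluster_means=((0.0, 0.0),))
        a = syn.simulate_cluster_features(spec, seed=3)
        b = syn.simulate_cluster_features(spec, seed=3)
        assert np.array_equal(a.features, b.features)
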