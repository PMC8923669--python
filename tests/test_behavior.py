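"""Freezing overlap arithmetic, epoch durations, extinction slope,
event counts, block averaging and the repeated-measures correlation
(including a cross-check against pingouin's implementation)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from fearpeth.behavior import (
    block_average,
    count_events,
    epoch_durations,
    extinction_slope,
    iti_window,
    per_trial_freezing,
    percent_freezing,
    rmcorr,
)
from fearpeth.core import BehaviorAnnotation, TrialEvents, ValidationError
from fearpeth.specs import BehaviorSpec, ProtocolSpec
from fearpeth.synthetic import make_protocol, simulate_behavior


def _annotation(records, duration, events=None):
    states = pd.DataFrame(records, columns=["start_s", "end_s", "state"])
    ev = events if events is not None else pd.DataFrame(
        {"time_s": pd.Series(dtype=float), "kind": pd.Series(dtype=str)}
    )
    return BehaviorAnnotation(states, ev, duration_s=duration)


def _events_at(tone_ons, tone_dur=10.0, duration=None):
    rows = [
        (i, "extinction", (i - 1) // 7 + 1, on, on + tone_dur, np.nan, np.nan)
        for i, on in enumerate(tone_ons, start=1)
    ]
    df = pd.DataFrame(rows, columns=list(TrialEvents.COLUMNS))
    return TrialEvents(df, duration_s=duration or (tone_ons[-1] + tone_dur + 60.0))


class TestPercentFreezing:
    def test_full_cover_is_100(self):
        ann = _annotation([(0.0, 20.0, "freeze"), (20.0, 30.0, "move")], 30.0)
        assert percent_freezing(ann, (5.0, 15.0)) == 100.0

    def test_partial_overlap(self):
        ann = _annotation(
            [(0.0, 2.0, "move"), (2.0, 7.0, "freeze"), (7.0, 10.0, "move")], 10.0
        )
        assert percent_freezing(ann, (0.0, 10.0)) == pytest.approx(50.0)

    def test_freeze_plus_move_is_100_any_window(self, short_events):
        ann = simulate_behavior(BehaviorSpec(), short_events, seed=21)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0, short_events.duration_s - 20)
            w = (a, a + rng.uniform(1, 20))
            f = percent_freezing(ann, w)
            m = 100.0 * _move_overlap(ann, w) / (w[1] - w[0])
            assert f + m == pytest.approx(100.0, abs=1e-9)

    def test_matches_1ms_sampling_oracle(self, short_events):
        ann = simulate_behavior(BehaviorSpec(), short_events, seed=22)
        rng = np.random.default_rng(1)
        freeze = ann.intervals("freeze")
        for _ in range(10):
            a = rng.uniform(0, short_events.duration_s - 60)
            w = (a, a + 30.0)
            grid = np.arange(w[0], w[1], 0.001) + 0.0005
            inside = np.zeros(grid.size, dtype=bool)
            for s, e in freeze:
                inside |= (grid >= s) & (grid < e)
            oracle = 100.0 * inside.mean()
            assert percent_freezing(ann, w) == pytest.approx(oracle, abs=0.02)

    def test_invalid_window_rejected(self):
        ann = _annotation([(0.0, 10.0, "move")], 10.0)
        with pytest.raises(ValidationError):
            percent_freezing(ann, (5.0, 5.0))


def _move_overlap(ann, window):
    from fearpeth.behavior import overlap_s

    return overlap_s(ann.intervals("move"), window)


class TestEpochDurations:
    def _ann(self):
        # 5 alternating move(2 s)/freeze(3 s) pairs before CS+ at 25 s,
        # then freeze(6 s)/move(4 s) pairs afterwards
        recs = []
        t = 0.0
        for _ in range(5):
            recs.append((t, t + 2.0, "move")); t += 2.0
            recs.append((t, t + 3.0, "freeze")); t += 3.0
        for _ in range(6):
            recs.append((t, t + 6.0, "freeze")); t += 6.0
            recs.append((t, t + 4.0, "move")); t += 4.0
        return _annotation(recs, t), t

    def test_baseline_takes_last_five_epochs_before_first_cs(self):
        ann, dur = self._ann()
        ev = _events_at([25.0], duration=dur)
        ep = epoch_durations(ann, ev, "baseline")
        assert ep.freeze_mean_s == pytest.approx(3.0)
        assert ep.move_mean_s == pytest.approx(2.0)
        assert not ep.shortfall

    def test_ee_takes_first_five_epochs_from_first_cs(self):
        ann, dur = self._ann()
        ev = _events_at([25.0], duration=dur)
        ep = epoch_durations(ann, ev, "EE")
        assert ep.freeze_mean_s == pytest.approx(6.0)
        assert ep.move_mean_s == pytest.approx(4.0)

    def test_shortfall_flag_with_fewer_epochs(self):
        ann = _annotation(
            [(0.0, 5.0, "move"), (5.0, 8.0, "freeze"), (8.0, 40.0, "move")], 40.0
        )
        ev = _events_at([20.0], duration=40.0)
        ep = epoch_durations(ann, ev, "baseline", k=5)
        assert ep.shortfall
        assert ep.freeze_mean_s == pytest.approx(3.0)

    def test_epoch_scale_three_tripls_ee_freeze_bouts(self, short_events):
        ratios = []
        for seed in range(15):
            base = simulate_behavior(BehaviorSpec(), short_events, seed=seed)
            scaled = simulate_behavior(
                BehaviorSpec(epoch_duration_scale=3.0), short_events, seed=seed
            )
            e1 = epoch_durations(base, short_events, "EE")
            e3 = epoch_durations(scaled, short_events, "EE")
            ratios.append(e3.freeze_mean_s / e1.freeze_mean_s)
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.4)


class TestSlopeCountsBlocks:
    def test_exact_linear_slope(self):
        y = [100.0 - 2.0 * t for t in range(1, 22)]
        assert extinction_slope(y) == pytest.approx(-2.0, abs=1e-10)

    def test_constant_series_slope_zero(self):
        assert extinction_slope([40.0] * 21) == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_on_random_series(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            y = rng.uniform(0, 100, size=21)
            x = np.arange(1, 22, dtype=float)
            expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
            assert extinction_slope(y) == pytest.approx(expected, abs=1e-10)

    def test_count_events_half_open_boundary(self):
        ev = pd.DataFrame({"time_s": [1.0, 5.0, 9.999, 10.0], "kind": ["rear"] * 4})
        ann = _annotation([(0.0, 20.0, "move")], 20.0, events=ev)
        assert count_events(ann, (0.0, 10.0), "rear") == 3
        assert count_events(ann, (0.0, 10.0), "usv") == 0

    def test_block_average_five_blocks_of_seven(self):
        y = np.arange(35.0)
        means, partial = block_average(y)
        assert means.size == 5 and not partial
        assert means[0] == pytest.approx(3.0)

    def test_block_average_example_and_partial_flag(self):
        means, partial = block_average(np.arange(1.0, 8.0))
        assert means[0] == pytest.approx(4.0) and not partial
        means, partial = block_average(np.arange(1.0, 10.0))
        assert partial and means.size == 2

    def test_iti_window_spans_to_next_tone(self):
        ev = _events_at([20.0, 60.0], duration=100.0)
        first = ev.select("extinction").iloc[0]
        assert iti_window(ev, first) == (30.0, 60.0)
        last = ev.select("extinction").iloc[1]
        assert iti_window(ev, last) == (70.0, 100.0)


class TestRmCorr:
    def test_perfect_within_subject_line_gives_r_one(self):
        subj = np.repeat([0, 1, 2], 4)
        x = np.tile(np.arange(4.0), 3)
        y = 2.0 * x + np.repeat([10.0, -5.0, 3.0], 4)
        res = rmcorr(subj, x, y)
        assert res.r_rm == pytest.approx(1.0)
        assert res.common_slope == pytest.approx(2.0)

    def test_df_for_six_subjects_five_blocks(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(6), 5)
        res = rmcorr(subj, rng.normal(size=30), rng.normal(size=30))
        assert res.df == 23

    def test_matches_design_matrix_oracle_and_pingouin(self):
        rng = np.random.default_rng(7)
        for i in range(30):
            n_subj = int(rng.integers(3, 7))
            k = int(rng.integers(3, 8))
            subj = np.repeat(np.arange(n_subj), k)
            x = rng.normal(size=n_subj * k)
            y = rng.normal(size=n_subj * k)
            res = rmcorr(subj, x, y)
            # independent oracle: explicit projection-based ANCOVA sums
            r_o, df_o, p_o, slope_o = _oracle_rmcorr(subj, x, y)
            assert res.r_rm == pytest.approx(r_o, abs=1e-10)
            assert res.df == df_o
            assert res.p_value == pytest.approx(p_o, abs=1e-10)
            assert res.common_slope == pytest.approx(slope_o, abs=1e-10)
            if i < 5:  # cross-library check on a few cases
                df = pd.DataFrame({"s": subj, "x": x, "y": y})
                pgres = pg.rm_corr(data=df, x="x", y="y", subject="s")
                assert res.r_rm == pytest.approx(float(pgres.r.iloc[0]), abs=1e-9)
                assert res.df == int(pgres.dof.iloc[0])

    def test_invariances(self):
        rng = np.random.default_rng(9)
        subj = np.repeat(np.arange(4), 5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = rmcorr(subj, x, y)
        shifted = rmcorr(subj, x, y + np.repeat(rng.normal(size=4) * 100, 5))
        assert shifted.r_rm == pytest.approx(base.r_rm, abs=1e-9)
        scaled = rmcorr(subj, 3.0 * x, y)
        assert scaled.r_rm == pytest.approx(base.r_rm, abs=1e-9)

    def test_subject_with_single_observation_rejected(self):
        with pytest.raises(ValidationError):
            rmcorr([0, 0, 1], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_within_subject_variance_rejected(self):
        subj = np.repeat([0, 1], 3)
        x = np.repeat([2.0, 5.0], 3)
        with pytest.raises(ValidationError):
            rmcorr(subj, x, np.arange(6.0))


def _oracle_rmcorr(subj, x, y):
    """Projection-based ANCOVA oracle: residualise x and y on subject
    dummies, then simple regression on the residuals."""
    subj = np.asarray(subj)
    ids = np.unique(subj)
    xr, yr = x.astype(float).copy(), y.astype(float).copy()
    for s in ids:
        m = subj == s
        xr[m] -= xr[m].mean()
        yr[m] -= yr[m].mean()
    slope = float(np.sum(xr * yr) / np.sum(xr * xr))
    resid = yr - slope * xr
    ss_res = float(np.sum(resid**2))
    ss_slope = float(np.sum(yr**2)) - ss_res
    r = np.sign(slope) * np.sqrt(ss_slope / (ss_slope + ss_res))
    df = len(x) - ids.size - 1
    from scipy import stats as st

    p = float(st.f.sf(ss_slope / (ss_res / df), 1, df))
    return float(r), df, p, slope


class TestPerTrialFreezing:
    def test_columns_and_block_labels(self, short_events):
        ann = simulate_behavior(BehaviorSpec(), short_events, seed=30)
        df = per_trial_freezing(ann, short_events)
        assert list(df.columns) == ["trial_index", "block", "freezing_cs", "freezing_iti"]
        assert len(df) == 35
        assert df.block.nunique() == 5
        assert df.freezing_cs.between(0, 100).all()
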