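"""Trial-table I/O, hysteresis, adaptation level, and the randomized control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluctlearn import (
    DegenerateDataError,
    EnergyModel,
    FormatError,
    LearnerConfig,
    Trajectory,
    adaptation_fraction,
    build_protocol,
    hysteresis_table,
    randomized_control,
    read_trials,
    simulate_run,
    trials_from_run,
    write_trials,
)


def _tracker_trials(protocol, fn, pid="T1"):
    """Trial table of a deterministic responder x_n = fn(theta history)."""
    thetas = protocol.thetas
    xs = fn(thetas)
    return trials_from_run(protocol, Trajectory(xs, source="observed", participant_id=pid))


class TestIO:
    def test_round_trip_is_bit_exact(self, tmp_path):
        p = build_protocol(n_cycles=2, baseline_length=10)
        traj = simulate_run(EnergyModel(), p, LearnerConfig(), seed=0, participant_id="S01")
        df = trials_from_run(p, traj)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trials(df, f1)
        back = read_trials(f1)
        write_trials(back, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert len(back) == len(df)

    def test_missing_column_reported_by_name(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("participant_id,block,cycle,trial_index,theta_deg\nS1,main,1,1,0.0\n")
        with pytest.raises(FormatError, match="response_deg"):
            read_trials(f)

    def test_non_numeric_angle_reports_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text(
            "participant_id,block,cycle,trial_index,theta_deg,response_deg\n"
            "S1,main,1,1,0.0,1.0\nS1,main,1,2,0.0,oops\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            read_trials(f)

    def test_empty_file_with_header_gives_empty_table(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("participant_id,block,cycle,trial_index,theta_deg,response_deg\n")
        assert len(read_trials(f)) == 0

    def test_unknown_columns_preserved(self, tmp_path):
        p = build_protocol(n_cycles=1, baseline_length=10)
        df = _tracker_trials(p, lambda th: th.copy())
        df["rt_ms"] = 400.0
        f = tmp_path / "extra.csv"
        write_trials(df, f)
        assert "rt_ms" in read_trials(f).columns


class TestHysteresis:
    def test_perfect_tracker_has_no_hysteresis(self):
        p = build_protocol(n_cycles=3, baseline_length=10)
        table = hysteresis_table(_tracker_trials(p, lambda th: th.copy()), p)
        assert len(table) == p.segment_length
        assert np.allclose(table["difference"], 0.0, atol=1e-12)
        assert np.allclose(table["forward_mean"], table["theta_deg"], atol=1e-12)

    def test_lagging_tracker_shows_sign_pattern(self):
        # response repeats the previous trial's angle: on ascending runs the
        # forward mean trails below while the mirrored backward mean sits
        # above (and vice versa on the descending run)
        p = build_protocol(n_cycles=2, baseline_length=10)
        lag = lambda th: np.concatenate([[0.0], th[:-1]])
        table = hysteresis_table(_tracker_trials(p, lag), p)
        d = table["difference"].to_numpy()
        assert np.all(d[0:6] < 0)    # first ascending run (positions 1-6)
        assert np.all(d[7:18] > 0)   # descending run (positions 8-18)
        assert np.all(d[19:25] < 0)  # final ascending run (positions 20-25)

    @settings(max_examples=20, deadline=None)
    @given(
        peak=st.floats(1.0, 80.0),
        length=st.integers(6, 30),
        plateau=st.integers(0, 6),
    )
    def test_memoryless_tracker_never_shows_hysteresis(self, peak, length, plateau):
        p = build_protocol(
            theta_peak=peak,
            forward_length=length,
            plateau_length=plateau,
            n_cycles=2,
            baseline_length=0,
        )
        table = hysteresis_table(_tracker_trials(p, lambda th: th.copy()), p)
        assert np.allclose(table["difference"], 0.0, atol=1e-12)

    def test_mh_cohort_shows_lag_hysteresis(self):
        # partially equilibrating learners lag the sweep: forward means fall
        # below the mirrored backward means on ascent, above on descent
        from fluctlearn import simulate_cohort

        p = build_protocol(theta_peak=30.0)
        cfg = LearnerConfig(proposal_scale=5.0, steps_per_trial=40)
        runs = simulate_cohort(
            p, cfg, n_participants=10, beta_range=(6.0, 9.0), support_halfwidth=45.0, seed=42
        )
        pooled = pd.concat(
            [trials_from_run(p, traj) for _, _, traj in runs], ignore_index=True
        )
        pooled["participant_id"] = "pooled"
        d = hysteresis_table(pooled, p)["difference"].to_numpy()
        assert d[0:5].mean() < 0   # forward trails below on the first ascent
        assert d[8:17].mean() > 0  # and above on the descent
        assert d[20:25].mean() < 0
        assert np.any(np.abs(d) > 0.5)


class TestAdaptation:
    def test_perfect_none_and_half_adaptation(self):
        p = build_protocol(n_cycles=2, baseline_length=10)
        full = adaptation_fraction(_tracker_trials(p, lambda th: th.copy()), p)
        none = adaptation_fraction(_tracker_trials(p, lambda th: np.zeros_like(th)), p)
        half = adaptation_fraction(_tracker_trials(p, lambda th: 0.5 * th), p)
        assert full == pytest.approx(1.0, abs=1e-12)
        assert none == pytest.approx(0.0, abs=1e-12)
        assert half == pytest.approx(0.5, abs=1e-12)
        assert half >= 0.5  # the well-adapted criterion is inclusive

    def test_invariant_under_joint_shift_of_bias(self):
        p = build_protocol(n_cycles=2, baseline_length=10)
        df = _tracker_trials(p, lambda th: 0.7 * th)
        shifted = df.copy()
        shifted["response_deg"] += 6.0
        shifted["theta_deg"] += 6.0
        a = adaptation_fraction(df, p)
        b = adaptation_fraction(shifted, p)
        assert b == pytest.approx(a, abs=1e-9)

    def test_flat_protocol_is_undefined(self):
        p = build_protocol(theta_peak=0.0, n_cycles=2, baseline_length=10)
        with pytest.raises(DegenerateDataError):
            adaptation_fraction(_tracker_trials(p, lambda th: th.copy()), p)


class TestRandomizedControl:
    def test_resamples_from_own_responses_only(self):
        p = build_protocol(n_cycles=2, baseline_length=10)
        df = pd.concat(
            [
                _tracker_trials(p, lambda th: th + 1.0, pid="A"),
                _tracker_trials(p, lambda th: th - 1.0, pid="B"),
            ],
            ignore_index=True,
        )
        out = randomized_control(df, seed=0)
        for pid in ("A", "B"):
            orig = set(df.loc[(df.participant_id == pid) & (df.block == "main"), "response_deg"])
            new = out.loc[(out.participant_id == pid) & (out.block == "main"), "response_deg"]
            assert set(new) <= orig
            assert len(new) == (df.participant_id == pid).sum() - 10
        # theta sequence and baseline untouched
        assert np.array_equal(out["theta_deg"], df["theta_deg"])
        base = df["block"] == "baseline"
        assert np.array_equal(out.loc[base, "response_deg"], df.loc[base, "response_deg"])

    def test_seed_reproducibility(self):
        p = build_protocol(n_cycles=2, baseline_length=10)
        df = _tracker_trials(p, lambda th: th.copy())
        a = randomized_control(df, seed=5)
        b = randomized_control(df, seed=5)
        assert a.equals(b)
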