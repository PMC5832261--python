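"""Pacing-law contracts: exact formulas, seeding, timing consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from restidyn.pacing import (InvalidProtocolError, PacingSchedule,
                             alternating_schedule, constant_schedule,
                             drop_beat, periodic_schedule, random_schedule,
                             switch_schedule)


def test_constant_schedule_times_and_degenerate_equivalences():
    sched = constant_schedule(350.0, 3)
    assert sched.stim_time == pytest.approx([350.0, 700.0, 1050.0])
    assert constant_schedule(350.0, 1).n_beats == 1
    per0 = periodic_schedule(350.0, 0.0, 2.4, 5)
    assert per0.cl == pytest.approx(constant_schedule(350.0, 5).cl)
    rnd0 = random_schedule(350.0, 0.0, 5, seed=1)
    assert rnd0.cl == pytest.approx(constant_schedule(350.0, 5).cl)
    assert alternating_schedule(350.0, 0.0, 5).cl == pytest.approx(
        constant_schedule(350.0, 5).cl)


def test_periodic_law_exact_values():
    sched = periodic_schedule(350.0, 35.0, 2.4, 10)
    n = np.arange(1, 11)
    assert sched.cl == pytest.approx(350.0 + 35.0 * np.sin(2.4 * n))
    # first cycle evaluates to 350 + 35*sin(2.4)
    assert sched.cl[0] == pytest.approx(373.6412, abs=1e-3)
    # integer-period sinusoid repeats exactly
    per = periodic_schedule(400.0, 40.0, 2.0 * np.pi / 8.0, 32)
    assert per.cl[:8] == pytest.approx(per.cl[8:16])


def test_alternating_law_exact_values():
    sched = alternating_schedule(350.0, 35.0, 4)
    assert sched.cl == pytest.approx([315.0, 385.0, 315.0, 385.0])


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_random_schedule_bounds_and_determinism(seed):
    s1 = random_schedule(350.0, 35.0, 200, seed)
    s2 = random_schedule(350.0, 35.0, 200, seed)
    assert np.array_equal(s1.cl, s2.cl)
    assert np.all((s1.cl >= 315.0) & (s1.cl <= 385.0))
    assert s1.stim_time == pytest.approx(np.cumsum(s1.cl))


def test_random_schedule_is_uniform():
    sched = random_schedule(350.0, 35.0, 10_000, seed=42)
    assert np.mean(sched.cl) == pytest.approx(350.0, abs=1.0)
    stat = kstest(sched.cl, "uniform", args=(315.0, 70.0))
    assert stat.pvalue > 0.01


@given(st.floats(100, 1000), st.floats(0, 99), st.integers(1, 50))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_cycle_time_consistency_across_laws(cl_star, clv, n):
    """t(N) - t(N-1) equals CL(N) exactly for every law."""
    clv = min(clv, 0.9 * cl_star)
    for sched in (periodic_schedule(cl_star, clv, 1.3, n),
                  random_schedule(cl_star, clv, n, 7),
                  alternating_schedule(cl_star, clv, n)):
        t = sched.stim_time
        assert np.diff(np.concatenate([[0.0], t])) == pytest.approx(sched.cl)


def test_invalid_protocols_rejected():
    with pytest.raises(InvalidProtocolError):
        random_schedule(350.0, 350.0, 10, 0)
    with pytest.raises(InvalidProtocolError):
        periodic_schedule(350.0, 400.0, 2.4, 10)
    with pytest.raises(InvalidProtocolError):
        constant_schedule(-10.0, 5)
    with pytest.raises(InvalidProtocolError):
        periodic_schedule(350.0, 35.0, -1.0, 10)


def test_drop_beat_semantics():
    sched = constant_schedule(350.0, 20)
    dropped = drop_beat(sched, 10)
    assert not dropped.stim_enabled[9]
    assert dropped.stim_time == pytest.approx(sched.stim_time)
    # inter-stimulus gap doubles around the withheld beat
    enabled_times = np.concatenate(
        [[0.0], dropped.stim_time])[:-1][dropped.stim_enabled]
    gaps = np.diff(enabled_times)
    assert np.max(gaps) == pytest.approx(700.0)
    # idempotent; re-enabling restores the original
    assert np.array_equal(drop_beat(dropped, 10).stim_enabled,
                          dropped.stim_enabled)
    restored = dropped.copy()
    restored.stim_enabled[9] = True
    assert np.array_equal(restored.stim_enabled, sched.stim_enabled)
    with pytest.raises(IndexError):
        drop_beat(sched, 21)


def test_switch_schedule_concatenation():
    dyn = periodic_schedule(350.0, 35.0, 2.4, 50)
    sched = switch_schedule((350.0, 17_000.0), dyn)
    assert sched.meta["constant_beats"] == 48     # floor(17000/350)
    assert sched.meta["switch_beat"] == 49
    assert sched.n_beats == 98
    assert np.all(sched.cl[:48] == 350.0)
    assert sched.cl[48:] == pytest.approx(dyn.cl)
    # degenerate dynamic part is indistinguishable from one constant run
    flat = switch_schedule((350.0, 3500.0), constant_schedule(350.0, 5))
    assert np.all(flat.cl == 350.0)


def test_schedule_roundtrips(tmp_path):
    sched = random_schedule(350.0, 35.0, 30, seed=9)
    path = tmp_path / "sched.csv"
    sched.to_csv(path)
    back = PacingSchedule.from_csv(path, meta=dict(sched.meta))
    assert back.cl == pytest.approx(sched.cl)
    back2 = PacingSchedule.from_json(sched.to_json())
    assert np.array_equal(back2.cl, sched.cl)
    assert back2.meta["seed"] == 9
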