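"""Goal decoding from spike phases: CV accuracy, permutation null, variants."""

import numpy as np
import pandas as pd
import pytest

from phasecode import LfpChannel
from phasecode import synthetic as syn
from phasecode.decoding import (
    LabeledPhaseSet,
    UndecodableError,
    bout_prevalence_by_goal,
    build_labeled_set,
    control_correlations,
    decode_by_period,
    decode_goal,
    hfa_events,
    hfa_phase_decoding,
    permutation_test,
)
from phasecode.io_sessions import SpikeTrain, TrialEvents
from phasecode.modal import BandDefinition, OscillationTrace


def make_set(phases, labels, period="all"):
    phases = np.asarray(phases, float)
    return LabeledPhaseSet(
        unit_id="u",
        band=(2.0, 4.0),
        phases=phases,
        labels=np.asarray(labels),
        times=np.arange(phases.size, dtype=float),
        period=period,
    )


def make_trace(phase, valid=None, fs=1000.0):
    phase = np.asarray(phase, float)
    valid = np.ones(phase.size, bool) if valid is None else valid
    return OscillationTrace(
        band=BandDefinition("c", 2.0, 4.0),
        phase=phase,
        inst_freq=np.full(phase.size, 3.0),
        valid=valid,
        fs=fs,
    )


def two_delivery_events():
    return TrialEvents(
        pd.DataFrame(
            {
                "delivery_id": [0, 1],
                "goal_id": [3, 5],
                "t_start_s": [0.0, 10.0],
                "t_end_s": [10.0, 20.0],
            }
        )
    )


# -- labeled sets ------------------------------------------------------------


def test_midpoint_split_is_half_open():
    """Spike at 4.9 s of a [0,10) delivery is planning; at 5.0 arrival."""
    trace = make_trace(np.zeros(20_000))
    ev = two_delivery_events()
    unit = SpikeTrain("u", "c", "H", np.array([4.9, 5.0, 12.0, 19.0]))
    planning = build_labeled_set(unit, trace, ev, period="planning")
    arrival = build_labeled_set(unit, trace, ev, period="arrival")
    assert planning.times.tolist() == [4.9, 12.0]
    assert arrival.times.tolist() == [5.0, 19.0]
    assert planning.labels.tolist() == [3, 5]


def test_all_spikes_invalid_is_undecodable():
    trace = make_trace(np.zeros(20_000), valid=np.zeros(20_000, bool))
    unit = SpikeTrain("u", "c", "H", np.array([1.0, 11.0]))
    with pytest.raises(UndecodableError):
        build_labeled_set(unit, trace, two_delivery_events())


def test_features_lie_on_unit_circle():
    s = make_set(np.random.default_rng(0).uniform(-np.pi, np.pi, 50), [1, 2] * 25)
    np.testing.assert_allclose((s.features**2).sum(axis=1), 1.0, atol=1e-12)


# -- decoding ----------------------------------------------------------------


def test_separable_phases_decode_perfectly():
    """Two goals at opposite phases are linearly separable in (sin, cos)."""
    rng = np.random.default_rng(1)
    phases = np.where(np.arange(200) % 2 == 0, 0.0, np.pi) + 0.05 * rng.standard_normal(200)
    labels = np.where(np.arange(200) % 2 == 0, 1, 4)
    assert decode_goal(make_set(phases, labels)) >= 0.99


def test_chance_level_for_random_labels():
    """Uniform phases + random labels: accuracy ~ 1/n_goals."""
    rng = np.random.default_rng(2)
    accs = [
        decode_goal(
            make_set(rng.uniform(-np.pi, np.pi, 600), rng.integers(1, 7, 600)), seed=i
        )
        for i in range(40)
    ]
    assert np.mean(accs) == pytest.approx(1 / 6, abs=0.03)


def test_goal_specific_phases_beat_chance():
    rng = np.random.default_rng(3)
    labels = rng.integers(1, 7, 600)
    phases = rng.vonmises((labels - 1) * np.pi / 3, 4.0)
    assert decode_goal(make_set(phases, labels)) >= 2 / 6


def test_single_goal_undecodable():
    with pytest.raises(UndecodableError):
        decode_goal(make_set(np.zeros(50), np.ones(50, int)))


def test_accuracy_invariant_to_global_phase_rotation():
    rng = np.random.default_rng(4)
    labels = rng.integers(1, 7, 500)
    phases = rng.vonmises((labels - 1) * np.pi / 3, 2.0)
    a1 = decode_goal(make_set(phases, labels))
    a2 = decode_goal(make_set(np.angle(np.exp(1j * (phases + 1.1))), labels))
    assert a1 == pytest.approx(a2, abs=0.02)


# -- permutation test --------------------------------------------------------


def test_permutation_p_for_strong_coder():
    """A clear phase coder beats every label rotation."""
    rng = np.random.default_rng(5)
    labels = rng.integers(1, 7, 400)
    phases = rng.vonmises((labels - 1) * np.pi / 3, 4.0)
    res = permutation_test(make_set(phases, labels), n_perm=99, seed=0)
    assert res.p_value == pytest.approx(1 / 100)
    assert res.null_accuracies.size == 99


def test_degenerate_ranking_gives_p_one():
    """If the observed accuracy ties every null accuracy, p = 1."""
    # phases carry no information and labels are perfectly balanced blocks:
    # every rotation yields the same majority-vote accuracy
    phases = np.zeros(60)
    labels = np.repeat([1, 2], 30)
    res = permutation_test(make_set(phases, labels), n_perm=50, seed=1)
    assert res.p_value == 1.0


def test_rotation_preserves_goal_counts():
    rng = np.random.default_rng(6)
    labels = rng.integers(1, 7, 300)
    s = make_set(rng.uniform(-np.pi, np.pi, 300), labels)
    res = permutation_test(s, n_perm=10, seed=2)
    assert res.goal_counts == {int(g): int(c) for g, c in zip(*np.unique(labels, return_counts=True))}


def test_n_perm_validated():
    with pytest.raises(ValueError):
        permutation_test(make_set(np.zeros(20), [1, 2] * 10), n_perm=0)


# -- period variants ---------------------------------------------------------


def _period_session(seed, period):
    """Session whose single unit phase-codes only during one task period."""
    mus = {g: (g - 1) * np.pi / 3 for g in range(1, 7)}
    spec = syn.SyntheticSpec(
        duration=400.0,
        fs=500.0,
        seed=seed,
        n_deliveries=50,
        bands=[syn.BandSpec()],
        units=[
            syn.UnitSpec(
                unit_id="u", base_rate=2.0, kappa=4.0,
                preferred_phase_by_goal=mus, modulate_period=period,
            )
        ],
    )
    session, gt = syn.generate_session(spec)
    # decode against the ground-truth phase trace (unit test isolates the
    # decoding stage; the full pipeline is exercised elsewhere)
    n = int(400.0 * 500.0)
    trace = OscillationTrace(
        band=BandDefinition("c", 2.5, 3.5),
        phase=gt.phase[0],
        inst_freq=gt.inst_freq[0],
        valid=np.ones(n, bool),
        fs=500.0,
    )
    return session.units[0], trace, session.events


def test_planning_only_coder_is_period_specific():
    unit, trace, events = _period_session(seed=7, period="planning")
    out = decode_by_period(unit, trace, events, n_perm=99, seed=0)
    assert out["planning"].p_value < 0.05
    assert out["arrival"].p_value > 0.05


def test_arrival_only_coder_flips():
    unit, trace, events = _period_session(seed=8, period="arrival")
    out = decode_by_period(unit, trace, events, n_perm=99, seed=0)
    assert out["arrival"].p_value < 0.05
    assert out["planning"].p_value > 0.05


def test_failed_period_does_not_abort_other():
    """No decodable arrival spikes: arrival gets an error marker, planning
    still returns a result."""
    trace = make_trace(np.tile(np.linspace(-np.pi, np.pi, 100), 200))
    ev = two_delivery_events()
    rng = np.random.default_rng(9)
    planning_spikes = np.sort(
        np.concatenate([rng.uniform(0, 5, 60), rng.uniform(10, 15, 60)])
    )
    unit = SpikeTrain("u", "c", "H", planning_spikes)
    out = decode_by_period(unit, trace, ev, n_perm=20, seed=0)
    assert isinstance(out["arrival"], str) and "undecodable" in out["arrival"]
    assert not isinstance(out["planning"], str)


# -- HFA variant -------------------------------------------------------------


def test_hfa_burst_detected_at_injection_time():
    fs = 2000.0
    rng = np.random.default_rng(10)
    x = rng.standard_normal(int(60 * fs))
    t = np.arange(int(0.1 * fs)) / fs
    x[int(30 * fs) : int(30.1 * fs)] += 8.0 * np.sin(2 * np.pi * 80 * t)
    events = hfa_events(LfpChannel("c", "H", fs, x))
    near = events[np.abs(events - 30.05) < 0.05]
    assert near.size >= 1


def test_hfa_no_events_on_constant_signal():
    lfp = LfpChannel("c", "H", 2000.0, np.zeros(int(10 * 2000)) + 1.0)
    assert hfa_events(lfp).size == 0


def test_hfa_noise_produces_some_events():
    rng = np.random.default_rng(11)
    lfp = LfpChannel("c", "H", 2000.0, rng.standard_normal(int(30 * 2000)))
    assert hfa_events(lfp).size > 0


def test_hfa_low_fs_rejected():
    with pytest.raises(ValueError, match="too low"):
        hfa_events(LfpChannel("c", "H", 200.0, np.zeros(2000)))


def test_hfa_phase_decoding_contract():
    """Goal-dependent event phases decode; zero events are undecodable."""
    rng = np.random.default_rng(12)
    n = 200_000
    fs = 1000.0
    phase = np.angle(np.exp(1j * 2 * np.pi * 3.0 * np.arange(n) / fs))
    trace = make_trace(phase, fs=fs)
    edges = np.linspace(0, n / fs, 41)
    ev = TrialEvents(
        pd.DataFrame(
            {
                "delivery_id": np.arange(40),
                "goal_id": (np.arange(40) % 6) + 1,
                "t_start_s": edges[:-1],
                "t_end_s": edges[1:],
            }
        )
    )
    goal_of_t = ev.goal_at(np.arange(n) / fs)
    mu = (goal_of_t - 1) * np.pi / 3
    w = np.exp(4.0 * np.cos(phase - mu)) * (goal_of_t > 0)
    idx = rng.choice(n, size=500, replace=False, p=w / w.sum())
    times = np.unique(np.sort(idx)) / fs
    res = hfa_phase_decoding(times, trace, ev, n_perm=99, seed=0)
    assert res.p_value < 0.05
    with pytest.raises(UndecodableError):
        hfa_phase_decoding(np.array([]), trace, ev)


# -- controls ----------------------------------------------------------------


def test_control_correlation_forced_identity():
    acc = np.linspace(0.1, 0.5, 20)
    out = control_correlations(acc, np.linspace(0, 1, 20), acc.copy())
    assert out["rho_accuracy_vs_bandwidth"] == pytest.approx(1.0)


def test_control_correlation_null_is_weak():
    rng = np.random.default_rng(13)
    out = control_correlations(
        rng.uniform(0.1, 0.3, 100), rng.uniform(0, 1, 100), rng.uniform(0.5, 3.0, 100)
    )
    assert abs(out["rho_accuracy_vs_bandwidth"]) < 0.2
    assert out["p_accuracy_vs_bandwidth"] > 0.05


def test_control_correlation_constant_regressor_flagged():
    rng = np.random.default_rng(14)
    out = control_correlations(rng.uniform(0, 1, 10), np.full(10, 0.5), rng.uniform(0, 1, 10))
    assert out["constant_prevalence"] and np.isnan(out["rho_accuracy_vs_prevalence"])


def test_control_correlation_too_few_units():
    with pytest.raises(ValueError, match="too few"):
        control_correlations(np.zeros(4), np.zeros(4), np.zeros(4))


# -- bout prevalence by goal -------------------------------------------------


def test_goal_locked_bouts_are_detected():
    """Oscillation valid only during goal-1 deliveries: p at the floor."""
    ev = syn.generate_task(60, 5.0, seed=15)
    n = int(300 * 100)
    t = np.arange(n) / 100.0
    valid = ev.goal_at(t) == 1
    trace = make_trace(np.zeros(n), valid=valid, fs=100.0)
    chi2, p = bout_prevalence_by_goal(trace, ev, n_shuffles=100, seed=0)
    assert p <= 1 / 101 + 1e-12


def test_goal_independent_bouts_not_significant():
    rng = np.random.default_rng(16)
    ev = syn.generate_task(60, 5.0, seed=17)
    n = int(300 * 100)
    valid = rng.random(n) < 0.5
    trace = make_trace(np.zeros(n), valid=valid, fs=100.0)
    _, p = bout_prevalence_by_goal(trace, ev, n_shuffles=100, seed=1)
    assert p > 0.05


def test_single_goal_rejected():
    ev = TrialEvents(
        pd.DataFrame(
            {"delivery_id": [0, 1], "goal_id": [2, 2], "t_start_s": [0.0, 5.0], "t_end_s": [5.0, 10.0]}
        )
    )
    trace = make_trace(np.zeros(1000), fs=100.0)
    with pytest.raises(ValueError, match="goals"):
        bout_prevalence_by_goal(trace, ev)
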