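"""Synthetic LFP / spike-train generator with known ground truth.

Emulates the signal regime the analysis stack targets: a 1/f^chi Gaussian
background with narrowband oscillatory bouts embedded at configurable
frequencies, high-amplitude artifact transients, a goal-delivery task
schedule, and Poisson spike trains whose intensity is von Mises-modulated by
oscillation phase with goal-dependent preferred phases (phase coding),
goal-dependent rates (rate coding), or neither (null cells).

The generative model per unit is an inhomogeneous Poisson process

    lambda(t) = lam0 * g(goal(t)) * exp(kappa * cos(phi(t) - mu_goal(t))) / I0(kappa)

during oscillatory bouts (``phi`` is the true injected phase) and
``lam0 * g(goal(t))`` outside bouts, sampled by thinning.  Outside delivery
intervals the goal is undefined and the unit fires at its base rate.

Everything is deterministic given the spec seed; the ground-truth object
records the exact phase series, bout and artifact intervals, and unit
parameters so downstream estimates can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import Generator
from scipy.special import i0

from .io_sessions import LfpChannel, Session, SpikeTrain, TrialEvents

__all__ = [
    "BandSpec",
    "ArtifactSpec",
    "UnitSpec",
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "generate_task",
    "generate_lfp",
    "generate_spikes",
    "generate_session",
]


@dataclass
class BandSpec:
    """One injected narrowband oscillation.

    amplitude is the RMS of the oscillation during bouts relative to the RMS
    of the 1/f background within [f_center - f_halfwidth, f_center +
    f_halfwidth]; bout_duty_cycle is the long-run fraction of time the
    oscillation is on (bouts alternate with gaps, both exponential with
    mean_bout_dur and the gap mean implied by the duty cycle).
    """

    f_center: float = 3.0
    f_halfwidth: float = 0.5
    amplitude: float = 2.0
    bout_duty_cycle: float = 1.0
    mean_bout_dur: float = 10.0


@dataclass
class ArtifactSpec:
    """A raised-cosine transient at time t (s), duration dur (s), peak
    amplitude gain x the artifact-free signal SD."""

    t: float
    dur: float = 0.2
    gain: float = 10.0


@dataclass
class UnitSpec:
    """Generative parameters of one synthetic unit.

    kappa = 0 with all gains 1 is a null cell; equal preferred phases across
    goals give pure phase locking; goal-dependent preferred phases give
    phase coding; goal-dependent gains give rate coding.
    ``modulate_period`` restricts the phase modulation to the first
    ("planning") or second ("arrival") half of each delivery; None applies
    it throughout.
    """

    unit_id: str = "u1"
    base_rate: float = 5.0
    kappa: float = 0.0
    preferred_phase_by_goal: dict[int, float] = field(default_factory=dict)
    rate_gain_by_goal: dict[int, float] = field(default_factory=dict)
    band_index: int = 0
    modulate_period: str | None = None  # None | "planning" | "arrival"

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if any(g <= 0 for g in self.rate_gain_by_goal.values()):
            raise ValueError("rate gains must be > 0")
        if self.modulate_period not in (None, "planning", "arrival"):
            raise ValueError("modulate_period must be None, 'planning' or 'arrival'")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic session channel."""

    duration: float = 60.0
    fs: float = 2000.0
    one_over_f_exponent: float = 1.0
    bands: list[BandSpec] = field(default_factory=list)
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    n_deliveries: int = 73
    mean_delivery_dur: float | None = None  # None: deliveries tile the session
    units: list[UnitSpec] = field(default_factory=list)
    seed: int = 0
    channel_id: str = "ch1"
    region: str = "Hipp"

    def __post_init__(self) -> None:
        nyq = self.fs / 2
        for b in self.bands:
            if not (0 < b.f_center - b.f_halfwidth and b.f_center + b.f_halfwidth < nyq):
                raise ValueError(
                    f"band out of range: {b.f_center}+-{b.f_halfwidth} Hz vs Nyquist {nyq} Hz"
                )
            if not 0 <= b.bout_duty_cycle <= 1:
                raise ValueError("bout_duty_cycle must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that an analysis should recover."""

    fs: float
    t0: float
    duration: float
    band_edges: list[tuple[float, float]]
    bout_intervals: list[list[tuple[float, float]]]  # per band
    artifact_intervals: list[tuple[float, float]]
    phase: list[np.ndarray]  # per band, full-session true phase, radians
    inst_freq: list[np.ndarray]  # per band, full-session true frequency, Hz
    units: list[UnitSpec] = field(default_factory=list)

    def phase_at(self, band_index: int, t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.rint((np.asarray(t) - self.t0) * self.fs).astype(int), 0, len(self.phase[band_index]) - 1)
        return self.phase[band_index][idx]

    def in_bout(self, band_index: int, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.bout_intervals[band_index]:
            out |= (t >= lo) & (t < hi)
        return out


# ---------------------------------------------------------------------------
# task schedule


def generate_task(
    n_deliveries: int,
    mean_dur: float,
    seed: int | Generator,
    t0: float = 0.0,
    n_goals: int = 6,
) -> TrialEvents:
    """Goal-delivery schedule tiling ``[t0, t0 + n*mean_dur)``.

    Delivery durations are gamma-distributed (shape 4) and rescaled so the
    deliveries exactly tile the requested span; goals are uniform on
    ``1..n_goals`` excluding immediate repeats (a new destination is always
    assigned on arrival).
    """
    if n_deliveries < 1:
        raise ValueError("no goal schedule: n_deliveries must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, Generator) else seed
    durs = rng.gamma(shape=4.0, scale=mean_dur / 4.0, size=n_deliveries)
    durs *= (n_deliveries * mean_dur) / durs.sum()
    edges = t0 + np.concatenate([[0.0], np.cumsum(durs)])
    goals = np.empty(n_deliveries, dtype=int)
    goals[0] = rng.integers(1, n_goals + 1)
    for i in range(1, n_deliveries):
        g = rng.integers(1, n_goals)  # n_goals - 1 choices
        goals[i] = g if g < goals[i - 1] else g + 1
    import pandas as pd

    return TrialEvents(
        pd.DataFrame(
            {
                "delivery_id": np.arange(n_deliveries),
                "goal_id": goals,
                "t_start_s": edges[:-1],
                "t_end_s": edges[1:],
            }
        )
    )


# ---------------------------------------------------------------------------
# LFP


def _one_over_f_noise(n: int, fs: float, exponent: float, rng: Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, unit SD."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _smooth_noise(n: int, fs: float, cutoff_hz: float, rng: Generator) -> np.ndarray:
    """Unit-SD Gaussian noise low-passed below ``cutoff_hz`` (FFT brick-wall)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[freqs > cutoff_hz] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _draw_bouts(
    duration: float, duty: float, mean_bout: float, rng: Generator
) -> list[tuple[float, float]]:
    """Alternating renewal process of exponential bouts and gaps."""
    if duty >= 1.0:
        return [(0.0, duration)]
    if duty <= 0.0:
        return []
    mean_gap = mean_bout * (1.0 - duty) / duty
    intervals: list[tuple[float, float]] = []
    t = 0.0
    in_bout = bool(rng.random() < duty)
    while t < duration:
        if in_bout:
            d = rng.exponential(mean_bout)
            intervals.append((t, min(t + d, duration)))
        else:
            d = rng.exponential(mean_gap)
        t += d
        in_bout = not in_bout
    return intervals


def _interval_mask(intervals: Sequence[tuple[float, float]], n: int, fs: float, t0: float = 0.0) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for lo, hi in intervals:
        i0_ = max(0, int(np.rint((lo - t0) * fs)))
        i1_ = min(n, int(np.rint((hi - t0) * fs)))
        mask[i0_:i1_] = True
    return mask


def generate_lfp(spec: SyntheticSpec) -> tuple[LfpChannel, SyntheticGroundTruth]:
    """Simulate one LFP channel plus the ground truth used to build it.

    The oscillation in each band is an amplitude-modulated sinusoid whose
    instantaneous frequency wanders slowly (smoothed Gaussian drive, hard
    clipped) inside ``f_center +- f_halfwidth``; it is gated on during bouts
    with 50 ms raised-cosine ramps.  Artifacts are raised-cosine transients
    scaled in units of the artifact-free signal SD.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    background = _one_over_f_noise(n, spec.fs, spec.one_over_f_exponent, rng)

    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    bg_spec = np.fft.rfft(background)

    signal = background.copy()
    band_edges: list[tuple[float, float]] = []
    bout_intervals: list[list[tuple[float, float]]] = []
    phases: list[np.ndarray] = []
    inst_freqs: list[np.ndarray] = []

    for band in spec.bands:
        f_lo = band.f_center - band.f_halfwidth
        f_hi = band.f_center + band.f_halfwidth
        band_edges.append((f_lo, f_hi))

        # frequency trajectory: slow wander clipped to the band
        wander = _smooth_noise(n, spec.fs, cutoff_hz=0.2, rng=rng)
        f_t = band.f_center + np.clip(wander * (band.f_halfwidth / 2.0), -band.f_halfwidth, band.f_halfwidth)
        phase = np.mod(2 * np.pi * np.cumsum(f_t) / spec.fs, 2 * np.pi)
        phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]

        # target RMS: amplitude ratio vs background RMS inside the band
        in_band = (freqs >= f_lo) & (freqs <= f_hi)
        bg_band = np.fft.irfft(np.where(in_band, bg_spec, 0.0), n=n)
        target_rms = band.amplitude * bg_band.std()
        amp_mod = 1.0 + 0.25 * _smooth_noise(n, spec.fs, cutoff_hz=0.5, rng=rng)
        amp_mod = np.clip(amp_mod, 0.2, None)

        bouts = _draw_bouts(spec.duration, band.bout_duty_cycle, band.mean_bout_dur, rng)
        bout_intervals.append(bouts)
        gate = _interval_mask(bouts, n, spec.fs).astype(float)
        ramp = max(3, int(round(0.05 * spec.fs)))
        win = np.hanning(2 * ramp + 1)
        gate = np.convolve(gate, win / win.sum(), mode="same")

        osc = amp_mod * np.cos(phase)
        rms0 = np.sqrt(np.mean(amp_mod**2) / 2.0)  # RMS of amp_mod * cos(phase)
        osc *= target_rms / rms0
        signal += osc * gate
        phases.append(phase)
        inst_freqs.append(f_t)

    sd = signal.std()
    artifact_intervals: list[tuple[float, float]] = []
    for art in spec.artifacts:
        i_start = int(np.rint(art.t * spec.fs))
        width = max(3, int(np.rint(art.dur * spec.fs)))
        i_end = min(n, i_start + width)
        if i_start >= n or i_end <= 0:
            continue
        bump = art.gain * sd * np.hanning(width)[: i_end - max(i_start, 0)]
        signal[max(i_start, 0) : i_end] += bump
        artifact_intervals.append((i_start / spec.fs, i_end / spec.fs))

    lfp = LfpChannel(
        channel_id=spec.channel_id,
        region=spec.region,
        fs=spec.fs,
        samples=signal,
        t0=0.0,
    )
    gt = SyntheticGroundTruth(
        fs=spec.fs,
        t0=0.0,
        duration=spec.duration,
        band_edges=band_edges,
        bout_intervals=bout_intervals,
        artifact_intervals=artifact_intervals,
        phase=phases,
        inst_freq=inst_freqs,
        units=list(spec.units),
    )
    return lfp, gt


# ---------------------------------------------------------------------------
# spikes


def generate_spikes(
    lfp_gt: SyntheticGroundTruth,
    unit: UnitSpec,
    events: TrialEvents,
    seed: int | Generator,
) -> SpikeTrain:
    """Sample one unit's spike train by thinning an inhomogeneous Poisson
    process driven by goal identity and (during bouts) oscillation phase."""
    if len(events) == 0:
        raise ValueError("no goal schedule: events table is empty")
    if unit.kappa > 0 and not (0 <= unit.band_index < len(lfp_gt.phase)):
        raise ValueError(f"band_index {unit.band_index} not present in ground truth")
    rng = np.random.default_rng(seed) if not isinstance(seed, Generator) else seed

    gains = np.ones(7)
    for g, v in unit.rate_gain_by_goal.items():
        gains[g] = v
    max_gain = gains.max()
    vm_max = np.exp(unit.kappa) / i0(unit.kappa) if unit.kappa > 0 else 1.0
    lam_max = unit.base_rate * max_gain * vm_max

    t_lo, t_hi = lfp_gt.t0, lfp_gt.t0 + lfp_gt.duration
    n_cand = rng.poisson(lam_max * (t_hi - t_lo))
    cand = np.sort(rng.uniform(t_lo, t_hi, size=n_cand))

    goal = events.goal_at(cand)
    lam = unit.base_rate * np.where(goal > 0, gains[np.clip(goal, 0, 6)], 1.0)

    if unit.kappa > 0:
        modulated = lfp_gt.in_bout(unit.band_index, cand) & (goal > 0)
        if unit.modulate_period is not None:
            dv = events.deliveries
            mid = np.full(cand.shape, np.nan)
            starts = dv["t_start_s"].to_numpy()
            ends = dv["t_end_s"].to_numpy()
            idx = np.searchsorted(starts, cand, side="right") - 1
            ok = (idx >= 0) & (goal > 0)
            mid[ok] = 0.5 * (starts[idx[ok]] + ends[idx[ok]])
            if unit.modulate_period == "planning":
                modulated &= cand < mid
            else:
                modulated &= cand >= mid
        mu = np.zeros(cand.shape)
        has_mu = np.zeros(cand.shape, dtype=bool)
        for g, m in unit.preferred_phase_by_goal.items():
            sel = goal == g
            mu[sel] = m
            has_mu[sel] = True
        modulated &= has_mu
        phi = lfp_gt.phase_at(unit.band_index, cand)
        vm = np.exp(unit.kappa * np.cos(phi - mu)) / i0(unit.kappa)
        lam = np.where(modulated, lam * vm, lam)

    keep = rng.uniform(0.0, lam_max, size=cand.size) < lam
    times = cand[keep]
    # strictly increasing: drop exact duplicates from the uniform draw
    if times.size > 1:
        times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(
        unit_id=unit.unit_id,
        channel_id="",  # caller assigns when assembling a Session
        region="",
        spike_times=times,
    )


def generate_session(spec: SyntheticSpec) -> tuple[Session, SyntheticGroundTruth]:
    """Assemble a full synthetic session: one channel, task events, all units."""
    lfp, gt = generate_lfp(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    mean_dur = spec.mean_delivery_dur or spec.duration / spec.n_deliveries
    events = generate_task(spec.n_deliveries, mean_dur, rng)
    units = []
    for i, u in enumerate(spec.units):
        st = generate_spikes(gt, u, events, np.random.default_rng(spec.seed * 97 + 7919 * (i + 1)))
        st.channel_id = spec.channel_id
        st.region = spec.region
        units.append(st)
    session = Session(
        channels=[lfp],
        units=units,
        events=events,
        metadata={"synthetic": True, "seed": spec.seed},
    )
    return session, gt
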