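"""Cross-validated decoding of navigational goal from spike phases.

Phase *coding* — as opposed to mere phase locking — means the phase at
which a neuron fires depends on the behavioral context (here, which of six
goal stores the subject is driving to).  It is assessed by predicting the
goal label of each spike from the oscillation phase at that spike:

* features are ``(sin phi, cos phi)`` so the circular variable lives on a
  plane where a linear decoder is meaningful;
* the decoder is multinomial logistic regression (L2, fixed strength) with
  stratified five-fold cross-validation, accuracy pooled over held-out
  folds;
* chance level varies across cells with the spike-count distribution over
  goals, so significance comes from a permutation test: the chronologically
  ordered per-spike label vector is circularly rotated by a random offset
  (preserving temporal structure and exact class counts), the full CV
  decode is re-run per rotation, and the p-value is the add-one rank of
  the observed accuracy in the null distribution.

Variants restrict spikes to the planning (first) or arrival (second) half
of each delivery, or substitute high-frequency-activity (HFA, 65-120 Hz)
power events for spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import butter, hilbert, sosfiltfilt
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .artifact_rejection import EpochMask
from .io_sessions import LfpChannel, SpikeTrain, TrialEvents
from .modal import OscillationTrace

__all__ = [
    "UndecodableError",
    "LabeledPhaseSet",
    "DecodeResult",
    "build_labeled_set",
    "decode_goal",
    "permutation_test",
    "decode_by_period",
    "hfa_events",
    "hfa_phase_decoding",
    "control_correlations",
    "bout_prevalence_by_goal",
]


class UndecodableError(ValueError):
    """The labeled set cannot support decoding (e.g. fewer than 2 goals)."""


@dataclass
class LabeledPhaseSet:
    """Per-spike (sin, cos) phase features with goal labels, in spike order."""

    unit_id: str
    band: tuple[float, float]
    phases: np.ndarray  # radians, chronological
    labels: np.ndarray  # goal ids
    times: np.ndarray  # spike times, s
    period: str = "all"  # all | planning | arrival

    @property
    def n(self) -> int:
        return self.phases.size

    @property
    def features(self) -> np.ndarray:
        return np.column_stack([np.sin(self.phases), np.cos(self.phases)])

    def goal_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class DecodeResult:
    unit_id: str
    band: tuple[float, float]
    period: str
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_spikes: int
    goal_counts: dict[int, int] = field(default_factory=dict)


def build_labeled_set(
    unit: SpikeTrain,
    trace: OscillationTrace,
    events: TrialEvents,
    period: str = "all",
) -> LabeledPhaseSet:
    """Label each spike with its delivery's goal; drop unusable spikes.

    Spikes outside any delivery or falling on invalid oscillation samples
    are excluded.  ``period`` keeps only the first (``planning``) or second
    (``arrival``) half of each delivery, split at the midpoint with
    half-open ``[start, mid)`` / ``[mid, end)`` windows.
    """
    if period not in ("all", "planning", "arrival"):
        raise ValueError(f"unknown period {period!r}")
    t = unit.spike_times
    goal = events.goal_at(t)
    keep = goal > 0
    if period != "all":
        dv = events.deliveries
        starts = dv["t_start_s"].to_numpy()
        ends = dv["t_end_s"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        mid = np.full(t.shape, np.nan)
        ok = idx >= 0
        mid[ok] = 0.5 * (starts[idx[ok]] + ends[idx[ok]])
        keep &= (t < mid) if period == "planning" else (t >= mid)
    sidx = trace.index_at(t)
    keep &= trace.valid[sidx]
    phases = trace.phase[sidx[keep]]
    labels = goal[keep]
    if np.unique(labels).size < 2:
        raise UndecodableError(
            "undecodable label set: fewer than 2 goals with surviving spikes"
        )
    return LabeledPhaseSet(
        unit_id=unit.unit_id,
        band=(trace.band.f_lo, trace.band.f_hi),
        phases=phases,
        labels=labels,
        times=t[keep],
        period=period,
    )


def _make_classifier() -> LogisticRegression:
    # fixed L2 strength for reproducibility; lbfgs handles multinomial loss
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, k_folds: int, seed: int) -> float:
    """Pooled held-out accuracy of the linear decoder.

    Folds are stratified by goal when every class has at least ``k_folds``
    members; otherwise plain chronological folds are used.
    """
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k_folds:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k_folds)
    correct = 0
    for train, test in splitter.split(X, y):
        if np.unique(y[train]).size < 2:
            continue  # degenerate fold: no decodable training set
        clf = _make_classifier()
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / y.size


def decode_goal(labeled: LabeledPhaseSet, k_folds: int = 5, seed: int = 0) -> float:
    """Cross-validated accuracy of goal prediction from spike phase."""
    if np.unique(labeled.labels).size < 2:
        raise UndecodableError("undecodable: single goal")
    if labeled.n < k_folds:
        raise UndecodableError(f"undecodable: fewer than {k_folds} spikes")
    return _cv_accuracy(labeled.features, labeled.labels, k_folds, seed)


def permutation_test(
    labeled: LabeledPhaseSet,
    n_perm: int = 500,
    k_folds: int = 5,
    seed: int = 0,
) -> DecodeResult:
    """Circular-shift permutation test of decoding accuracy.

    Each surrogate rotates the chronologically ordered label vector by a
    random offset in ``[1, n-1]`` — class counts and the labels' temporal
    autocorrelation are preserved exactly — and re-runs the full
    cross-validated decode.  ``p = (1 + #{null >= observed}) / (1 + n_perm)``
    (add-one rank rule, so p is never 0).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = labeled.features
    y = labeled.labels
    observed = decode_goal(labeled, k_folds=k_folds, seed=seed)
    null = np.empty(n_perm)
    for j in range(n_perm):
        offset = int(rng.integers(1, labeled.n))
        y_rot = np.roll(y, offset)
        null[j] = _cv_accuracy(X, y_rot, k_folds, seed)
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm)
    return DecodeResult(
        unit_id=labeled.unit_id,
        band=labeled.band,
        period=labeled.period,
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=p,
        n_spikes=labeled.n,
        goal_counts=labeled.goal_counts(),
    )


def decode_by_period(
    unit: SpikeTrain,
    trace: OscillationTrace,
    events: TrialEvents,
    n_perm: int = 500,
    k_folds: int = 5,
    seed: int = 0,
) -> dict[str, DecodeResult | str]:
    """Independent planning-period and arrival-period decodes.

    A period whose labeled set is undecodable yields its error message in
    place of a result without aborting the other period.
    """
    out: dict[str, DecodeResult | str] = {}
    for i, period in enumerate(("planning", "arrival")):
        try:
            labeled = build_labeled_set(unit, trace, events, period=period)
            out[period] = permutation_test(
                labeled, n_perm=n_perm, k_folds=k_folds, seed=seed + i
            )
        except UndecodableError as err:
            out[period] = str(err)
    return out


def hfa_events(
    lfp: LfpChannel,
    mask: EpochMask | None = None,
    band: tuple[float, float] = (65.0, 120.0),
    z_thresh: float = 1.96,
) -> np.ndarray:
    """Center times of high-frequency-activity power events.

    HFA power is the squared analytic-signal magnitude of the band-passed
    trace, z-scored over good samples; each maximal run of supra-threshold
    samples becomes one event at its temporal center.  Events inside bad
    epochs are discarded.
    """
    if lfp.fs <= 2 * band[1]:
        raise ValueError(f"fs={lfp.fs} too low for a {band} Hz band")
    bad = (
        mask.sample_mask(lfp.samples.size, lfp.fs, lfp.t0)
        if mask is not None
        else np.zeros(lfp.samples.size, dtype=bool)
    )
    x = lfp.samples - lfp.samples.mean()
    sos = butter(4, band, btype="band", fs=lfp.fs, output="sos")
    power = np.abs(hilbert(sosfiltfilt(sos, x))) ** 2
    good = ~bad
    mu, sd = power[good].mean(), power[good].std()
    if sd == 0:
        return np.empty(0)
    z = (power - mu) / sd
    supra = z > z_thresh
    edges = np.flatnonzero(np.diff(np.concatenate([[0], supra.astype(np.int8), [0]])))
    centers = []
    for s, e in zip(edges[::2], edges[1::2]):
        c = (s + e - 1) // 2
        if not bad[c]:
            centers.append(lfp.t0 + c / lfp.fs)
    return np.asarray(centers)


def hfa_phase_decoding(
    event_times: np.ndarray,
    trace: OscillationTrace,
    events: TrialEvents,
    channel_id: str = "",
    n_perm: int = 500,
    k_folds: int = 5,
    seed: int = 0,
) -> DecodeResult:
    """Goal decoding from low-frequency phase at HFA events.

    Each HFA event is treated as if it were an action potential; the
    contract is identical to ``build_labeled_set`` + ``permutation_test``.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise UndecodableError("undecodable: zero HFA events")
    pseudo = SpikeTrain(
        unit_id=f"hfa:{channel_id}",
        channel_id=channel_id,
        region="",
        spike_times=np.unique(event_times),
    )
    labeled = build_labeled_set(pseudo, trace, events, period="all")
    return permutation_test(labeled, n_perm=n_perm, k_folds=k_folds, seed=seed)


def control_correlations(
    accuracies: np.ndarray,
    oscillation_prevalence: np.ndarray,
    bandwidths: np.ndarray,
) -> dict[str, float]:
    """Spearman rank correlations of decoder accuracy against LFP features.

    Checks that decoding accuracy is not a byproduct of how often the
    oscillation was present (``prevalence`` = fraction of valid samples)
    or of band width.  A constant regressor yields ``nan`` rho with a flag.
    """
    acc = np.asarray(accuracies, dtype=float)
    prev = np.asarray(oscillation_prevalence, dtype=float)
    bw = np.asarray(bandwidths, dtype=float)
    if acc.size < 5 or prev.size != acc.size or bw.size != acc.size:
        raise ValueError("too few units: need >= 5 matched values")
    out: dict[str, float] = {}
    for name, x in (("prevalence", prev), ("bandwidth", bw)):
        if np.ptp(x) == 0 or np.ptp(acc) == 0:
            out[f"rho_accuracy_vs_{name}"] = np.nan
            out[f"p_accuracy_vs_{name}"] = np.nan
            out[f"constant_{name}"] = True
        else:
            rho, p = stats.spearmanr(acc, x)
            out[f"rho_accuracy_vs_{name}"] = float(rho)
            out[f"p_accuracy_vs_{name}"] = float(p)
            out[f"constant_{name}"] = False
    return out


def bout_prevalence_by_goal(
    trace: OscillationTrace,
    events: TrialEvents,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Does oscillation prevalence differ across goals?

    Builds the (valid, invalid) x goal contingency table of oscillation
    samples inside deliveries and compares its chi-square statistic to a
    surrogate distribution obtained by circularly rotating the
    delivery-level goal sequence (``n_shuffles`` rotations); p by add-one
    rank.  A significant result would mean apparent phase coding could
    ride on goal-dependent oscillation prevalence.
    """
    goals = events.goal_ids
    uniq = np.unique(goals)
    if uniq.size < 2:
        raise ValueError("need >= 2 goals")
    if not trace.valid.any():
        raise ValueError("empty trace: no valid samples")
    rng = np.random.default_rng(seed)

    # per-delivery valid/invalid sample counts
    n_dv = len(events)
    valid_counts = np.zeros(n_dv)
    total_counts = np.zeros(n_dv)
    for i, (_, _, t0, t1) in enumerate(events):
        i0 = trace.index_at(np.array([t0]))[0]
        i1 = trace.index_at(np.array([t1]))[0]
        seg = trace.valid[i0:i1]
        valid_counts[i] = seg.sum()
        total_counts[i] = seg.size

    def chi2_of(goal_seq: np.ndarray) -> float:
        table = np.zeros((2, uniq.size))
        for k, g in enumerate(uniq):
            sel = goal_seq == g
            table[0, k] = valid_counts[sel].sum()
            table[1, k] = total_counts[sel].sum() - valid_counts[sel].sum()
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            return 0.0
        chi2, _, _, _ = stats.chi2_contingency(table)
        return float(chi2)

    observed = chi2_of(goals)
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        null[j] = chi2_of(np.roll(goals, int(rng.integers(1, n_dv))))
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_shuffles)
    return observed, p
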