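"""Firing-rate and population-level statistics.

Each delivery is split at its midpoint into a planning half (driving
toward the goal) and an arrival half; per-half firing rates enter a
two-way fixed-effects ANOVA with factors goal (up to 6 levels) and task
period (2 levels) plus their interaction.  Rates rather than raw counts
are analyzed because half-durations are equal within but not across
deliveries.  Population-level prevalence of significant cells is tested
against the per-test alpha with exact binomial tests, regional enrichment
with chi-square tests, and behavioral learning with a Kruskal-Wallis test
over chronological quintiles of drive time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io_sessions import SpikeTrain, TrialEvents

__all__ = [
    "RateTable",
    "AnovaResult",
    "build_rate_table",
    "goal_period_anova",
    "binomial_population_test",
    "behavioral_learning_test",
    "hfa_rate_correlation",
    "region_count_chisq",
    "coding_overlap_chisq",
]


@dataclass
class RateTable:
    """Per unit x delivery x half: spike count, duration and rate (Hz)."""

    unit_id: str
    table: pd.DataFrame  # columns: delivery_id, goal_id, period, count, duration_s, rate_hz


@dataclass
class AnovaResult:
    unit_id: str
    p_goal: float
    p_period: float
    p_interaction: float
    period_direction: str  # "planning>arrival" | "arrival>planning" | "none"
    interaction_dropped: bool = False


def build_rate_table(unit: SpikeTrain, events: TrialEvents) -> RateTable:
    """Spike counts and rates per half-delivery (half-open midpoint split)."""
    if len(events) < 1:
        raise ValueError("need >= 1 delivery")
    t = unit.spike_times
    rows = []
    for delivery_id, goal_id, t0, t1 in events:
        mid = 0.5 * (t0 + t1)
        for period, lo, hi in (("planning", t0, mid), ("arrival", mid, t1)):
            count = int(np.count_nonzero((t >= lo) & (t < hi)))
            dur = hi - lo
            rows.append(
                {
                    "delivery_id": delivery_id,
                    "goal_id": goal_id,
                    "period": period,
                    "count": count,
                    "duration_s": dur,
                    "rate_hz": count / dur,
                }
            )
    return RateTable(unit_id=unit.unit_id, table=pd.DataFrame(rows))


def goal_period_anova(rate_table: RateTable) -> AnovaResult:
    """Two-way goal x period ANOVA on per-half rates (type-II SS).

    If some goal x period design cell is empty the interaction term is
    dropped (main effects only) and the result flagged.
    """
    df = rate_table.table.copy()
    goal_sizes = df.groupby("goal_id")["delivery_id"].nunique()
    if (goal_sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 goals with >= 2 deliveries each")
    df["goal"] = df["goal_id"].astype("category")
    cell_counts = df.groupby(["goal", "period"], observed=True).size()
    full_design = cell_counts.ge(1).all() and len(cell_counts) == df["goal"].nunique() * 2
    formula = (
        "rate_hz ~ C(goal) * C(period)" if full_design else "rate_hz ~ C(goal) + C(period)"
    )
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_goal = float(table.loc["C(goal)", "PR(>F)"])
    p_period = float(table.loc["C(period)", "PR(>F)"])
    p_inter = (
        float(table.loc["C(goal):C(period)", "PR(>F)"]) if full_design else np.nan
    )
    means = df.groupby("period", observed=True)["rate_hz"].mean()
    if means.get("planning", 0) > means.get("arrival", 0):
        direction = "planning>arrival"
    elif means.get("planning", 0) < means.get("arrival", 0):
        direction = "arrival>planning"
    else:
        direction = "none"
    return AnovaResult(
        unit_id=rate_table.unit_id,
        p_goal=p_goal,
        p_period=p_period,
        p_interaction=p_inter,
        period_direction=direction,
        interaction_dropped=not full_design,
    )


def binomial_population_test(
    n_sig: int, n_total: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Is the count of significant cells above the chance expectation?

    Returns ``(p, expected_count)`` where ``expected_count = alpha *
    n_total`` and p is the exact upper-tail binomial probability
    ``P(X >= n_sig | n_total, alpha)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= n_sig <= n_total:
        raise ValueError("need 0 <= n_sig <= n_total")
    expected = alpha * n_total
    p = float(stats.binom.sf(n_sig - 1, n_total, alpha))
    return p, expected


def behavioral_learning_test(drive_times: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis test of drive time across chronological quintiles.

    Falling drive times over a session indicate the subject learned the
    environment and planned efficient routes.
    """
    x = np.asarray(drive_times, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 deliveries")
    groups = np.array_split(x, 5)
    if np.ptp(x) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def hfa_rate_correlation(
    hfa_z: np.ndarray,
    spike_times: np.ndarray,
    fs: float,
    valid: np.ndarray | None = None,
    kernel_s: float = 0.5,
    kernel: str = "gaussian",
    n_shuffles: int = 200,
    seed: int = 0,
    t0: float = 0.0,
) -> tuple[float, float]:
    """Pearson correlation of z-scored HFA power with smoothed firing rate.

    The spike train is binned on the LFP sample grid and convolved with a
    500 ms kernel (Gaussian by default; the SD is kernel_s/2 so virtually
    all mass lies within the stated width).  Significance comes from
    circular rotations of the rate vector, p by add-one rank.
    """
    hfa_z = np.asarray(hfa_z, dtype=float)
    n = hfa_z.size
    if n / fs < 10.0:
        raise ValueError("need >= 10 s of overlapping signal")
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise ValueError("zero-spike unit: correlation undefined")
    counts = np.zeros(n)
    idx = np.clip(np.rint((spike_times - t0) * fs).astype(int), 0, n - 1)
    np.add.at(counts, idx, 1.0)
    if kernel == "gaussian":
        sd = kernel_s / 2.0 * fs
        half = int(4 * sd)
        tt = np.arange(-half, half + 1)
        k = np.exp(-0.5 * (tt / sd) ** 2)
    elif kernel == "boxcar":
        k = np.ones(max(1, int(kernel_s * fs)))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    k /= k.sum()
    rate = np.convolve(counts, k, mode="same") * fs  # Hz
    sel = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    if sel.sum() < 10 * fs:
        raise ValueError("need >= 10 s of valid overlap")
    rng = np.random.default_rng(seed)
    rho = float(stats.pearsonr(hfa_z[sel], rate[sel])[0])
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        rolled = np.roll(rate, int(rng.integers(1, n)))
        null[j] = stats.pearsonr(hfa_z[sel], rolled[sel])[0]
    p = (1 + int((null >= rho - 1e-15).sum())) / (1 + n_shuffles)
    return rho, p


def region_count_chisq(
    counts: dict[str, tuple[int, int]]
) -> tuple[float, int, float, bool]:
    """Chi-square test of significant-cell proportion across brain regions.

    ``counts`` maps region -> (n_significant, n_total).  Returns
    ``(chi2, dof, p, low_expected_warning)``; the warning flags any
    expected cell below 1.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 regions")
    table = np.array([[sig, tot - sig] for sig, tot in counts.values()], dtype=float)
    if (table < 0).any():
        raise ValueError("n_sig cannot exceed n_total")
    chi2, p, dof, expected = stats.chi2_contingency(table)
    return float(chi2), int(dof), float(p), bool((expected < 1).any())


def coding_overlap_chisq(flags_a: np.ndarray, flags_b: np.ndarray) -> tuple[float, float]:
    """2x2 chi-square of co-occurrence of two per-channel coding flags
    (e.g. spike-phase coding vs HFA-phase coding)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.size != b.size:
        raise ValueError("flag vectors must have equal length")
    if a.size < 20:
        raise ValueError("need >= 20 channels")
    if a.all() or (~a).all() or b.all() or (~b).all():
        raise ValueError("degenerate margin: a flag vector is constant")
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)
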