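"""MODAL: adaptive narrowband-oscillation detection above the 1/f background.

Rather than imposing a priori frequency bands, the algorithm discovers, per
channel, the band(s) in which power exceeds the aperiodic 1/f spectrum:

1. Morlet wavelet power (6 cycles) on a 1-50 Hz grid in 0.5 Hz steps,
   time-averaged outside bad epochs.
2. A robust line (iteratively reweighted least squares, bisquare weights)
   is fit to the spectrum in log-log space; the 1/f background appears
   linear there and narrowband oscillations as positive excursions.
3. Bands are maximal runs of contiguous bins above the fit (>= 2 bins).
4. Within each band the instantaneous phase and frequency are computed by
   "frequency sliding": zero-phase band-pass, analytic-signal angle, and
   the temporal derivative of unwrapped phase, median-filtered across ~10
   window lengths (10-400 ms) to suppress transients.  Samples whose
   frequency estimate escapes the band ("phase slips") are invalid.
5. Detection gating: power spectra and background fits are recomputed in
   10 s non-overlapping windows; a sample stays valid only while its
   instantaneous power at the bin nearest its instantaneous frequency
   exceeds that window's fit line, so phase is only reported while the
   oscillation is actually present.

Phase convention: 0 rad at the local peak of the band-filtered signal,
+-pi at the trough, -pi/2 on the ascending zero-crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.ndimage import median_filter
from scipy.signal import fftconvolve, firls, hilbert

from .artifact_rejection import EpochMask
from .io_sessions import LfpChannel

__all__ = [
    "DEFAULT_FREQS",
    "PowerSpectrogram",
    "BackgroundFit",
    "BandDefinition",
    "OscillationTrace",
    "wavelet_power",
    "fit_background",
    "detect_bands",
    "frequency_sliding",
    "gate_by_windowed_power",
    "detect_oscillations",
    "prevalence_profile",
]

#: 1-50 Hz in 0.5 Hz steps.
DEFAULT_FREQS = np.arange(1.0, 50.0 + 1e-9, 0.5)


@dataclass
class PowerSpectrogram:
    """Per-sample wavelet log10 power on a frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    log_power: np.ndarray  # (n_freqs, n_samples) float32, log10 of power
    fs: float
    t0: float
    bad: np.ndarray  # (n_samples,) bool, True inside bad epochs

    @property
    def n_samples(self) -> int:
        return self.log_power.shape[1]

    def mean_log_power(self, sl: slice | None = None) -> np.ndarray:
        """log10 of time-averaged power per bin, bad samples excluded.

        Power is averaged in linear units and the log taken afterwards, so
        the resulting spectrum (and any line fit to it) sits at the mean
        power level — an instantaneous power sample exceeds it only during
        genuine elevations, not half the time as it would a mean-log curve.
        """
        whole = sl is None
        if whole and getattr(self, "_mean_cache", None) is not None:
            return self._mean_cache
        sl = sl if sl is not None else slice(None)
        good = ~self.bad[sl]
        n_good = int(good.sum())
        if n_good == 0:
            return np.full(self.freqs.size, np.nan)
        ln10 = np.float32(np.log(10.0))
        out = np.empty(self.freqs.size)
        all_good = n_good == good.size
        for i in range(self.freqs.size):
            row = self.log_power[i, sl]
            if not all_good:
                row = row[good]
            # row-wise float32 exp keeps memory and time bounded
            out[i] = np.exp(row * ln10, dtype=np.float32).mean(dtype=np.float64)
        result = np.log10(out)
        if whole:
            self._mean_cache = result
        return result


@dataclass
class BackgroundFit:
    """Robust line through the spectrum in log10-log10 space."""

    slope: float
    intercept: float
    freqs: np.ndarray
    fitted: np.ndarray  # fitted log10 power per bin

    def at(self, f: np.ndarray | float) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(f, dtype=float))


@dataclass
class BandDefinition:
    """A detected oscillatory band [f_lo, f_hi] on one channel."""

    channel_id: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band edges must satisfy f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi

    def intersects(self, lo: float, hi: float) -> bool:
        return self.f_lo <= hi and self.f_hi >= lo


@dataclass
class OscillationTrace:
    """Instantaneous phase/frequency of one band plus a validity mask.

    ``phase`` and ``inst_freq`` are defined per sample but meaningful only
    where ``valid`` is True (oscillation present, frequency inside the
    band, outside bad epochs).
    """

    band: BandDefinition
    phase: np.ndarray  # radians in (-pi, pi]
    inst_freq: np.ndarray  # Hz
    valid: np.ndarray  # bool
    fs: float
    t0: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def valid_fraction(self) -> float:
        return float(self.valid.mean())

    def index_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.rint((np.asarray(t) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, self.n_samples - 1)


# ---------------------------------------------------------------------------
# spectral estimation


def wavelet_power(
    lfp: LfpChannel,
    mask: EpochMask | None = None,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> PowerSpectrogram:
    """Six-cycle Morlet wavelet power at every sample and grid frequency.

    Wavelets are unit-energy; convolution is done in the frequency domain
    with the analytic (positive-frequency) Morlet kernel, so the squared
    magnitude is the instantaneous band power.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= lfp.fs / 2:
        raise ValueError(f"frequency grid exceeds Nyquist ({lfp.fs / 2} Hz)")
    x = lfp.samples - lfp.samples.mean()
    n = x.size
    X = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n, d=1.0 / lfp.fs)
    n_cycles = 6.0
    log_power = np.empty((freqs.size, n), dtype=np.float32)
    tiny = np.finfo(np.float32).tiny
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        # unit-energy analytic Morlet in the frequency domain
        kernel = (4 * np.pi * sigma_t**2) ** 0.25 * np.exp(
            -0.5 * sigma_t**2 * (omega - 2 * np.pi * f) ** 2
        )
        kernel[omega < 0] = 0.0
        conv = np.fft.ifft(X * kernel)
        log_power[i] = np.log10(np.abs(conv) ** 2 + tiny)
    bad = (
        mask.sample_mask(n, lfp.fs, lfp.t0)
        if mask is not None
        else np.zeros(n, dtype=bool)
    )
    return PowerSpectrogram(freqs=freqs, log_power=log_power, fs=lfp.fs, t0=lfp.t0, bad=bad)


def _robust_line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """IRLS line fit with Tukey bisquare weights (c=4.685), MAD scale."""
    X = sm.add_constant(log_f)
    rlm = sm.RLM(log_p, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = rlm.fit()
    return float(res.params[1]), float(res.params[0])


def fit_background(spec: PowerSpectrogram, sl: slice | None = None) -> BackgroundFit:
    """Robust log-log line through the time-averaged power spectrum.

    ``sl`` restricts the average to a sample slice (used for the 10 s
    windowed re-fits during gating).
    """
    mean_lp = spec.mean_log_power(sl)
    ok = np.isfinite(mean_lp)
    if ok.sum() < 10:
        raise ValueError("need >= 10 valid frequency bins for a background fit")
    if np.ptp(mean_lp[ok]) < 1e-12:
        raise ValueError("degenerate (constant) spectrum")
    log_f = np.log10(spec.freqs[ok])
    slope, intercept = _robust_line(log_f, mean_lp[ok])
    fitted = intercept + slope * np.log10(spec.freqs)
    return BackgroundFit(slope=slope, intercept=intercept, freqs=spec.freqs, fitted=fitted)


def detect_bands(
    spec: PowerSpectrogram,
    fit: BackgroundFit,
    min_bins: int = 2,
    margin: float = 0.15,
    channel_id: str = "",
) -> list[BandDefinition]:
    """Maximal contiguous runs of supra-fit bins, at least ``min_bins`` wide.

    ``margin`` (log10-power units) is how far above the aperiodic fit a bin
    must sit to count as oscillatory.  The background fit has smooth
    curvature residuals (the wavelet-estimated spectrum of an exact power
    law is not perfectly log-log linear), so with ``margin=0`` roughly half
    of all bins lie above the line and spurious wide bands appear on pure
    1/f signals.  The default 0.15 (~1.4x power) sits well above that
    curvature (<= ~0.12 observed on simulated aperiodic channels) and well
    below a genuine narrowband oscillation (an in-band power doubling is
    ~+0.7).  Set ``margin=0`` for the strict exceedance rule.
    """
    mean_lp = spec.mean_log_power()
    above = np.isfinite(mean_lp) & (mean_lp > fit.fitted + margin)
    bands: list[BandDefinition] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_bins:
            bands.append(
                BandDefinition(channel_id=channel_id, f_lo=float(spec.freqs[s]), f_hi=float(spec.freqs[e - 1]))
            )
    return bands


# ---------------------------------------------------------------------------
# frequency sliding


def _bandpass_fir(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Zero-phase FIR band-pass with a plateau passband and 15% transitions."""
    nyq = fs / 2
    trans_lo = f_lo * 0.15
    trans_hi = f_hi * 0.15
    lo_stop = max(f_lo - trans_lo, 1e-3)
    hi_stop = min(f_hi + trans_hi, nyq * 0.99)
    numtaps = int(round(3 * fs / f_lo))
    numtaps += 1 - numtaps % 2  # odd => symmetric, linear phase
    numtaps = min(numtaps, 2 * (x.size // 2) - 1)
    taps = firls(
        numtaps,
        [0, lo_stop, f_lo, f_hi, hi_stop, nyq],
        [0, 0, 1, 1, 0, 0],
        fs=fs,
    )
    # symmetric FIR applied once in 'same' mode is already zero-phase
    return fftconvolve(x, taps, mode="same")


def _median_smooth(f_inst: np.ndarray, fs: float, n_windows: int = 10) -> np.ndarray:
    """Average of running medians over log-spaced windows (10-400 ms)."""
    spans = np.geomspace(0.010, 0.400, n_windows)
    out = np.zeros_like(f_inst)
    for span in spans:
        w = max(3, int(round(span * fs)))
        w += 1 - w % 2
        out += median_filter(f_inst, size=w, mode="nearest")
    return out / n_windows


def frequency_sliding(
    lfp: LfpChannel,
    band: BandDefinition,
    mask: EpochMask | None = None,
) -> OscillationTrace:
    """Instantaneous phase/frequency of one band via the analytic signal.

    The artifact-masked trace (bad spans zeroed) is band-passed with a
    zero-phase FIR, the analytic angle gives phase, and the derivative of
    unwrapped phase gives instantaneous frequency, median-filtered across
    log-spaced windows.  Samples whose smoothed frequency leaves
    ``[f_lo, f_hi]`` are phase slips and marked invalid, as are bad epochs.
    """
    if band.f_hi >= lfp.fs / 2:
        raise ValueError("band exceeds Nyquist")
    if band.width < 2.0 / lfp.duration:
        raise ValueError("band unresolvable: narrower than 2/duration Hz")
    bad = (
        mask.sample_mask(lfp.samples.size, lfp.fs, lfp.t0)
        if mask is not None
        else np.zeros(lfp.samples.size, dtype=bool)
    )
    x = lfp.samples - lfp.samples.mean()
    x = np.where(bad, 0.0, x)
    filtered = _bandpass_fir(x, lfp.fs, band.f_lo, band.f_hi)
    analytic = hilbert(filtered)
    phase = np.angle(analytic)
    unwrapped = np.unwrap(phase)
    f_inst = np.gradient(unwrapped) * lfp.fs / (2 * np.pi)  # central differences
    f_inst = _median_smooth(f_inst, lfp.fs)
    valid = (f_inst >= band.f_lo) & (f_inst <= band.f_hi) & ~bad
    return OscillationTrace(
        band=band, phase=phase, inst_freq=f_inst, valid=valid, fs=lfp.fs, t0=lfp.t0
    )


def _nearest_bin(freqs: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Index of the grid frequency nearest each value."""
    hi = np.clip(np.searchsorted(freqs, values), 1, freqs.size - 1)
    lo = hi - 1
    pick_hi = np.abs(freqs[hi] - values) < np.abs(freqs[lo] - values)
    return np.where(pick_hi, hi, lo)


def gate_by_windowed_power(
    trace: OscillationTrace,
    lfp: LfpChannel,
    mask: EpochMask | None = None,
    window: float = 10.0,
    spec: PowerSpectrogram | None = None,
) -> OscillationTrace:
    """Keep phase estimates only while band power beats the local 1/f fit.

    The spectrum and its robust fit are recomputed in non-overlapping
    ``window``-second windows; a sample survives if its instantaneous
    wavelet power at the bin nearest its instantaneous frequency exceeds
    the window's fitted background at that bin.
    """
    if spec is None:
        spec = wavelet_power(lfp, mask)
    n = trace.n_samples
    win_samples = int(round(window * trace.fs))
    if win_samples <= 0:
        raise ValueError("window must be positive")
    win_samples = min(win_samples, n)
    nearest_bin = _nearest_bin(spec.freqs, trace.inst_freq)
    valid = trace.valid.copy()
    for start in range(0, n, win_samples):
        sl = slice(start, min(start + win_samples, n))
        try:
            fit = fit_background(spec, sl)
        except ValueError:
            valid[sl] = False  # window entirely bad / degenerate
            continue
        idx = np.arange(sl.start, sl.stop)
        bins = nearest_bin[idx]
        supra = spec.log_power[bins, idx] > fit.fitted[bins]
        valid[idx] &= supra
    return OscillationTrace(
        band=trace.band,
        phase=trace.phase,
        inst_freq=trace.inst_freq,
        valid=valid,
        fs=trace.fs,
        t0=trace.t0,
    )


def detect_oscillations(
    lfp: LfpChannel,
    mask: EpochMask | None = None,
    freqs: np.ndarray = DEFAULT_FREQS,
    min_bins: int = 2,
    band_range: tuple[float, float] | None = None,
    gate: bool = True,
) -> list[OscillationTrace]:
    """Full MODAL pass on one channel: detect bands, track phase, gate.

    ``band_range`` keeps only bands intersecting the given (lo, hi) Hz
    interval — e.g. (1, 10) for the slow-theta analyses or (10, 30) for
    the alpha/beta variant.
    """
    spec = wavelet_power(lfp, mask, freqs)
    fit = fit_background(spec)
    bands = detect_bands(spec, fit, min_bins=min_bins, channel_id=lfp.channel_id)
    if band_range is not None:
        bands = [b for b in bands if b.intersects(*band_range)]
    traces = []
    for band in bands:
        tr = frequency_sliding(lfp, band, mask)
        if gate:
            tr = gate_by_windowed_power(tr, lfp, mask, spec=spec)
        traces.append(tr)
    return traces


def prevalence_profile(
    traces_by_channel: list[list[OscillationTrace]],
    freqs: np.ndarray = DEFAULT_FREQS,
) -> dict[str, np.ndarray]:
    """Population summary of band prevalence across channels.

    Returns ``channel_fraction`` — fraction of channels with a detected
    band covering each grid frequency — and ``time_fraction`` — among
    those channels, the mean fraction of session time each frequency was
    the detected instantaneous frequency (nearest grid bin, valid samples
    only).
    """
    if not traces_by_channel:
        raise ValueError("need >= 1 channel")
    freqs = np.asarray(freqs, dtype=float)
    step = np.median(np.diff(freqs)) if freqs.size > 1 else 0.5
    has_band = np.zeros((len(traces_by_channel), freqs.size), dtype=bool)
    time_frac = np.zeros((len(traces_by_channel), freqs.size))
    for c, traces in enumerate(traces_by_channel):
        for tr in traces:
            covered = (freqs >= tr.band.f_lo) & (freqs <= tr.band.f_hi)
            has_band[c] |= covered
            if tr.valid.any():
                f_valid = tr.inst_freq[tr.valid]
                counts, _ = np.histogram(
                    f_valid, bins=np.concatenate([freqs - step / 2, [freqs[-1] + step / 2]])
                )
                time_frac[c] += counts / tr.n_samples
    channel_fraction = has_band.mean(axis=0)
    with np.errstate(invalid="ignore"):
        time_fraction = np.where(
            has_band.any(axis=0),
            time_frac.sum(axis=0) / np.maximum(has_band.sum(axis=0), 1),
            0.0,
        )
    return {"freqs": freqs, "channel_fraction": channel_fraction, "time_fraction": time_fraction}
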