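"""Spectrograms, USV detection and envelope-weighted GCC delay estimation.

The delay estimator (EWGCC) band-passes both channels to the ultrasonic band,
weights each channel by its normalized analytic envelope, whitens the cross
spectrum (PHAT with a spectral floor) restricted to the band, and reads the delay
off the correlation peak with 3-point parabolic sub-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegenerateSignalError,
    NoDelayError,
    SlimlocError,
    ValidationError,
)
from .geometry import MicArrayGeometry

#: analog anti-alias guard of the recording chain: content above this is ignored
ANTI_ALIAS_HZ = 120_000.0

#: default ultrasonic vocalization band, Hz
USV_BAND = (30_000.0, 110_000.0)


@dataclass
class AudioRecording:
    """Multichannel waveform, volts-proportional floats.

    ``samples`` has shape ``(n_channels, n_samples)``.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if s.ndim != 2:
            raise ValidationError("samples must be a (n_channels, n_samples) array")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        self.samples = s

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def slice_seconds(self, start: float, stop: float) -> np.ndarray:
        """Channel-wise view of samples within [start, stop) seconds."""
        i0 = max(0, int(round((start - self.start_time) * self.sampling_rate)))
        i1 = min(self.n_samples, int(round((stop - self.start_time) * self.sampling_rate)))
        if i1 <= i0:
            raise ValidationError(f"empty window [{start}, {stop}) s")
        return self.samples[:, i0:i1]


@dataclass(frozen=True)
class USVSegment:
    """One detected vocalization: onset/offset in seconds, analysis band in Hz."""

    onset: float
    offset: float
    band: tuple[float, float] = USV_BAND
    detection_channel: int = 0

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError("segment offset must exceed onset")
        if not (0 < self.band[0] < self.band[1]):
            raise ValidationError("invalid frequency band")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass(frozen=True)
class DelayEstimate:
    """Signed arrival-time difference for one microphone pair.

    ``delta_t`` > 0 means the sound reached microphone ``j`` later than ``i``
    (the source is closer to microphone ``i``).
    """

    pair_ids: tuple[int, int]
    delta_t: float
    peak_value: float
    window: tuple[float, float]


@dataclass
class DetectionParams:
    """Thresholds of the simplified spectrogram-based USV detector."""

    band: tuple[float, float] = USV_BAND
    threshold_db: float = 8.0
    min_duration_ms: float = 5.0
    merge_gap_ms: float = 10.0
    window_ms: float = 2.0
    step_ms: float = 1.0


def spectrogram(
    rec: AudioRecording,
    channel: int,
    window_ms: float = 2.0,
    step_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Power spectral density over time for one channel.

    Returns ``(freqs_hz, frame_times_s, psd)`` where ``psd`` has shape
    ``(n_freqs, n_frames)`` in V^2/Hz; summing over frequency (times the bin
    width) recovers the signal power of a stationary input.
    """
    if not window_ms >= step_ms > 0:
        raise ValidationError("require window_ms >= step_ms > 0")
    x = rec.samples[channel]
    if x.size == 0:
        raise ValidationError("empty channel")
    fs = rec.sampling_rate
    nperseg = max(8, int(round(window_ms * 1e-3 * fs)))
    noverlap = nperseg - max(1, int(round(step_ms * 1e-3 * fs)))
    f, t, sxx = signal.spectrogram(
        x, fs=fs, nperseg=nperseg, noverlap=noverlap, scaling="density", mode="psd"
    )
    return f, t + rec.start_time, sxx


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo = max(band[0], 1.0)
    hi = min(band[1], ANTI_ALIAS_HZ, 0.999 * fs / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_usvs(
    rec: AudioRecording,
    params: DetectionParams | None = None,
    channels: list[int] | None = None,
) -> list[USVSegment]:
    """Simplified energy-threshold USV detection.

    In-band spectrogram power per frame is compared against a median-based noise
    floor; frames exceeding ``threshold_db`` above the floor on *any* channel are
    active (a vocalization only has to be detected on one microphone). Active
    runs closer than ``merge_gap_ms`` are merged; runs shorter than
    ``min_duration_ms`` are dropped.
    """
    params = params or DetectionParams()
    channels = list(range(rec.n_channels)) if channels is None else channels
    active = None
    times = None
    best_channel_power = None
    channel_of_max = None
    for ch in channels:
        f, t, sxx = spectrogram(rec, ch, params.window_ms, params.step_ms)
        inband = (f >= params.band[0]) & (f <= params.band[1])
        p = sxx[inband].sum(axis=0)  # V^2/Hz summed over band ~ in-band power
        floor = np.median(p)
        if floor <= 0:
            floor = np.finfo(float).tiny
        act = p > floor * 10 ** (params.threshold_db / 10)
        if active is None:
            active = act
            times = t
            best_channel_power = p.copy()
            channel_of_max = np.full(p.shape, ch)
        else:
            active |= act
            better = p > best_channel_power
            best_channel_power[better] = p[better]
            channel_of_max[better] = ch
    if active is None or not active.any():
        return []

    step_s = params.step_ms * 1e-3
    # runs of active frames
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    # merge runs separated by less than the merge gap
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and (times[s] - times[merged[-1][1] - 1]) < params.merge_gap_ms * 1e-3:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    half_win = params.window_ms * 1e-3 / 2
    out = []
    for s, e in merged:
        onset = times[s] - half_win
        offset = times[e - 1] + half_win
        if (offset - onset) * 1e3 < params.min_duration_ms:
            continue
        ch = int(np.bincount(channel_of_max[s:e]).argmax())
        out.append(
            USVSegment(onset=max(rec.start_time, onset), offset=offset,
                       band=params.band, detection_channel=ch)
        )
    return out


def ewgcc(
    rec: AudioRecording,
    i: int,
    j: int,
    window: tuple[float, float],
    band: tuple[float, float] = USV_BAND,
    spectral_floor: float = 1e-8,
    spectral_focus: float = 0.01,
    max_lag_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope-weighted generalized cross-correlation of channels ``i`` and ``j``.

    Returns ``(lags_s, corr)``; a positive-lag peak means channel ``j`` lags
    channel ``i`` (the source is closer to microphone ``i``). ``max_lag_s``
    restricts the returned lags (defaults to the full computed range); physical
    feasibility is enforced later by :func:`estimate_delay`.

    ``spectral_focus`` implements the spectral focusing of the correlation:
    after PHAT whitening, each bin is re-weighted by
    ``|S|/(|S| + spectral_focus * max|S|)`` so that bins without call energy do
    not enter at full (unit) weight — under pure whitening their random phases
    would contribute an SNR-independent error term. 0 disables the gate.
    """
    xw = rec.slice_seconds(*window)
    xi, xj = xw[i], xw[j]
    if not (np.any(xi) and np.any(xj)):
        raise DegenerateSignalError("all-zero analysis window")
    fs = rec.sampling_rate
    xi = _bandpass(xi, fs, band)
    xj = _bandpass(xj, fs, band)

    # envelope weighting: emphasize the parts of the window where the call is on;
    # the mild taper suppresses window-edge transients that would otherwise be
    # boosted to full weight by the whitening and correlate at zero lag
    taper = signal.windows.tukey(len(xi), 0.1)
    for_env = []
    for x in (xi, xj):
        env = np.abs(signal.hilbert(x))
        m = env.max()
        for_env.append(x * (env / m if m > 0 else env) * taper)
    yi, yj = for_env

    n = len(yi)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fi = np.fft.rfft(yi, nfft)
    fj = np.fft.rfft(yj, nfft)
    cross = np.conj(fi) * fj
    mag = np.abs(cross)
    eps = spectral_floor * (mag.max() if mag.max() > 0 else 1.0)
    white = cross / (mag + eps)
    if spectral_focus > 0:
        white *= mag / (mag + spectral_focus * mag.max())
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= min(band[1], ANTI_ALIAS_HZ))
    white[~keep] = 0.0
    corr = np.fft.irfft(white, nfft)
    corr = np.concatenate((corr[-(n - 1):], corr[:n]))  # lags -(n-1) .. n-1
    lags = np.arange(-(n - 1), n) / fs
    if max_lag_s is not None:
        m = np.abs(lags) <= max_lag_s
        lags, corr = lags[m], corr[m]
    return lags, corr


def estimate_delay(
    lags: np.ndarray,
    corr: np.ndarray,
    pair_ids: tuple[int, int] = (0, 1),
    window: tuple[float, float] = (0.0, 0.0),
    max_delay_s: float | None = None,
) -> DelayEstimate:
    """Sub-sample delay from a correlation function.

    The integer-lag peak is searched among physically feasible lags
    (|lag| <= ``max_delay_s``); ties break toward smaller |lag|. A 3-point
    parabola around the peak refines the delay to sub-sample resolution.
    """
    lags = np.asarray(lags, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if lags.size < 3 or not np.any(np.isfinite(corr)) or np.all(corr == 0):
        raise DegenerateSignalError("degenerate correlation function")
    feasible = np.ones_like(lags, dtype=bool)
    if max_delay_s is not None:
        feasible = np.abs(lags) <= max_delay_s
        if not feasible.any():
            raise NoDelayError("no feasible lag range")
    # coarse stage: the correlation envelope has no carrier comb, so its peak
    # resolves the cycle ambiguity; the raw-correlation peak within half a
    # carrier period of it then gives carrier-level precision
    env = np.abs(signal.hilbert(corr))
    e = np.where(feasible, env, -np.inf)
    k_env = int(np.argmax(e))
    dt_samp = 1.0 / np.mean(np.diff(lags))  # samples per second
    near = feasible & (np.abs(lags - lags[k_env]) <= 2.0 / dt_samp)
    c = np.where(near, corr, -np.inf)
    peak = float(np.max(c))
    if not np.isfinite(peak):
        raise NoDelayError("no feasible correlation peak")
    candidates = np.flatnonzero(c == peak)
    k = candidates[np.argmin(np.abs(lags[candidates]))]  # ties -> smaller |lag|

    dt = 1.0 / np.mean(np.diff(lags))
    delta = lags[k]
    if 0 < k < len(lags) - 1:
        ym, y0, yp = corr[k - 1], corr[k], corr[k + 1]
        denom = ym - 2 * y0 + yp
        if denom < 0:  # proper maximum
            frac = 0.5 * (ym - yp) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            delta = lags[k] + frac / dt
    if max_delay_s is not None:
        delta = float(np.clip(delta, -max_delay_s, max_delay_s))
    return DelayEstimate(pair_ids=pair_ids, delta_t=float(delta),
                         peak_value=max(peak, 0.0), window=window)


def pair_delay(
    rec: AudioRecording,
    geometry: MicArrayGeometry,
    i: int,
    j: int,
    window: tuple[float, float],
    band: tuple[float, float] = USV_BAND,
) -> DelayEstimate:
    """EWGCC + peak extraction for one pair, with the feasibility bound applied."""
    max_delay = geometry.max_delay_s(i, j) * 1.05 + 2.0 / rec.sampling_rate
    lags, corr = ewgcc(rec, i, j, window, band=band, max_lag_s=max_delay)
    return estimate_delay(lags, corr, pair_ids=(i, j), window=window,
                          max_delay_s=geometry.max_delay_s(i, j))
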