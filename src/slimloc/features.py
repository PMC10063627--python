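"""Acoustic properties of ultrasonic vocalizations and the 203-dim shape vector.

The fundamental frequency line is the per-1-ms peak frequency of the in-band
spectrum; together with its derivative (100 + 100 components), the duration, the
frequency directionality and the snout-to-snout distance it forms the
203-dimensional shape vector used for embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustics import AudioRecording, USVSegment, _bandpass
from .errors import FeatureExtractionError, ValidationError

#: frame length of the frequency line, ms
FRAME_MS = 1.0

#: the shape vector keeps the first this-many milliseconds of the line
LINE_LEN = 100

SHAPE_DIM = 2 * LINE_LEN + 3


@dataclass
class USVFeatures:
    """Scalar and vectorial acoustic properties of one vocalization."""

    duration_ms: float
    freq_line: np.ndarray  # Hz, one value per 1-ms frame
    freq_line_derivative: np.ndarray  # Hz/ms, first differences
    mean_frequency: float  # Hz
    frequency_range: float  # Hz
    wiener_entropy: float  # spectral flatness in [0, 1]
    sound_level: float  # V (SD of band-passed waveform, loudest channel)
    mean_energy: float  # V^2/s
    directionality: float  # mean sign of the derivative, [-1, 1]


def _frame_spectra(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-1-ms-frame in-band power spectra (rectangular frames, no overlap)."""
    n_frame = int(round(FRAME_MS * 1e-3 * fs))
    n = len(x) // n_frame
    if n == 0:
        raise FeatureExtractionError("segment shorter than one analysis frame")
    frames = x[: n * n_frame].reshape(n, n_frame)
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_frame, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise FeatureExtractionError("analysis band contains no frequency bins")
    return freqs[keep], spec[:, keep]


def spectral_flatness(power: np.ndarray) -> float:
    """Geometric-to-arithmetic mean ratio of a power spectrum (0 tonal, 1 flat)."""
    p = np.asarray(power, dtype=float)
    p = p[p >= 0]
    am = p.mean()
    if am <= 0:
        return 0.0
    gm = np.exp(np.mean(np.log(np.maximum(p, np.finfo(float).tiny))))
    return float(gm / am)


def extract_features(
    rec: AudioRecording,
    segment: USVSegment,
    channel: int | None = None,
    per_frame_flatness: bool = False,
) -> USVFeatures:
    """Extract the acoustic properties of one vocalization.

    ``channel=None`` selects the loudest channel (largest in-band waveform SD).
    Wiener entropy is the spectral flatness of the frame-averaged in-band
    spectrum; ``per_frame_flatness=True`` instead averages per-frame flatness
    values (a noisier estimator that is biased low for broadband signals).
    """
    fs = rec.sampling_rate
    xw = rec.slice_seconds(segment.onset, segment.offset)
    banded = np.array([_bandpass(xw[c], fs, segment.band) for c in range(rec.n_channels)])
    levels = banded.std(axis=1)
    if channel is None:
        channel = int(np.argmax(levels))
    x = banded[channel]
    if not np.any(x) or levels[channel] == 0:
        raise FeatureExtractionError("no in-band energy in segment")

    freqs, spec = _frame_spectra(x, fs, segment.band)
    line = freqs[np.argmax(spec, axis=1)]
    deriv = np.diff(line) / FRAME_MS if len(line) > 1 else np.zeros(0)

    if per_frame_flatness:
        flat = float(np.mean([spectral_flatness(s) for s in spec]))
    else:
        flat = spectral_flatness(spec.mean(axis=0))

    dur_s = segment.duration
    return USVFeatures(
        duration_ms=dur_s * 1e3,
        freq_line=line,
        freq_line_derivative=deriv,
        mean_frequency=float(line.mean()),
        frequency_range=float(line.max() - line.min()),
        wiener_entropy=flat,
        sound_level=float(levels[channel]),
        mean_energy=float(np.mean(x**2) / dur_s),
        directionality=_directionality(deriv),
    )


def _directionality(deriv: np.ndarray) -> float:
    """Mean sign of the non-zero frequency steps (zero steps are bin
    quantization of a slow sweep, not flat frequency); 0 when all steps are 0."""
    s = np.sign(deriv)
    nz = s != 0
    return float(s[nz].mean()) if nz.any() else 0.0


def shape_vector(features: USVFeatures, snout_distance_mm: float) -> np.ndarray:
    """Assemble the 203-component shape vector.

    Order: frequency line (100, Hz; padded with its final value, truncated at
    100 ms), line derivative (100, Hz/ms; padded with zeros), duration (ms),
    directionality, snout-to-snout distance (mm).
    """
    line = np.asarray(features.freq_line, dtype=float)
    deriv = np.asarray(features.freq_line_derivative, dtype=float)
    if line.size == 0 or not np.all(np.isfinite(line)):
        raise ValidationError("frequency line must be non-empty and finite")

    if len(line) >= LINE_LEN:
        line_c = line[:LINE_LEN]
    else:
        line_c = np.concatenate((line, np.full(LINE_LEN - len(line), line[-1])))
    deriv_c = np.zeros(LINE_LEN)
    m = min(len(deriv), LINE_LEN)
    deriv_c[:m] = deriv[:m]

    vec = np.concatenate(
        (line_c, deriv_c,
         [features.duration_ms, features.directionality, snout_distance_mm])
    )
    if not np.all(np.isfinite(vec)):
        raise ValidationError("shape vector contains non-finite values")
    assert vec.shape == (SHAPE_DIM,)
    return vec
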