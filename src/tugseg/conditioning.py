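"""Signal conditioning: detrend, amplitude normalization, ideal band-pass.

The conditioning chain prepares each raw inertial channel for peak-based
activity detection: a linear trend (sensor drift) is removed by least
squares, the signal is normalized against its absolute maximum (making all
subjects comparable in unitless amplitude), and an ideal frequency-domain
band-pass filter H(w) = 1 for w1 <= |w| <= w2, 0 elsewhere, isolates the
slow postural dynamics that carry the activity peaks. The filter is a
brick wall by construction: band-edge bins are kept with unit gain,
everything else is zeroed, and the edge ringing this implies is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import DegenerateSignalError, ValidationError
from .types import SensorTrace


@dataclass
class ConditionedTrace:
    """A detrended, normalized, band-passed channel ready for peak analysis."""

    source: tuple[str, str, str]  # (site, quantity, axis); axis may be a joint tag
    samples: np.ndarray
    rate_hz: float
    w1_hz: float
    w2_hz: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz


def detrend(samples: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend from a 1-D signal."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValidationError("detrend expects a 1-D signal")
    if len(samples) < 2:
        raise DegenerateSignalError("detrend needs at least 2 samples")
    return scipy.signal.detrend(samples, type="linear")


def normalize(samples: np.ndarray) -> np.ndarray:
    """Scale a signal by its absolute maximum so that max |output| = 1."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise DegenerateSignalError("cannot normalize an empty signal")
    peak = np.max(np.abs(samples))
    # Treat numerically-zero residues (e.g. a detrended pure ramp) as zero.
    if peak < 1e-12:
        raise DegenerateSignalError("degenerate signal: all samples are zero")
    return samples / peak


def ideal_bandpass(
    samples: np.ndarray, rate_hz: float, w1_hz: float, w2_hz: float
) -> np.ndarray:
    """Brick-wall band-pass: keep DFT bins with |f| in [w1, w2], zero the rest.

    Band membership is inclusive on both edges; positive and negative
    frequencies are treated symmetrically (real transform). The inverse
    transform is returned at the input length.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValidationError("ideal_bandpass expects a 1-D signal")
    nyquist = rate_hz / 2.0
    if not (0 <= w1_hz < w2_hz):
        raise ValidationError(f"need 0 <= w1 < w2, got w1={w1_hz}, w2={w2_hz}")
    if w2_hz > nyquist:
        raise ValidationError(
            f"w2={w2_hz} Hz exceeds the Nyquist frequency {nyquist} Hz"
        )
    n = len(samples)
    spectrum = np.fft.rfft(samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    keep = (freqs >= w1_hz) & (freqs <= w2_hz)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=n)


def condition_samples(
    samples: np.ndarray,
    rate_hz: float,
    w1_hz: float,
    w2_hz: float,
    source: tuple[str, str, str] = ("", "", ""),
) -> ConditionedTrace:
    """Apply the full chain detrend -> normalize -> band-pass to a 1-D series."""
    out = ideal_bandpass(normalize(detrend(samples)), rate_hz, w1_hz, w2_hz)
    return ConditionedTrace(
        source=source, samples=out, rate_hz=rate_hz, w1_hz=w1_hz, w2_hz=w2_hz
    )


def condition(
    trace: SensorTrace, axis: str, w1_hz: float, w2_hz: float
) -> ConditionedTrace:
    """Condition one axis of a sensor trace, recording the applied band."""
    return condition_samples(
        trace.component(axis),
        trace.rate_hz,
        w1_hz,
        w2_hz,
        source=(trace.site, trace.quantity, axis),
    )
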