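"""MR pulse-sequence representation and sequence-level exposure descriptors.

A sequence is described by the RF pulse train played in one repetition time
(TR) and by the gradient events of one TR, treated as the periodic unit of
the waveform.  Two sequence-level quantities feed the exposure pipeline:

* the RF stress index ``psi`` — a dimensionless multiplier such that the
  TR-averaged SAR equals ``psi`` times the configuration index field;
* the gradient spectrum ``G(f)`` — per-channel Fourier-series coefficients
  (peak phasors) of the periodic gradient waveform.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from implantheat.constants import (
    GAMMA_PROTON,
    REF_FLIP_ANGLE,
    REF_PULSE_LENGTH,
)
from implantheat.errors import (
    DegenerateEnvelopeError,
    ResampleRequiredError,
    UnderspecifiedSequenceError,
    ValidationError,
)

__all__ = [
    "PulseShape",
    "Axis",
    "RFPulse",
    "GradientEvent",
    "SequenceModel",
    "GradientSpectrum",
    "pulse_energy_ratio",
    "rf_stress_index",
    "computed_b1rms",
    "gradient_spectrum",
]

#: Frequencies above this are dropped from gradient spectra (quasi-static band).
SPECTRUM_MAX_FREQUENCY = 100e3
#: Fraction of the f^2-weighted spectral energy retained after truncation.
SPECTRUM_ENERGY_FRACTION = 0.999
#: Quadrature resolution for envelope integrals.
_ENVELOPE_SAMPLES = 8192


class PulseShape(str, enum.Enum):
    HARD = "hard"
    APODIZED_SINC = "apodized_sinc"
    RECT_WINDOW = "rect_window"
    CUSTOM_ENVELOPE = "custom_envelope"


class Axis(str, enum.Enum):
    X = "x"
    Y = "y"
    Z = "z"

    @property
    def index(self) -> int:
        return "xyz".index(self.value)


@dataclass
class RFPulse:
    """One RF pulse: flip angle, duration and modulation envelope.

    Parameters
    ----------
    flip_angle:
        Nominal flip angle in radians (>= 0).
    duration:
        Pulse length in seconds (> 0).
    shape:
        Envelope family.  ``rect_window`` is a rectangular envelope active on
        a ``window_fraction`` of the duration; ``custom_envelope`` takes
        peak-normalised uniform samples spanning the full duration.
    time_bandwidth:
        Time-bandwidth product for sinc shapes (dimensionless).
    envelope_samples:
        Normalised amplitude samples (peak 1) for ``custom_envelope``.
    window_fraction:
        Active fraction of the duration for ``rect_window``.
    """

    flip_angle: float
    duration: float
    shape: PulseShape = PulseShape.HARD
    time_bandwidth: float = 4.0
    envelope_samples: np.ndarray | None = None
    window_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.shape = PulseShape(self.shape)
        if self.flip_angle < 0:
            raise ValidationError("flip_angle must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.shape is PulseShape.RECT_WINDOW and not 0 < self.window_fraction <= 1:
            raise ValidationError("window_fraction must be in (0, 1]")
        if self.shape is PulseShape.CUSTOM_ENVELOPE:
            if self.envelope_samples is None:
                raise ValidationError("custom_envelope requires envelope_samples")
            env = np.asarray(self.envelope_samples, dtype=float)
            if not np.all(np.isfinite(env)):
                raise ValidationError("envelope samples must be finite")
            peak = np.max(np.abs(env))
            if not math.isclose(peak, 1.0, rel_tol=1e-9):
                raise ValidationError("envelope samples must be peak-normalised to 1")
            self.envelope_samples = env

    def envelope(self, n: int = _ENVELOPE_SAMPLES) -> np.ndarray:
        """Sample the normalised envelope on ``n`` uniform points over the duration."""
        if self.shape is PulseShape.HARD:
            return np.ones(n)
        if self.shape is PulseShape.RECT_WINDOW:
            tau = np.linspace(0.0, 1.0, n, endpoint=False) + 0.5 / n
            return (tau < self.window_fraction).astype(float)
        if self.shape is PulseShape.APODIZED_SINC:
            # symmetric sinc with time-bandwidth lobes, Hanning-apodised
            tau = np.linspace(-0.5, 0.5, n)
            env = np.sinc(self.time_bandwidth * tau)
            env *= 0.5 * (1.0 + np.cos(2.0 * np.pi * tau))
            return env
        assert self.envelope_samples is not None
        src = self.envelope_samples
        tau = np.linspace(0.0, 1.0, n)
        return np.interp(tau, np.linspace(0.0, 1.0, src.size), src)

    def b1_peak(self) -> float:
        """Peak B1 amplitude (tesla) delivering the nominal flip angle."""
        area = self.duration * _envelope_mean(self)
        if area == 0.0:
            raise DegenerateEnvelopeError("envelope integrates to zero")
        return self.flip_angle / (GAMMA_PROTON * area)


def _envelope_mean(pulse: RFPulse) -> float:
    """Mean of the normalised envelope over the duration (closed form when exact)."""
    if pulse.shape is PulseShape.HARD:
        return 1.0
    if pulse.shape is PulseShape.RECT_WINDOW:
        return pulse.window_fraction
    env = pulse.envelope()
    return float(np.trapezoid(env, dx=1.0 / (env.size - 1)))


def _envelope_mean_sq(pulse: RFPulse) -> float:
    if pulse.shape is PulseShape.HARD:
        return 1.0
    if pulse.shape is PulseShape.RECT_WINDOW:
        return pulse.window_fraction
    env = pulse.envelope()
    return float(np.trapezoid(env**2, dx=1.0 / (env.size - 1)))


def pulse_energy_ratio(pulse: RFPulse) -> float:
    """Energy ratio ``r`` of the modulated pulse to the equal-flip hard pulse.

    For a peak-normalised envelope ``e(t)`` over duration ``T``::

        r = T * int(e^2) / (int(e))^2

    equal to 1 for a hard pulse and >= 1 for any envelope (Cauchy-Schwarz).

    Raises
    ------
    DegenerateEnvelopeError
        If the envelope integrates to zero (flip angle unreachable).
    """
    mean = _envelope_mean(pulse)
    if mean == 0.0:
        raise DegenerateEnvelopeError("envelope integrates to zero")
    return _envelope_mean_sq(pulse) / mean**2


@dataclass
class GradientEvent:
    """One gradient event on a single physical channel.

    ``trapezoid`` events are ramp-up/flat/ramp-down with the given peak
    amplitude; ``sampled`` events carry uniform samples at ``sample_dt``
    spacing starting at ``start_time``.  Overlapping events on one channel
    add linearly.
    """

    channel: Axis
    kind: str = "trapezoid"  # "trapezoid" | "sampled"
    amplitude: float = 0.0  # T/m, peak
    ramp_time: float = 0.0
    flat_time: float = 0.0
    start_time: float = 0.0
    samples: np.ndarray | None = None
    sample_dt: float | None = None
    sample_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel = Axis(self.channel)
        if self.kind not in ("trapezoid", "sampled"):
            raise ValidationError(f"unknown gradient event kind {self.kind!r}")
        if self.kind == "sampled":
            if self.samples is None:
                raise ValidationError("sampled event requires samples")
            self.samples = np.asarray(self.samples, dtype=float)
            if self.sample_times is not None:
                times = np.asarray(self.sample_times, dtype=float)
                dts = np.diff(times)
                if dts.size and not np.allclose(dts, dts[0], rtol=1e-6, atol=0.0):
                    raise ResampleRequiredError(
                        "sampled gradient waveform is not uniformly sampled"
                    )
                self.sample_dt = float(dts[0]) if dts.size else self.sample_dt
                self.start_time = float(times[0])
            if self.sample_dt is None:
                raise ValidationError("sampled event requires sample_dt or sample_times")

    @property
    def end_time(self) -> float:
        if self.kind == "trapezoid":
            return self.start_time + 2.0 * self.ramp_time + self.flat_time
        assert self.samples is not None and self.sample_dt is not None
        return self.start_time + self.samples.size * self.sample_dt


@dataclass
class SequenceModel:
    """An MR pulse sequence: RF pulse train and gradient events of one TR."""

    name: str
    TR: float
    duration: float
    rf_pulses: list[RFPulse] = field(default_factory=list)
    gradient_events: list[GradientEvent] = field(default_factory=list)
    duty_cycle: float = 1.0
    b1rms: float | None = None  # tesla
    freq_encode_axis: Axis | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ValidationError("TR must be > 0")
        if self.duration < self.TR:
            raise ValidationError("duration must be >= TR")
        if not 0 < self.duty_cycle <= 1:
            raise ValidationError("duty_cycle must be in (0, 1]")
        total_rf = sum(p.duration for p in self.rf_pulses)
        if total_rf > self.TR * (1 + 1e-12):
            raise ValidationError("sum of RF pulse durations exceeds TR")
        if self.freq_encode_axis is not None:
            self.freq_encode_axis = Axis(self.freq_encode_axis)


@dataclass
class GradientSpectrum:
    """Fourier-series lines of the periodic gradient waveform.

    ``coefficients[j]`` is the complex 3-vector of per-channel peak phasors
    (T/m) at ``frequencies[j]``; the waveform on channel ``k`` is
    ``DC + sum_j Re(coefficients[j, k] * exp(2i*pi*f_j*t))``.  Power formulas
    carry the explicit 1/2 factor of the peak-phasor convention.  The DC term
    is discarded (it deposits no power).
    """

    frequencies: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.frequencies.ndim != 1:
            raise ValidationError("frequencies must be 1-D")
        if self.coefficients.shape != (self.frequencies.size, 3):
            raise ValidationError("coefficients must have shape (n_freq, 3)")
        if self.frequencies.size:
            if np.any(self.frequencies <= 0):
                raise ValidationError("frequencies must be strictly positive")
            if np.any(np.diff(self.frequencies) <= 0):
                raise ValidationError("frequencies must be strictly increasing")

    @property
    def is_empty(self) -> bool:
        return self.frequencies.size == 0

    def permuted(self, mapping: dict[Axis, Axis]) -> "GradientSpectrum":
        """Return a copy with channels reassigned per ``mapping`` (src -> dst)."""
        coeff = np.zeros_like(self.coefficients)
        for src in Axis:
            dst = mapping.get(src, src)
            coeff[:, dst.index] += self.coefficients[:, src.index]
        return GradientSpectrum(self.frequencies.copy(), coeff)


# ---------------------------------------------------------------------------
# RF stress index


def rf_stress_index(seq: SequenceModel) -> float:
    """Sequence RF stress index ``psi`` (dimensionless).

    Pulse-train route (used when ``rf_pulses`` is non-empty)::

        psi = (1/TR) * sum_i r_i * T_i * (alpha_i/alpha_90 * dt/T_i)^2

    with ``alpha_90 = pi/2`` and ``dt = 1 ms`` the reference hard pulse.
    When only a declared B1+ rms is available the equivalent closed form
    ``psi = (gamma * dt * B1rms / (pi/2))^2`` is used; the two routes are
    algebraically identical for any pulse train.
    """
    if seq.rf_pulses:
        acc = 0.0
        for p in seq.rf_pulses:
            r = pulse_energy_ratio(p)
            scale = (p.flip_angle / REF_FLIP_ANGLE) * (REF_PULSE_LENGTH / p.duration)
            acc += r * p.duration * scale**2
        return acc / seq.TR
    if seq.b1rms is not None:
        return (GAMMA_PROTON * REF_PULSE_LENGTH * seq.b1rms / REF_FLIP_ANGLE) ** 2
    raise UnderspecifiedSequenceError(
        f"sequence {seq.name!r} has neither rf_pulses nor a declared b1rms"
    )


def computed_b1rms(seq: SequenceModel) -> float:
    """Root-mean-square B1 amplitude (tesla) over one TR of the pulse train."""
    if not seq.rf_pulses:
        raise UnderspecifiedSequenceError("sequence has no rf_pulses")
    acc = 0.0
    for p in seq.rf_pulses:
        acc += p.b1_peak() ** 2 * _envelope_mean_sq(p) * p.duration
    return math.sqrt(acc / seq.TR)


# ---------------------------------------------------------------------------
# Gradient spectrum


def _trapezoid_coefficients(ev: GradientEvent, freqs: np.ndarray) -> np.ndarray:
    """Analytic Fourier-transform values of one trapezoid at the given frequencies."""
    width_mid = ev.ramp_time + ev.flat_time  # full width at half amplitude
    centre = ev.start_time + ev.ramp_time + 0.5 * ev.flat_time
    # trapezoid = rect(width_mid) convolved with unit-area rect(ramp_time)
    mag = ev.amplitude * width_mid * np.sinc(freqs * width_mid)
    if ev.ramp_time > 0:
        mag = mag * np.sinc(freqs * ev.ramp_time)
    return mag * np.exp(-2j * np.pi * freqs * centre)


def _sampled_coefficients(ev: GradientEvent, freqs: np.ndarray) -> np.ndarray:
    assert ev.samples is not None and ev.sample_dt is not None
    t = ev.start_time + ev.sample_dt * np.arange(ev.samples.size)
    phase = np.exp(-2j * np.pi * np.outer(freqs, t))
    return phase @ ev.samples * ev.sample_dt


def gradient_spectrum(seq: SequenceModel) -> GradientSpectrum:
    """Fourier-series peak phasors of the periodic per-channel gradient waveform.

    One TR is the periodic unit; harmonics are computed up to
    ``SPECTRUM_MAX_FREQUENCY`` and the list is truncated (by increasing
    frequency) once the cumulative f^2-weighted energy reaches
    ``SPECTRUM_ENERGY_FRACTION`` of the computed total.  An empty or
    all-zero waveform yields an empty spectrum.
    """
    events = [e for e in seq.gradient_events if _event_is_nonzero(e)]
    if not events:
        return GradientSpectrum(np.empty(0), np.empty((0, 3)))
    n_harm = int(math.floor(SPECTRUM_MAX_FREQUENCY * seq.TR))
    if n_harm < 1:
        return GradientSpectrum(np.empty(0), np.empty((0, 3)))
    freqs = np.arange(1, n_harm + 1) / seq.TR
    coeff = np.zeros((n_harm, 3), dtype=complex)
    for ev in events:
        if ev.kind == "trapezoid":
            contrib = _trapezoid_coefficients(ev, freqs)
        else:
            contrib = _sampled_coefficients(ev, freqs)
        coeff[:, ev.channel.index] += contrib
    coeff *= 2.0 / seq.TR  # series coefficient = (2/TR) * windowed FT
    weight = freqs**2 * np.sum(np.abs(coeff) ** 2, axis=1)
    total = float(np.sum(weight))
    if total == 0.0:
        return GradientSpectrum(np.empty(0), np.empty((0, 3)))
    cum = np.cumsum(weight) / total
    keep = int(np.searchsorted(cum, SPECTRUM_ENERGY_FRACTION) + 1)
    keep = min(keep, n_harm)
    return GradientSpectrum(freqs[:keep], coeff[:keep])


def _event_is_nonzero(ev: GradientEvent) -> bool:
    if ev.kind == "trapezoid":
        return ev.amplitude != 0.0 and (ev.ramp_time > 0 or ev.flat_time > 0)
    assert ev.samples is not None
    return bool(np.any(ev.samples != 0.0))
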