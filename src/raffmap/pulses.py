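"""RAFF2 pulse synthesis and rotating-frame field geometry.

RAFF2 (Relaxation Along a Fictitious Field in the 2nd rotating frame)
preparation pulses are amplitude- and frequency-modulated RF pulses driven in
a sub-adiabatic regime.  The amplitude modulation is a rectified sine and the
frequency modulation a cosine of equal peak amplitude ``omega1max``::

    omega1(t)      = omega1max * |sin(omega1max*t + phi0)|
    delta_omega(t) = omega1max *  cos(omega1max*t + phi0)

The frequency modulation is played out on the scanner as a phase modulation,
the running integral of ``delta_omega``.  Because the AM and FM envelopes are
a sine/cosine pair of equal amplitude, the effective field in the first
rotating frame has constant magnitude ``omega1max`` and sweeps its tilt angle
at the constant rate ``omega1max``; in the doubly rotating frame the
(effective + fictitious) field is therefore stationary with magnitude
``sqrt(2)*omega1max``.  Magnetization precessing about that stationary field
relaxes with the characteristic time TRAFF2.

Public interfaces use Hz for field amplitudes and seconds for time; arrays
carry rad/s internally (``Waveform``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson

TWO_PI = 2.0 * math.pi


class ConfigurationError(ValueError):
    """Invalid pulse or protocol configuration."""


def default_duration(f1max: float) -> float:
    """Default single-pulse duration in seconds: ``sqrt(2)/f1max``.

    This is the duration over which the doubly-rotating-frame effective field
    (magnitude ``sqrt(2)*f1max`` Hz) accumulates exactly two full revolutions
    (4*pi rad) of precession.  At f1max = 625 Hz it evaluates to 2.26 ms.
    """
    if f1max <= 0:
        raise ConfigurationError(f"f1max must be positive, got {f1max}")
    return math.sqrt(2.0) / f1max


@dataclass(frozen=True)
class PulseConfig:
    """Configuration of a single RAFF2 pulse.

    Parameters
    ----------
    f1max : float
        Peak RF pulse frequency omega1max/2pi in Hz.
    phi0 : float
        Initial phase of the AM/FM pair in radians.
    duration : float, optional
        Single-pulse duration in seconds.  If omitted, the two-revolution
        convention ``sqrt(2)/f1max`` is used.
    n_samples : int
        Samples per pulse (>= 16).
    b1_scale : float
        Transmit-field scaling eta1 in (0, 2].  Applied to the AM function
        only: a miscalibrated transmit gain scales the achieved B1 amplitude
        but not the digitally synthesized phase ramp.
    """

    f1max: float
    phi0: float = 0.0
    duration: float | None = None
    n_samples: int = 256
    b1_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.f1max <= 0:
            raise ConfigurationError(f"f1max must be positive, got {self.f1max}")
        if self.duration is not None and self.duration <= 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if int(self.n_samples) < 16:
            raise ConfigurationError(f"n_samples must be >= 16, got {self.n_samples}")
        if not (0.0 < self.b1_scale <= 2.0):
            raise ConfigurationError(f"b1_scale must be in (0, 2], got {self.b1_scale}")

    @property
    def omega1max(self) -> float:
        """Peak pulse amplitude in rad/s."""
        return TWO_PI * self.f1max

    @property
    def duration_s(self) -> float:
        return self.duration if self.duration is not None else default_duration(self.f1max)

    def replace(self, **kw) -> "PulseConfig":
        d = dict(
            f1max=self.f1max, phi0=self.phi0, duration=self.duration,
            n_samples=self.n_samples, b1_scale=self.b1_scale,
        )
        d.update(kw)
        return PulseConfig(**d)


@dataclass
class Waveform:
    """A sampled RF pulse.

    Attributes
    ----------
    t : ndarray
        Time samples in seconds, strictly increasing, ``t[0] == 0``.
    omega1 : ndarray
        RF amplitude omega1(t) in rad/s, non-negative.
    delta_omega : ndarray
        Frequency modulation in rad/s.
    phase : ndarray
        Phase modulation in radians, ``phase[0] == 0`` (integral of
        ``delta_omega`` from 0).
    omega1max_nominal : float, optional
        Nominal (unscaled) peak amplitude in rad/s; used as the power
        reference when the AM function is B1-scaled.
    am_sign : ndarray, optional
        Sign of the un-rectified AM function at each sample, carrying the
        sweep direction through the |sin| rectification.
    """

    t: np.ndarray
    omega1: np.ndarray
    delta_omega: np.ndarray
    phase: np.ndarray
    omega1max_nominal: float | None = None
    am_sign: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.delta_omega = np.asarray(self.delta_omega, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        n = self.t.size
        if not (self.omega1.size == self.delta_omega.size == self.phase.size == n):
            raise ValueError("waveform arrays must share one length")
        if n < 2 or self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing with t[0] == 0")
        if np.any(self.omega1 < 0):
            raise ValueError("omega1 must be non-negative (rectified AM)")
        if self.phase[0] != 0.0:
            raise ValueError("phase[0] must be 0")

    @classmethod
    def from_fm(cls, t, omega1, delta_omega, **kw) -> "Waveform":
        """Build a waveform from an FM definition.

        The phase modulation is the running integral of ``delta_omega``
        (composite Simpson), anchored at ``phase[0] = 0``.
        """
        t = np.asarray(t, dtype=float)
        delta_omega = np.asarray(delta_omega, dtype=float)
        phase = cumulative_simpson(delta_omega, x=t, initial=0.0)
        return cls(t=t, omega1=np.asarray(omega1, float), delta_omega=delta_omega,
                   phase=phase, **kw)

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


def make_raff2_pulse(config: PulseConfig) -> Waveform:
    """Synthesize a single RAFF2 pulse from its sine/cosine AM-FM definition."""
    w1 = config.omega1max
    t = np.linspace(0.0, config.duration_s, int(config.n_samples))
    x = w1 * t + config.phi0
    s = np.sin(x)
    omega1 = config.b1_scale * w1 * np.abs(s)
    delta_omega = w1 * np.cos(x)
    sign = np.sign(s)
    return Waveform.from_fm(t, omega1, delta_omega,
                            omega1max_nominal=w1, am_sign=sign)


def make_raff2_composite(config: PulseConfig) -> Waveform:
    """Synthesize a self-refocusing RAFF2 pulse element (P followed by P^-1).

    The first half of the element is the plain sine/cosine AM-FM segment;
    the second half is its time-reversed, phase-inverted counterpart
    (amplitude mirrored, frequency sweep negated, RF phase offset by pi).
    On resonance the second half exactly undoes the coherent rotation of
    the first for any transmit scaling, so magnetization returns to its
    initial orientation and only relaxation accumulates across a spoiled
    pulse train; a static B0 offset breaks the cancellation, which is the
    origin of the off-resonance sensitivity of TRAFF2 maps.  Total duration
    and RF power match the plain element.
    """
    w1 = config.omega1max
    tau = config.duration_s / 2.0
    m = max(int(config.n_samples) // 2, 16) + 1
    t1 = np.linspace(0.0, tau, m)
    x = w1 * t1 + config.phi0
    s = np.sin(x)
    omega1_1 = config.b1_scale * w1 * np.abs(s)
    delta_1 = w1 * np.cos(x)
    phase_1 = cumulative_simpson(delta_1, x=t1, initial=0.0)
    sign_1 = np.sign(s)

    t2 = tau + t1[1:]
    omega1_2 = omega1_1[::-1][1:]
    delta_2 = -delta_1[::-1][1:]
    phase_2 = phase_1[::-1][1:] + math.pi
    sign_2 = sign_1[::-1][1:]

    return Waveform(
        t=np.concatenate([t1, t2]),
        omega1=np.concatenate([omega1_1, omega1_2]),
        delta_omega=np.concatenate([delta_1, delta_2]),
        phase=np.concatenate([phase_1, phase_2]),
        omega1max_nominal=w1,
        am_sign=np.concatenate([sign_1, sign_2]),
    )


@dataclass
class PrepTrain:
    """An ordered RAFF2 preparation block: pulses with spoiler gaps between.

    The total duration (the abscissa of the three-parameter signal model) is
    ``n_pulses * pulse_duration + (n_pulses - 1) * spoiler_duration``:
    spoilers sit strictly between consecutive pulses.
    """

    pulses: list
    spoiler_duration: float

    def __post_init__(self) -> None:
        if len(self.pulses) < 1:
            raise ConfigurationError("a preparation train needs at least one pulse")
        if self.spoiler_duration < 0:
            raise ConfigurationError("spoiler_duration must be >= 0")

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def pulse_duration(self) -> float:
        return self.pulses[0].duration

    @property
    def total_duration(self) -> float:
        n = self.n_pulses
        return n * self.pulse_duration + (n - 1) * self.spoiler_duration


def assemble_prep_train(pulse: Waveform, n_pulses: int, spoiler_duration: float) -> PrepTrain:
    """Assemble ``n_pulses`` identical RAFF2 pulses interleaved with spoilers."""
    if n_pulses < 1:
        raise ConfigurationError(f"n_pulses must be >= 1, got {n_pulses}")
    return PrepTrain(pulses=[pulse] * int(n_pulses), spoiler_duration=float(spoiler_duration))


@dataclass
class FieldTrajectory:
    """Rotating-frame field geometry along a pulse.

    ``b_eff_mag`` is the first-rotating-frame effective field magnitude in
    Hz; ``alpha`` its (unwrapped, continuous) tilt angle from z in radians;
    ``sweep_rate`` = d(alpha)/dt in rad/s; ``e_field_mag`` the
    doubly-rotating-frame effective field (including the fictitious
    component from the sweep) in Hz.
    """

    t: np.ndarray
    b_eff_mag: np.ndarray
    alpha: np.ndarray
    sweep_rate: np.ndarray
    e_field_mag: np.ndarray


def _infer_am_sign(omega1: np.ndarray) -> np.ndarray:
    """Alternating sign across |sin| rectification points (near-zero local minima)."""
    n = omega1.size
    peak = float(np.max(omega1))
    sign = np.ones(n)
    if peak == 0:
        return sign
    flips = [
        i for i in range(1, n - 1)
        if omega1[i] <= omega1[i - 1] and omega1[i] <= omega1[i + 1]
        and omega1[i] < 0.05 * peak
    ]
    cur = 1.0
    prev = 0
    for i in flips:
        sign[prev:i] = cur
        cur = -cur
        prev = i
    sign[prev:] = cur
    return sign


def field_trajectory(wf: Waveform, delta_omega0: float = 0.0) -> FieldTrajectory:
    """Compute effective-field geometry for a waveform at B0 offset ``delta_omega0`` (Hz).

    The tilt angle is made continuous by carrying the sweep direction through
    the AM rectification (the sign of the un-rectified sine); numerical
    differentiation of alpha is stable for n_samples >= 64.
    """
    off = TWO_PI * float(delta_omega0)
    bz = wf.delta_omega + off
    b_eff = np.hypot(wf.omega1, bz) / TWO_PI
    sign = wf.am_sign if wf.am_sign is not None else _infer_am_sign(wf.omega1)
    sign = np.where(sign == 0, 1.0, sign)
    alpha = np.unwrap(np.arctan2(sign * wf.omega1, bz))
    sweep = np.gradient(alpha, wf.t)
    e_mag = np.hypot(TWO_PI * b_eff, sweep) / TWO_PI
    return FieldTrajectory(t=wf.t, b_eff_mag=b_eff, alpha=alpha,
                           sweep_rate=sweep, e_field_mag=e_mag)


def rf_power_fraction(wf: Waveform, omega1max: float | None = None) -> float:
    """Time-averaged ``(omega1/omega1max)**2`` over the pulse.

    This is the B1-power part of the SAR comparison between a RAFF2 train and
    a continuous-wave train of equal peak amplitude: for the sine AM averaged
    over an integer number of half-periods it equals 0.5, while a
    constant-amplitude pulse at ``omega1max`` gives 1.0.

    ``omega1max`` defaults to the waveform's nominal peak amplitude (so a
    B1-scaled pulse is referenced to the nominal amplitude), else to the
    realized maximum.
    """
    ref = omega1max
    if ref is None:
        ref = wf.omega1max_nominal
    if ref is None:
        ref = float(np.max(wf.omega1))
    if ref == 0 or not np.any(wf.omega1):
        return 0.0
    frac = (wf.omega1 / ref) ** 2
    span = wf.t[-1] - wf.t[0]
    return float(np.trapezoid(frac, wf.t) / span)


def waveform_to_csv(wf: Waveform, path) -> None:
    """Export a waveform as 3-column CSV (t_s, omega1_hz, phase_rad)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "omega1_hz", "phase_rad"])
        for ti, wi, pi in zip(wf.t, wf.omega1 / TWO_PI, wf.phase):
            writer.writerow([repr(float(ti)), repr(float(wi)), repr(float(pi))])


def waveform_from_csv(path) -> Waveform:
    """Read a waveform written by :func:`waveform_to_csv`."""
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    t, f1_hz, phase = data[:, 0], data[:, 1], data[:, 2]
    omega1 = TWO_PI * f1_hz
    # recover delta_omega = d(phase)/dt for completeness
    delta_omega = np.gradient(phase, t)
    return Waveform(t=t, omega1=omega1, delta_omega=delta_omega, phase=phase)
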