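"""The four target distortions, the anchor recipe, and THD metrology.

Distortion kinds and their control parameters (detection/discrimination
staircase schedules and suprathreshold low/high amounts) follow the
study's experimental parameter table:

* spectral ripple — sinusoidal spectral-envelope modulation on a log-f
  axis, 10 periods between 50 Hz and 16 kHz (~1.2 ripples/octave);
  amount = peak-to-valley ratio in dB.
* nonlinear saturation — memoryless soft clipper y = x - a*x^3, input
  limited to +-1/sqrt(3a) where the cubic's slope reaches zero; amount =
  dimensionless weight a (alpha).
* intensity — broadband gain in dB relative to the reference.
* spatial — azimuth offset of the target source in degrees (rendered by
  the room-acoustics module).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .signals import RATE, AudioSignal

RIPPLE_N_PERIODS = 10
RIPPLE_F_LO = 50.0
RIPPLE_F_HI = 16000.0

ANCHOR_LOWPASS_HZ = 3500.0
ANCHOR_ALPHA = 0.55
ANCHOR_AZIMUTH_DEG = 40.0

DISTORTION_KINDS = ("ripple", "saturation", "intensity", "spatial")

#: Printed (alpha, THD@peak %) pairs for the saturating nonlinearity.
ALPHA_THD_PAIRS = [
    (0.11, 15.3),
    (0.175, 21.4),
    (0.18, 22.1),
    (0.22, 24.5),
    (0.37, 29.7),
    (0.44, 31.2),
    (0.45, 31.4),
]


@dataclass(frozen=True)
class DistortionSpec:
    """One distortion kind with its scalar amount in printed units."""

    kind: str
    amount: float

    def __post_init__(self):
        if self.kind not in DISTORTION_KINDS:
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if not np.isfinite(self.amount):
            raise ValueError("amount must be finite")
        if self.kind in ("ripple", "saturation") and self.amount < 0:
            raise ValueError(f"{self.kind} amount must be >= 0")
        if self.kind == "spatial" and not 0.0 <= self.amount <= 90.0:
            raise ValueError("azimuth must lie in [0, 90] degrees")


@dataclass(frozen=True)
class THDResult:
    """Total harmonic distortion of a saturated sinusoid.

    ``thd_percent`` uses the primary fundamental-referenced convention
    (harmonic RMS over fundamental RMS); ``thd_total_percent`` is the
    total-referenced variant (harmonic RMS over total RMS).
    """

    thd_percent: float
    thd_total_percent: float
    amplitude: float
    convention: str = "fundamental"


# ---------------------------------------------------------------- ripple

def ripple_density_per_octave(n_periods: float, f_lo: float, f_hi: float) -> float:
    """Spectral-ripple density: periods per octave across [f_lo, f_hi]."""
    if not (f_hi > f_lo > 0):
        raise ValueError("need f_hi > f_lo > 0")
    return n_periods / np.log2(f_hi / f_lo)


def ripple_gain_db(f: np.ndarray, depth_db: float) -> np.ndarray:
    """Log-magnitude of the ripple filter in dB at frequencies ``f``.

    Cosine in log2(f) with a gain maximum at 50 Hz, exactly 10 periods up
    to 16 kHz, peak-to-valley ``depth_db``; unity gain outside the band.
    """
    f = np.asarray(f, dtype=np.float64)
    g = np.zeros_like(f)
    band = (f >= RIPPLE_F_LO) & (f <= RIPPLE_F_HI)
    phase = (
        2.0 * np.pi * RIPPLE_N_PERIODS
        * np.log2(f[band] / RIPPLE_F_LO)
        / np.log2(RIPPLE_F_HI / RIPPLE_F_LO)
    )
    g[band] = 0.5 * depth_db * np.cos(phase)
    return g


def apply_spectral_ripple(signal: AudioSignal, depth_db: float) -> AudioSignal:
    """Zero-phase FFT-domain spectral-ripple filter of given depth (dB)."""
    if depth_db < 0:
        raise ValueError("ripple depth must be >= 0")
    n = signal.n_samples
    f = np.fft.rfftfreq(n, d=1.0 / signal.rate)
    gain = 10.0 ** (ripple_gain_db(f, depth_db) / 20.0)

    def _filt(x):
        return np.fft.irfft(np.fft.rfft(x) * gain, n=n)

    x = signal.samples
    y = _filt(x) if x.ndim == 1 else np.stack([_filt(x[:, c]) for c in range(x.shape[1])], axis=1)
    return replace(signal, samples=y)


# ------------------------------------------------------------ saturation

def saturation_limit(alpha: float) -> float:
    """Input magnitude x_c = 1/sqrt(3*alpha) where the cubic saturates."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return 1.0 / np.sqrt(3.0 * alpha)


def saturate(x: np.ndarray, alpha: float) -> np.ndarray:
    """Memoryless soft clipper y = x - alpha*x^3, flat beyond +-x_c."""
    xc = saturation_limit(alpha)
    y = x - alpha * x**3
    return np.where(np.abs(x) > xc, np.sign(x) * (2.0 / 3.0) * xc, y)


def apply_saturation(signal: AudioSignal, alpha: float) -> AudioSignal:
    """Apply the saturating nonlinearity channel-wise."""
    return replace(signal, samples=saturate(signal.samples, alpha))


def thd_small_signal_percent(alpha: float, amplitude: float) -> float:
    """Closed-form THD of the pure cubic (no clipping engaged).

    For x = A sin(wt):  y = (A - 3aA^3/4) sin(wt) + (aA^3/4) sin(3wt),
    so THD = 100 * (aA^2/4) / (1 - 3aA^2/4) %.  Valid while A <= x_c.
    """
    u = alpha * amplitude**2
    return 100.0 * (u / 4.0) / (1.0 - 3.0 * u / 4.0)


def thd_at_peak(alpha: float, amplitude: float, f0: float = 441.0) -> THDResult:
    """THD of a sinusoid of given peak amplitude through the soft clipper.

    Computed from one second of steady state (an integer number of
    periods at 44.1 kHz), reading harmonic magnitudes off exact FFT bins.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    n = RATE
    t = np.arange(n) / RATE
    y = saturate(amplitude * np.sin(2.0 * np.pi * f0 * t), alpha)
    spec = np.abs(np.fft.rfft(y)) / n
    k0 = int(round(f0 * n / RATE))
    fund = spec[k0]
    ks = np.arange(2 * k0, n // 2 + 1, k0)
    harm = np.sqrt(np.sum(spec[ks] ** 2))
    return THDResult(
        thd_percent=100.0 * harm / fund,
        thd_total_percent=100.0 * harm / np.sqrt(fund**2 + harm**2),
        amplitude=amplitude,
    )


def calibrate_peak_amplitude(
    pairs: list[tuple[float, float]], convention: str = "fundamental"
) -> float:
    """Peak sinusoid amplitude A* consistent with printed (alpha, THD%) pairs.

    For a single pair the mapping is inverted exactly (THD is monotone in
    amplitude); for several pairs A* minimizes the summed squared THD
    residual.  Searched on (0, 10] full scale.
    """
    if not pairs:
        raise ValueError("need at least one (alpha, thd) pair")

    def predicted(a, amp):
        r = thd_at_peak(a, amp)
        return r.thd_percent if convention == "fundamental" else r.thd_total_percent

    if len(pairs) == 1:
        a, thd = pairs[0]
        return brentq(lambda amp: predicted(a, amp) - thd, 1e-3, 10.0)

    amps = np.linspace(0.05, 10.0, 400)
    cost = [
        sum((predicted(a, amp) - thd) ** 2 for a, thd in pairs) for amp in amps
    ]
    amp0 = amps[int(np.argmin(cost))]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda amp: sum((predicted(a, amp) - thd) ** 2 for a, thd in pairs),
        bracket=(max(amp0 - 0.1, 1e-3), amp0, min(amp0 + 0.1, 10.0)),
    )
    return float(res.x)


# ------------------------------------------------------------- intensity

def apply_intensity(signal: AudioSignal, delta_db: float) -> AudioSignal:
    """Broadband gain of delta_db dB relative to the reference signal."""
    if not np.isfinite(delta_db):
        raise ValueError("delta must be finite")
    return replace(signal, samples=signal.samples * 10.0 ** (delta_db / 20.0))


# ---------------------------------------------------------------- anchor

def anchor_lowpass(signal: AudioSignal) -> AudioSignal:
    """8th-order Butterworth low-pass at 3.5 kHz (anchor stage 1)."""
    sos = sps.butter(8, ANCHOR_LOWPASS_HZ, btype="low", fs=signal.rate, output="sos")
    x = signal.samples
    y = sps.sosfilt(sos, x, axis=0)
    return replace(signal, samples=y)


def make_anchor(signal: AudioSignal, room=None, placement=None) -> AudioSignal:
    """Strongly degraded anchor: 3.5 kHz low-pass, saturation (alpha=0.55),
    and, when a room/placement is given, spatial rendering at 40 degrees
    azimuth.  Without a scene the first two (monaural) stages are applied.
    """
    out = apply_saturation(anchor_lowpass(signal), ANCHOR_ALPHA)
    if room is not None and placement is not None:
        from . import room_acoustics as ra

        pl = ra.with_target_azimuth(placement, ANCHOR_AZIMUTH_DEG)
        out = ra.render_scene(room, pl, [(out, "target")])
    return out
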