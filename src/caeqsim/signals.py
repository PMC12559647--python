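"""Target and masker waveform generation, calibration and trial timing.

All study stimuli are sampled at 44.1 kHz.  Levels are expressed in dB SPL
under a fixed digital calibration convention: a full-scale sinusoid
(peak 1.0) corresponds to ``FULLSCALE_SINE_DB_SPL`` = 100 dB SPL.  The
constant is arbitrary — every quantity in the pipeline is a level
difference — but it is fixed so that dB SPL numbers are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile as _wavfile

RATE = 44100
FULLSCALE_SINE_DB_SPL = 100.0
#: RMS of a full-scale sinusoid; the reference RMS for the SPL convention.
_REF_RMS = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform with a dB SPL calibration convention.

    ``samples`` has shape ``(n,)`` for mono or ``(n, 2)`` for binaural
    signals, in full-scale units.  ``calibration`` is the dB SPL produced
    by a full-scale sinusoid.
    """

    samples: np.ndarray
    rate: int = RATE
    calibration: float = FULLSCALE_SINE_DB_SPL

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim not in (1, 2) or (s.ndim == 2 and s.shape[1] not in (1, 2)):
            raise ValueError("samples must be (n,) or (n, 1|2)")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def rms(self) -> float:
        """Broadband RMS over all channels."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def level_db_spl(self) -> float:
        """Broadband level in dB SPL under the calibration convention."""
        r = self.rms()
        if r == 0.0:
            raise ValueError("level of an all-zero signal is undefined")
        return self.calibration + 20.0 * np.log10(r / _REF_RMS)


def _check_duration(duration_s: float) -> int:
    if not duration_s > 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    return int(round(duration_s * RATE))


def generate_pink_noise(duration_s: float, seed: int) -> AudioSignal:
    """Stationary pink noise, 10 Hz – 22.05 kHz, unit RMS.

    Realized by FFT-domain 1/sqrt(f) magnitude shaping of Gaussian white
    noise so that power spectral density falls as 1/f across the passband
    (equal energy per octave).  Deterministic for a fixed seed.
    """
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / RATE)
    shape = np.zeros_like(f)
    band = (f >= 10.0) & (f <= RATE / 2)
    shape[band] = 1.0 / np.sqrt(f[band])
    x = np.fft.irfft(spec * shape, n=n)
    x /= np.sqrt(np.mean(x**2))
    return AudioSignal(x)


def generate_speech_surrogate(
    duration_s: float, seed: int, modulation_depth: float = 1.0
) -> AudioSignal:
    """Speech-like target: narrowband carrier with ~5 Hz envelope modulation.

    A stand-in for a recorded female speech target.  The carrier is
    100 Hz – 8 kHz noise with a speech-shaped spectral tilt (flat to
    500 Hz, −6 dB/octave above), amplitude-modulated by a slow positive
    envelope whose modulation spectrum peaks near 5 Hz.
    ``modulation_depth`` = 0 yields a stationary output.
    """
    n = _check_duration(duration_s)
    rng = np.random.default_rng(seed)

    # speech-shaped carrier via FFT magnitude shaping
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / RATE)
    shape = np.zeros_like(f)
    band = (f >= 100.0) & (f <= 8000.0)
    tilt = np.ones_like(f)
    hi = f > 500.0
    tilt[hi] = 500.0 / f[hi]  # -6 dB/octave above 500 Hz
    shape[band] = tilt[band]
    carrier = np.fft.irfft(spec * shape, n=n)
    carrier /= np.sqrt(np.mean(carrier**2))

    # slow envelope: modulator noise band-passed 2-8 Hz (peak near 5 Hz)
    mod_spec = np.fft.rfft(rng.standard_normal(n))
    mod_band = (f >= 2.0) & (f <= 8.0)
    mod_shape = np.zeros_like(f)
    mod_shape[mod_band] = 1.0
    m = np.fft.irfft(mod_spec * mod_shape, n=n)
    if np.std(m) > 0:
        m = m / np.std(m)
    env = np.maximum(1.0 + modulation_depth * 0.5 * m, 0.0)

    x = carrier * env
    x /= np.sqrt(np.mean(x**2))
    return AudioSignal(x)


def set_level(signal: AudioSignal, level_db_spl: float) -> AudioSignal:
    """Scale a signal so its broadband RMS sits at ``level_db_spl``."""
    current = signal.level_db_spl()  # raises on silence
    gain = 10.0 ** ((level_db_spl - current) / 20.0)
    return replace(signal, samples=signal.samples * gain)


def apply_raised_cosine_ramps(signal: AudioSignal, ramp_ms: float) -> AudioSignal:
    """Apply raised-cosine on/off ramps of ``ramp_ms`` milliseconds."""
    if ramp_ms < 0:
        raise ValueError("ramp must be non-negative")
    n_ramp = int(round(ramp_ms * 1e-3 * signal.rate))
    if n_ramp == 0:
        return signal
    if 2 * n_ramp >= signal.n_samples:
        raise ValueError("ramps longer than half the signal")
    # half-cosine rising from 0 to 1; gain at the ramp midpoint is 0.5
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    win = np.ones(signal.n_samples)
    win[:n_ramp] = ramp
    win[-n_ramp:] = ramp[::-1]
    if signal.samples.ndim == 2:
        win = win[:, None]
    return replace(signal, samples=signal.samples * win)


def schedule_trial(
    target: AudioSignal, maskers: list[AudioSignal], mode: str
) -> AudioSignal:
    """Time-align target and maskers and sum them into the trial mixture.

    ``mode='rating'``: maskers lead the target by 0.5 s (quality-rating
    sessions).  ``mode='detection'``: all sources start simultaneously.
    """
    if mode not in ("detection", "rating"):
        raise ValueError(f"unknown mode {mode!r}")
    for m in maskers:
        if m.rate != target.rate:
            raise ValueError("sampling-rate mismatch between target and masker")
    offset = 0 if mode == "detection" else int(round(0.5 * target.rate))
    if mode == "rating":
        for m in maskers:
            if m.duration < target.duration:
                raise ValueError("rating-mode maskers must cover the target")
    sigs = [(target, offset)] + [(m, 0) for m in maskers]
    channels = max(s.channels for s, _ in sigs)
    total = max(off + s.n_samples for s, off in sigs)
    out = np.zeros((total, channels)) if channels == 2 else np.zeros(total)
    for s, off in sigs:
        x = s.samples
        if channels == 2 and x.ndim == 1:
            x = np.stack([x, x], axis=1)
        out[off : off + s.n_samples] += x
    return AudioSignal(out, rate=target.rate, calibration=target.calibration)


def snr_db(target: AudioSignal, maskers: list[AudioSignal]) -> float:
    """Signal-to-noise ratio in dB: target power over summed masker power.

    Powers are long-term mean-square values over each source's own support
    (the target's support in a trial), so the result is independent of the
    0.5 s masker lead in rating mode.
    """
    if not maskers:
        raise ValueError("at least one masker required")
    p_t = np.mean(np.square(target.samples))
    p_m = sum(np.mean(np.square(m.samples)) for m in maskers)
    if p_m == 0.0:
        raise ValueError("silent maskers: SNR undefined")
    return float(10.0 * np.log10(p_t / p_m))


def draw_detection_segment(
    parent: AudioSignal, segment_s: float, seed: int
) -> AudioSignal:
    """Seed-deterministic 1-s-style segment draw from a longer parent.

    Detection-experiment targets are short segments selected per trial
    from a 2 s parent recording.
    """
    n_seg = int(round(segment_s * parent.rate))
    if n_seg > parent.n_samples:
        raise ValueError("segment longer than parent")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, parent.n_samples - n_seg + 1))
    return replace(parent, samples=parent.samples[start : start + n_seg].copy())


def write_wav(path, signal: AudioSignal) -> None:
    """Write a signal as 32-bit float RIFF WAV."""
    _wavfile.write(path, signal.rate, signal.samples.astype(np.float32))


def read_wav(path, calibration: float = FULLSCALE_SINE_DB_SPL) -> AudioSignal:
    """Read a RIFF WAV (PCM 16/24-bit or float) into an AudioSignal."""
    rate, data = _wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, rate=rate, calibration=calibration)
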