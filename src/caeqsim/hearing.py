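"""Audiogram handling, NAL-R linear compensation, and pure-tone averages.

Hearing loss is characterized by per-ear audiograms in dB HL at the
audiometric frequencies 125 Hz - 6 kHz.  Compensation follows the NAL-R
linear prescription: insertion gain at frequency f is

    G_f = X + 0.31 * HTL_f + k_f,    X = 0.05 * (HTL_500 + HTL_1000 + HTL_2000)

with the standard per-frequency constants k_f, floored at 0 dB.  Very
mild and moderate sensorineural losses are represented by the Bisgaard
N1 and N3 standard audiogram profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import AudioSignal

AUDIOMETRIC_FREQS = (125, 250, 500, 1000, 2000, 3000, 4000, 6000)
PTA_FREQS = (500, 1000, 2000, 4000)

#: NAL-R per-frequency constants k_f (dB), from the standard prescription.
NAL_R_K = {250: -17.0, 500: -8.0, 1000: 1.0, 1500: 1.0,
           2000: -1.0, 3000: -2.0, 4000: -2.0, 6000: -2.0}

#: Bisgaard standard audiogram profiles (dB HL) at AUDIOMETRIC_FREQS;
#: N1 = very mild, N3 = moderate sensorineural loss.  125 Hz extended
#: flat from 250 Hz.
BISGAARD_PROFILES = {
    "N1": {125: 10, 250: 10, 500: 10, 1000: 10, 2000: 15, 3000: 20,
           4000: 30, 6000: 40},
    "N3": {125: 35, 250: 35, 500: 35, 1000: 45, 2000: 55, 3000: 60,
           4000: 65, 6000: 70},
}

#: Comfortable-level offsets re the NAL-R based level, and the observed
#: cohort split 14:8:2 across {-5, 0, +5} dB.
COMFORT_OFFSETS = (-5.0, 0.0, 5.0)
COMFORT_SPLIT = (14, 8, 2)

MAX_INTERAURAL_ASYMMETRY_DB = 10.0


@dataclass(frozen=True)
class Audiogram:
    """Per-ear hearing levels in dB HL.

    ``left``/``right`` map frequency (Hz) -> threshold; all of
    AUDIOMETRIC_FREQS except 3000 Hz are required.
    """

    left: dict[int, float]
    right: dict[int, float]

    def __post_init__(self):
        required = [f for f in AUDIOMETRIC_FREQS if f != 3000]
        for ear in (self.left, self.right):
            missing = [f for f in required if f not in ear]
            if missing:
                raise ValueError(f"audiogram missing frequencies {missing}")
            for f, v in ear.items():
                if not -10.0 <= v <= 120.0:
                    raise ValueError(f"threshold {v} dB HL at {f} Hz out of range")

    def ear(self, which: str) -> dict[int, float]:
        if which not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        return self.left if which == "left" else self.right

    def max_asymmetry(self) -> float:
        common = sorted(set(self.left) & set(self.right))
        return max(abs(self.left[f] - self.right[f]) for f in common)


@dataclass(frozen=True)
class GainTable:
    """Insertion gain (dB) per audiometric frequency."""

    gains: dict[int, float]

    def __post_init__(self):
        if any(not np.isfinite(g) for g in self.gains.values()):
            raise ValueError("gains must be finite")


def nal_r_gains(audiogram: Audiogram, ear: str) -> GainTable:
    """NAL-R insertion gains for one ear, floored at 0 dB."""
    htl = audiogram.ear(ear)
    for f in (500, 1000, 2000, 4000):
        if f not in htl:
            raise ValueError(f"audiogram must cover {f} Hz for NAL-R")
    x = 0.05 * (htl[500] + htl[1000] + htl[2000])
    gains = {}
    for f, k in NAL_R_K.items():
        if f not in htl:
            continue
        gains[f] = max(0.0, x + 0.31 * htl[f] + k)
    return GainTable(gains)


def _design_gain_fir(gains: dict[int, float], rate: int, n_taps: int = 512) -> np.ndarray:
    """Minimum-phase FIR matching the gain table at audiometric frequencies.

    The gain table is interpolated on a log-frequency axis (held constant
    beyond its edges) and turned into a minimum-phase impulse response by
    the real-cepstrum method.
    """
    n_fft = 4096
    freqs = np.array(sorted(gains))
    vals = np.array([gains[f] for f in freqs])
    grid = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    logf = np.log10(np.maximum(grid, 1.0))
    interp_db = np.interp(logf, np.log10(freqs), vals)
    log_mag = interp_db * np.log(10.0) / 20.0
    # fold the real cepstrum to obtain the minimum-phase spectrum
    cep = np.fft.irfft(log_mag, n=n_fft)
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1 : n_fft // 2] = 2.0 * cep[1 : n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    h_min = np.fft.irfft(np.exp(np.fft.rfft(fold)), n=n_fft)
    return h_min[:n_taps]


def apply_compensation(
    signal: AudioSignal, gains: GainTable, comfort_offset: float = 0.0
) -> AudioSignal:
    """Filter a signal through the NAL-R gain shape plus a comfort offset.

    ``comfort_offset`` is the listener-selected broadband adjustment in
    dB (one of -5, 0, +5 in the study) applied after the gain filter.
    For 2-channel input the same (single-ear) table is applied to both
    channels; call per ear with per-ear tables for binaural use.
    """
    if comfort_offset not in COMFORT_OFFSETS:
        raise ValueError(f"comfort offset must be one of {COMFORT_OFFSETS}")
    fir = _design_gain_fir(gains.gains, signal.rate)
    off = 10.0 ** (comfort_offset / 20.0)
    x = signal.samples
    if x.ndim == 1:
        y = sps.fftconvolve(x, fir)[: len(x)]
    else:
        y = np.stack(
            [sps.fftconvolve(x[:, c], fir)[: x.shape[0]] for c in range(x.shape[1])],
            axis=1,
        )
    from dataclasses import replace

    return replace(signal, samples=y * off)


def pta_better_ear(audiogram: Audiogram) -> float:
    """Better-ear pure-tone average over 0.5, 1, 2 and 4 kHz (dB HL)."""
    means = []
    for ear in ("left", "right"):
        htl = audiogram.ear(ear)
        missing = [f for f in PTA_FREQS if f not in htl]
        if missing:
            raise ValueError(f"{ear} ear missing PTA frequencies {missing}")
        means.append(np.mean([htl[f] for f in PTA_FREQS]))
    return float(min(means))


def generate_audiogram(profile: str, seed: int, jitter_db: float = 5.0) -> Audiogram:
    """Synthetic audiogram: Bisgaard prototype with seeded +-jitter noise.

    Each ear receives independent uniform jitter within +-jitter_db per
    frequency, which bounds the interaural asymmetry by 2*jitter_db
    (<= 10 dB at the default), matching the study's inclusion criterion.
    """
    if profile not in BISGAARD_PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    if jitter_db > MAX_INTERAURAL_ASYMMETRY_DB / 2:
        raise ValueError("jitter would violate the asymmetry bound")
    proto = BISGAARD_PROFILES[profile]
    rng = np.random.default_rng(seed)
    ears = []
    for _ in range(2):
        ears.append(
            {
                f: float(np.clip(v + rng.uniform(-jitter_db, jitter_db), -10, 120))
                for f, v in proto.items()
            }
        )
    return Audiogram(left=ears[0], right=ears[1])
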