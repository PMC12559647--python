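"""Binaural room impulse response synthesis and room metrology.

Two shoebox rooms are modelled after the study's listening scenes: a
living-room lab ("LRL", 4.97 x 3.78 x 2.71 m, average T60 0.5 s) and a
large room ("Large", 7.5 x 4.52 x 3 m, T60 1.5 s).  Early reflections up
to third order come from the image-source model with uniform wall
absorption solved from Eyring's formula to meet the target T60; the late
field is a feedback delay network (FDN, 8 mutually prime delay lines,
Householder feedback) whose decay rate is set exactly to the target T60
and whose energy follows diffuse-field theory (4/A).  Binaural cues use
a spherical-head model: Woodworth ITD and a first-order head-shadow
filter — a deliberate simplification relative to measured HRTFs, so
direct-to-reverberant ratios are meaningful only in their ordering
across rooms, not as absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signals import RATE, AudioSignal

SPEED_OF_SOUND = 343.0  # m/s
HEAD_RADIUS = 0.0875  # m
DIRECT_WINDOW_S = 2.5e-3  # half-width of the direct-sound window
DRR_CAP_DB = 50.0


@dataclass(frozen=True)
class RoomSpec:
    """Shoebox room with a target average reverberation time."""

    name: str
    length: float
    width: float
    height: float
    target_t60: float

    def __post_init__(self):
        if min(self.length, self.width, self.height) <= 0 or self.target_t60 <= 0:
            raise ValueError("room dimensions and T60 must be positive")

    @property
    def volume(self) -> float:
        return self.length * self.width * self.height

    @property
    def surface(self) -> float:
        l, w, h = self.length, self.width, self.height
        return 2.0 * (l * w + l * h + w * h)

    def eyring_absorption(self) -> float:
        """Uniform wall absorption coefficient meeting target_t60."""
        a = 1.0 - np.exp(-0.161 * self.volume / (self.surface * self.target_t60))
        if not 0 < a < 1:
            raise ValueError(f"unreachable T60 {self.target_t60} for {self.name}")
        return float(a)


LRL_ROOM = RoomSpec("LRL", 4.97, 3.78, 2.71, 0.5)
LARGE_ROOM = RoomSpec("Large", 7.5, 4.52, 3.0, 1.5)
ROOMS = {"LRL": LRL_ROOM, "Large": LARGE_ROOM}

MASKER_CONFIGS = ("0M", "1M_sep", "2M_co", "2M_sep")


@dataclass(frozen=True)
class Source:
    """Source placement relative to the receiver.

    Azimuth in degrees, 0 = frontal, positive to the listener's right.
    """

    azimuth_deg: float
    distance_m: float
    height_m: float


@dataclass(frozen=True)
class ScenePlacement:
    """Receiver and source layout for one scene.

    ``sources`` is a tuple of (label, Source); labels are "target",
    "masker_left" (speech-surrogate masker), "masker_right" (music-like
    masker).  ``masker_level_ref_distance`` triggers the LRL masker level
    reduction towards the target's reference distance.
    """

    room_name: str
    receiver_height: float
    sources: tuple[tuple[str, Source], ...]
    masker_config: str = "0M"
    masker_level_ref_distance: float | None = None

    def source(self, label: str) -> Source:
        for lab, src in self.sources:
            if lab == label:
                return src
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.sources)


def make_placement(
    room: RoomSpec, masker_config: str = "0M", target_azimuth: float = 0.0
) -> ScenePlacement:
    """Study scene layouts for either room.

    LRL: target at 2.55 m, maskers at 1.59 m, heights 1.05/1.10/1.02 m
    (receiver/target/maskers), masker levels referenced to 2.55 m.
    Large: everything at 2 m and 1.7 m height.  Separated maskers sit at
    -45 (speech) and +45 (music) degrees; co-located maskers share the
    target position.
    """
    if masker_config not in MASKER_CONFIGS:
        raise ValueError(f"unknown masker configuration {masker_config!r}")
    if room.name == "LRL":
        rec_h, tgt_h, msk_h = 1.05, 1.10, 1.02
        d_target, d_masker, ref = 2.55, 1.59, 2.55
    else:
        rec_h, tgt_h, msk_h = 1.7, 1.7, 1.7
        d_target = d_masker = 2.0
        ref = None
    target = Source(target_azimuth, d_target, tgt_h)
    sources = [("target", target)]
    if masker_config == "1M_sep":
        sources.append(("masker_left", Source(-45.0, d_masker, msk_h)))
    elif masker_config == "2M_sep":
        sources.append(("masker_left", Source(-45.0, d_masker, msk_h)))
        sources.append(("masker_right", Source(45.0, d_masker, msk_h)))
    elif masker_config == "2M_co":
        co = Source(target_azimuth, d_target, tgt_h)
        sources.append(("masker_left", co))
        sources.append(("masker_right", co))
    return ScenePlacement(
        room.name, rec_h, tuple(sources), masker_config, ref
    )


def with_target_azimuth(placement: ScenePlacement, azimuth_deg: float) -> ScenePlacement:
    """Copy of a placement with the target moved to a new azimuth."""
    new = tuple(
        (lab, replace(src, azimuth_deg=azimuth_deg) if lab == "target" else src)
        for lab, src in placement.sources
    )
    return replace(placement, sources=new)


@dataclass(frozen=True)
class BRIR:
    """Binaural impulse-response pair with direct-arrival indices."""

    left: np.ndarray
    right: np.ndarray
    rate: int
    direct_index_left: int
    direct_index_right: int

    def __post_init__(self):
        for h in (self.left, self.right):
            if not np.all(np.isfinite(h)):
                raise ValueError("impulse response must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.left)


# ----------------------------------------------------------- geometry

def _receiver_position(room: RoomSpec, placement: ScenePlacement) -> np.ndarray:
    """Receiver head centre; laterally offset 0.3 m for asymmetry.

    The receiver faces +x; "right" is the -y direction.
    """
    d_t = placement.source("target").distance_m
    x = (room.length - d_t) / 2.0
    y = room.width / 2.0 + 0.3
    return np.array([x, y, placement.receiver_height])


def _source_position(
    room: RoomSpec, placement: ScenePlacement, src: Source
) -> np.ndarray:
    rec = _receiver_position(room, placement)
    az = np.deg2rad(src.azimuth_deg)
    # facing +x, right = -y
    pos = rec + src.distance_m * np.array([np.cos(az), -np.sin(az), 0.0])
    pos[2] = src.height_m
    for lo, hi, v in zip((0, 0, 0), (room.length, room.width, room.height), pos):
        if not lo < v < hi:
            raise ValueError(
                f"source at {pos} lies outside room {room.name}"
            )
    return pos


def woodworth_itd(lateral_angle_rad: float) -> float:
    """Full interaural time difference for a spherical head (seconds)."""
    th = abs(lateral_angle_rad)
    return HEAD_RADIUS / SPEED_OF_SOUND * (th + np.sin(th))


def _ear_delay(sin_lat: float, ear_sign: int) -> float:
    """Per-ear path correction re head centre (ear_sign +1 = right)."""
    th = abs(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
    a_c = HEAD_RADIUS / SPEED_OF_SOUND
    if ear_sign * sin_lat >= 0:  # ipsilateral: ear leads
        return -a_c * np.sin(th)
    return a_c * th  # contralateral: ear lags


@lru_cache(maxsize=16)
def _shadow_kernel(alpha_q: float, rate: int) -> np.ndarray:
    """Impulse response of the first-order head-shadow filter.

    Brown-Duda single-pole/zero model H(s) = (alpha*s + b0)/(s + b0),
    b0 = 2c/a; alpha in [0, 2] (2 = ipsilateral boost, 0 = deep shadow).
    """
    b0 = 2.0 * SPEED_OF_SOUND / HEAD_RADIUS
    b, a = sps.bilinear([alpha_q, b0], [1.0, b0], fs=rate)
    x = np.zeros(64)
    x[0] = 1.0
    return sps.lfilter(b, a, x)


def _image_sources(room: RoomSpec, src_pos: np.ndarray, max_order: int = 3):
    """Yield (image position, reflection order) for orders <= max_order."""
    dims = (room.length, room.width, room.height)
    rng_l = range(-max_order, max_order + 1)
    for u in range(2):
        for v in range(2):
            for w in range(2):
                for lx in rng_l:
                    nx = abs(lx - u) + abs(lx)
                    if nx > max_order:
                        continue
                    for ly in rng_l:
                        ny = abs(ly - v) + abs(ly)
                        if nx + ny > max_order:
                            continue
                        for lz in rng_l:
                            nz = abs(lz - w) + abs(lz)
                            order = nx + ny + nz
                            if order > max_order:
                                continue
                            img = np.array(
                                [
                                    (1 - 2 * u) * src_pos[0] + 2 * lx * dims[0],
                                    (1 - 2 * v) * src_pos[1] + 2 * ly * dims[1],
                                    (1 - 2 * w) * src_pos[2] + 2 * lz * dims[2],
                                ]
                            )
                            yield img, order


# ----------------------------------------------------------------- FDN

_FDN_OUT_SIGNS_L = np.array([1, -1, 1, 1, -1, 1, -1, -1], dtype=float)
_FDN_OUT_SIGNS_R = np.array([1, 1, -1, 1, 1, -1, -1, 1], dtype=float)


def _fdn_tail(room: RoomSpec, n_samples: int, rate: int) -> np.ndarray:
    """Two-channel FDN impulse response with exact target-T60 decay."""
    mfp = 4.0 * room.volume / (SPEED_OF_SOUND * room.surface)
    base = max(int(mfp * rate), 64)
    # mutually prime delay lengths scattered around the mean free path
    primes = []
    cand = base
    while len(primes) < 8:
        if all(np.gcd(cand, p) == 1 for p in primes):
            primes.append(cand)
        cand += int(base * 0.12) + 1
    delays = np.array(primes)
    g = 10.0 ** (-3.0 * delays / (rate * room.target_t60))
    n_lines = 8
    A = np.eye(n_lines) - 2.0 / n_lines * np.ones((n_lines, n_lines))  # Householder

    S = np.zeros((n_lines, n_samples))
    inp = np.zeros((n_lines, n_samples))
    inp[:, 0] = 1.0
    m = int(delays.min())
    D = np.empty((n_lines, m))
    for t0 in range(0, n_samples, m):
        blk = min(m, n_samples - t0)
        for i in range(n_lines):
            lo = t0 - delays[i]
            seg = np.zeros(blk)
            if lo + blk > 0:
                a0 = max(lo, 0)
                seg[a0 - lo : blk] = S[i, a0 : lo + blk]
            D[i, :blk] = g[i] * seg
        S[:, t0 : t0 + blk] = inp[:, t0 : t0 + blk] + A @ D[:, :blk]
    out = np.zeros((n_samples, 2))
    for i in range(n_lines):
        d = int(delays[i])
        out[d:, 0] += _FDN_OUT_SIGNS_L[i] * g[i] * S[i, : n_samples - d]
        out[d:, 1] += _FDN_OUT_SIGNS_R[i] * g[i] * S[i, : n_samples - d]
    return out


# ------------------------------------------------------------ synthesis

def synthesize_brir(
    room: RoomSpec, placement: ScenePlacement, source: str = "target"
) -> BRIR:
    """Synthesize the binaural room impulse response for one source.

    Image sources up to third order with Eyring wall absorption carry the
    early field; the FDN tail is cross-faded in at the third-order
    horizon with diffuse-field (4/A) energy.  Pressure amplitudes follow
    1/distance; ITD/ILD from the spherical-head model.
    """
    return _synthesize_brir_cached(room, placement, source)


@lru_cache(maxsize=64)
def _synthesize_brir_cached(
    room: RoomSpec, placement: ScenePlacement, source: str
) -> BRIR:
    rate = RATE
    rec = _receiver_position(room, placement)
    src_pos = _source_position(room, placement, placement.source(source))
    absorption = room.eyring_absorption()
    beta = np.sqrt(1.0 - absorption)

    images = list(_image_sources(room, src_pos))
    dists = [float(np.linalg.norm(img - rec)) for img, _ in images]
    t_mix = max(dists) / SPEED_OF_SOUND + 1e-3
    n = int(rate * (t_mix + 1.2 * room.target_t60))
    h = np.zeros((n + 128, 2))

    right_axis = np.array([0.0, -1.0, 0.0])  # facing +x
    direct_idx = [0, 0]
    for (img, order), d in zip(images, dists):
        u = (img - rec) / d
        sin_lat = float(np.dot(u, right_axis))
        amp = beta**order / d
        t0 = d / SPEED_OF_SOUND
        for ch, ear in ((0, -1), (1, 1)):  # left, right
            t_ear = t0 + _ear_delay(sin_lat, ear)
            idx = int(round(t_ear * rate))
            alpha_q = round(1.0 + ear * sin_lat, 2)
            kern = _shadow_kernel(alpha_q, rate)
            h[idx : idx + len(kern), ch] += amp * kern
            if order == 0:
                direct_idx[ch] = idx
    h = h[:n]

    # FDN tail gated at the third-order horizon, diffuse-field energy
    tail = _fdn_tail(room, n, rate)
    i_mix = int(t_mix * rate)
    gate = np.zeros(n)
    ramp = int(5e-3 * rate)
    gate[i_mix : i_mix + ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    gate[i_mix + ramp :] = 1.0
    tail = tail * gate[:, None]
    e_tail = float(np.sum(tail**2) / 2.0)  # per ear
    # total reverberant energy 16*pi/A in 1/d-pressure units; the part
    # after t_mix continues the exponential decay
    a_sab = 0.161 * room.volume / room.target_t60
    e_target = 16.0 * np.pi / a_sab * 10.0 ** (-6.0 * t_mix / room.target_t60)
    if e_tail > 0:
        tail *= np.sqrt(e_target / e_tail)
    h += tail

    return BRIR(
        left=h[:, 0],
        right=h[:, 1],
        rate=rate,
        direct_index_left=direct_idx[0],
        direct_index_right=direct_idx[1],
    )


# ------------------------------------------------------------ metrology

def estimate_t60(brir: BRIR) -> float:
    """Reverberation time via Schroeder backward integration (T30 x 2).

    The decay curve is fitted between -5 and -35 dB per ear and the two
    estimates are averaged.  Raises if the decay range is insufficient.
    """
    t60s = []
    for h in (brir.left, brir.right):
        edc = np.cumsum(h[::-1] ** 2)[::-1]
        if edc[0] <= 0:
            raise ValueError("empty impulse response")
        edc_db = 10.0 * np.log10(np.maximum(edc / edc[0], 1e-30))
        i5 = np.argmax(edc_db <= -5.0)
        i35 = np.argmax(edc_db <= -35.0)
        if i35 == 0 or edc_db.min() > -35.0 or i35 <= i5:
            raise ValueError("decay range below 35 dB; cannot estimate T60")
        if i35 > 0.95 * len(h):
            # a stationary (noise-like) tail only "decays" at the very
            # end of the backward integral
            raise ValueError("no usable decay: -35 dB reached only at the tail end")
        seg = slice(i5, i35)
        t = np.arange(len(h))[seg] / brir.rate
        slope, _ = np.polyfit(t, edc_db[seg], 1)
        if slope >= 0:
            raise ValueError("non-decaying impulse response")
        t60s.append(-60.0 / slope)
    return float(np.mean(t60s))


def compute_drr(brir: BRIR) -> tuple[float, float]:
    """Direct-to-reverberant ratio per ear (left, right) in dB.

    Direct window = direct arrival +- 2.5 ms; capped at +50 dB when the
    reverberant part carries no energy.
    """
    half = int(DIRECT_WINDOW_S * brir.rate)
    out = []
    for h, idx in (
        (brir.left, brir.direct_index_left),
        (brir.right, brir.direct_index_right),
    ):
        lo, hi = idx - half, idx + half + 1
        if lo < 0 or hi > len(h):
            raise ValueError("direct window exceeds impulse response")
        e_dir = float(np.sum(h[lo:hi] ** 2))
        e_rev = float(np.sum(h**2)) - e_dir
        if e_rev <= 0 or 10.0 * np.log10(e_dir / e_rev) > DRR_CAP_DB:
            out.append(DRR_CAP_DB)
        else:
            out.append(10.0 * np.log10(e_dir / e_rev))
    return out[0], out[1]


# -------------------------------------------------------------- render

def render_scene(
    room: RoomSpec,
    placement: ScenePlacement,
    sources: list[tuple[AudioSignal, str]],
) -> AudioSignal:
    """Convolve each mono source with its BRIR and sum (2-channel output).

    In the LRL, masker sources are attenuated by the inverse-distance
    ratio towards the target's 2.55 m reference distance so target and
    maskers have approximately the same level at the receiver.
    """
    rendered = []
    calib = sources[0][0].calibration
    for sig, label in sources:
        if sig.channels != 1:
            raise ValueError("scene sources must be mono")
        if sig.rate != RATE:
            raise ValueError("sampling-rate mismatch")
        brir = synthesize_brir(room, placement, label)
        gain = 1.0
        ref = placement.masker_level_ref_distance
        if ref is not None and label.startswith("masker"):
            gain = placement.source(label).distance_m / ref
        out = np.stack(
            [
                sps.fftconvolve(sig.samples * gain, brir.left),
                sps.fftconvolve(sig.samples * gain, brir.right),
            ],
            axis=1,
        )
        rendered.append(out)
    total = max(r.shape[0] for r in rendered)
    mix = np.zeros((total, 2))
    for r in rendered:
        mix[: r.shape[0]] += r
    return AudioSignal(mix, rate=RATE, calibration=calib)
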