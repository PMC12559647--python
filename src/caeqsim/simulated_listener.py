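"""Simulated listeners: psychometric observers, rating behaviour, cohorts.

Human participants are replaced by parametric observers.  For the 3-AFC
detection task an observer answers correctly with probability

    p(a) = gamma + (1 - gamma - lambda) * F((g(a) - g(t)) / sigma + c)

where F is the logistic function, gamma = 1/3 (3-AFC guessing),
lambda a small lapse rate, t the observer's 70.7%-correct threshold for
the given distortion kind and room context, and g a log transform for
ratio-like amounts (ripple depth, saturation alpha) or the identity for
dB/degree amounts.  The constant c shifts the curve so that
p(t) = 0.707 exactly — the point tracked by a 1-up/2-down staircase.

The rating model maps a threshold-normalized perceptual distance
(log2 of the signal distortion-to-detection ratio, clipped at 0) to a
0-100 quality score with group-dependent slope and masker interaction:
very-mild-loss (ON1) and normal-hearing (YNH) observers show partial
masking of distortions (maskers raise scores of distorted items), while
moderate-loss (ON3) observers down-rate every masked item including the
hidden reference.  Group parameters are free defaults chosen to emulate
these qualitative patterns, not fits to any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import hearing
from .distortions import DISTORTION_KINDS

GROUPS = ("YNH", "ON1", "ON3")
CONTEXTS = ("LRL", "Large", "LRL_2Msep")
GUESS_RATE = 1.0 / 3.0
TARGET_PC = 0.5**0.5  # 70.7%, the 1-up/2-down convergence point

#: Amount transform per kind: log for ratio-like units, identity for
#: dB-difference and degree units.
LOG_KINDS = ("ripple", "saturation")

#: Default 70.7% thresholds per (kind, group, context), in printed amount
#: units (dB peak-to-valley, alpha, dB, degrees).  Chosen to emulate the
#: qualitative group/context pattern: masked contexts are hardest, and
#: moderate loss costs most in the presence of maskers.
DEFAULT_THRESHOLDS = {
    "ripple": {
        "YNH": {"LRL": 6.5, "Large": 7.0, "LRL_2Msep": 12.0},
        "ON1": {"LRL": 8.4, "Large": 8.8, "LRL_2Msep": 16.0},
        "ON3": {"LRL": 8.3, "Large": 8.8, "LRL_2Msep": 22.0},
    },
    "saturation": {
        "YNH": {"LRL": 0.10, "Large": 0.12, "LRL_2Msep": 0.25},
        "ON1": {"LRL": 0.28, "Large": 0.30, "LRL_2Msep": 0.45},
        "ON3": {"LRL": 0.50, "Large": 0.52, "LRL_2Msep": 0.70},
    },
    "intensity": {
        "YNH": {"LRL": 1.4, "Large": 1.5, "LRL_2Msep": 3.0},
        "ON1": {"LRL": 1.8, "Large": 1.9, "LRL_2Msep": 4.0},
        "ON3": {"LRL": 2.1, "Large": 2.2, "LRL_2Msep": 5.5},
    },
    "spatial": {
        "YNH": {"LRL": 2.0, "Large": 3.0, "LRL_2Msep": 8.0},
        "ON1": {"LRL": 14.0, "Large": 16.0, "LRL_2Msep": 22.0},
        "ON3": {"LRL": 17.0, "Large": 19.0, "LRL_2Msep": 26.0},
    },
}

#: Minimum staircase steps per kind (shared with the adaptive module);
#: default observer spread = 2 minimum steps.
_MIN_STEPS = {"ripple": 1.5, "saturation": 0.035, "intensity": 0.4, "spatial": 0.5}

#: Rating-model group parameters: slope (score points per distance unit),
#: masker release of distorted items, masked-reference penalty, rating
#: noise sd, perceived anchor distance.
RATING_PARAMS = {
    "YNH": {"slope": 20.0, "release": 8.0, "ref_penalty": 2.0, "noise_sd": 4.0},
    "ON1": {"slope": 18.0, "release": 8.0, "ref_penalty": 8.0, "noise_sd": 5.0},
    "ON3": {"slope": 11.0, "release": 0.0, "ref_penalty": 20.0, "noise_sd": 8.0},
}
ANCHOR_DISTANCE = 3.5

_YNH_PROTO = {f: 0.0 for f in hearing.AUDIOMETRIC_FREQS}


def amount_transform(kind: str, amount: float) -> float:
    """g(amount): log for ratio-like amounts, identity otherwise."""
    if kind in LOG_KINDS:
        return float(np.log(amount)) if amount > 0 else -np.inf
    return float(amount)


def default_spread(kind: str, threshold: float) -> float:
    """Observer spread sigma in g-units, equivalent to 2 minimum steps."""
    two_steps = 2.0 * _MIN_STEPS[kind]
    if kind in LOG_KINDS:
        return float(np.log((threshold + two_steps) / threshold))
    return two_steps


@dataclass(frozen=True)
class SimulatedListener:
    """A psychometric observer with a rating model.

    ``thresholds`` maps (kind, context) -> 70.7% point in amount units;
    ``spreads`` maps the same keys to sigma in g-units.
    """

    listener_id: int
    group: str
    audiogram: hearing.Audiogram
    thresholds: dict[tuple[str, str], float]
    spreads: dict[tuple[str, str], float]
    lapse_rate: float = 0.01
    comfort_offset: float = -5.0
    rating_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse rate must lie in [0, 0.05]")
        if not self.rating_params:
            object.__setattr__(
                self, "rating_params", dict(RATING_PARAMS[self.group])
            )

    def threshold(self, kind: str, context: str) -> float:
        key = (kind, context)
        if key not in self.thresholds:
            raise KeyError(f"no threshold for {key}")
        return self.thresholds[key]

    def prob_correct(self, kind: str, context: str, amount: float) -> float:
        """3-AFC percent-correct at a given distortion amount."""
        t = self.threshold(kind, context)
        sigma = self.spreads[(kind, context)]
        lam = self.lapse_rate
        shift = logit((TARGET_PC - GUESS_RATE) / (1.0 - GUESS_RATE - lam))
        z = (amount_transform(kind, amount) - amount_transform(kind, t)) / sigma
        return float(GUESS_RATE + (1.0 - GUESS_RATE - lam) * expit(z + shift))


def simulate_trial_response(
    listener: SimulatedListener,
    kind: str,
    context: str,
    amount: float,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli 3-AFC trial outcome (True = correct interval)."""
    if kind not in DISTORTION_KINDS:
        raise ValueError(f"unknown distortion kind {kind!r}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    return bool(rng.random() < listener.prob_correct(kind, context, amount))


# --------------------------------------------------------------- rating

def perceived_distance(listener: SimulatedListener, item) -> float:
    """Threshold-normalized perceptual distance of a rating item.

    log2 of the distortion amount over the listener's unmasked-room
    detection threshold, clipped at 0 (sub-threshold distortions are
    imperceptible); the anchor has a fixed large distance.
    """
    if item.level == "ref":
        return 0.0
    if item.level == "anchor":
        return ANCHOR_DISTANCE
    t = listener.threshold(item.kind, item.room)
    if item.amount <= 0 or t <= 0:
        return 0.0
    return max(0.0, float(np.log2(item.amount / t)))


def expected_rating(listener: SimulatedListener, item) -> float:
    """Noise-free expected 0-100 quality score for one item."""
    p = listener.rating_params
    d = perceived_distance(listener, item)
    score = 100.0 - p["slope"] * d
    if item.masker_config != "0M":
        score += p["release"] * min(d, 2.0)
        score -= p["ref_penalty"]
    return float(np.clip(score, 0.0, 100.0))


def simulate_rating(
    listener: SimulatedListener, item, rng: np.random.Generator | None = None
) -> int:
    """One rated 0-100 integer score (expected score plus rating noise)."""
    score = expected_rating(listener, item)
    if rng is not None and listener.rating_params["noise_sd"] > 0:
        score += rng.normal(0.0, listener.rating_params["noise_sd"])
    return int(np.clip(round(score), 0, 100))


# --------------------------------------------------------------- cohort

#: PTA of the generating prototypes, used to centre the PTA coupling.
_PROTO_PTA = {
    "YNH": 0.0,
    "ON1": float(np.mean([hearing.BISGAARD_PROFILES["N1"][f] for f in hearing.PTA_FREQS])),
    "ON3": float(np.mean([hearing.BISGAARD_PROFILES["N3"][f] for f in hearing.PTA_FREQS])),
}

#: PTA-threshold coupling slope in g-units per dB HL: strong in masked
#: contexts (and for saturation everywhere), weak otherwise — mirroring
#: where PTA predicts detection thresholds.
def _pta_slope(kind: str, context: str) -> float:
    strong = context == "LRL_2Msep" or kind == "saturation"
    if kind in LOG_KINDS:
        return 0.012 if strong else 0.002
    return 0.08 if strong else 0.01


def make_listener(
    listener_id: int, group: str, seed: int, lapse_rate: float = 0.01
) -> SimulatedListener:
    """One seed-deterministic listener of the given group."""
    rng = np.random.default_rng(seed)
    if group == "YNH":
        aud = hearing.Audiogram(left=dict(_YNH_PROTO), right=dict(_YNH_PROTO))
    else:
        aud = hearing.generate_audiogram(
            "N1" if group == "ON1" else "N3", int(rng.integers(2**31))
        )
    pta = hearing.pta_better_ear(aud)
    thresholds, spreads = {}, {}
    for kind in DISTORTION_KINDS:
        for ctx in CONTEXTS:
            base = DEFAULT_THRESHOLDS[kind][group][ctx]
            dg = _pta_slope(kind, ctx) * (pta - _PROTO_PTA[group])
            dg += rng.normal(0.0, 0.05 if kind in LOG_KINDS else 0.15 * _MIN_STEPS[kind] / 0.35)
            if kind in LOG_KINDS:
                t = float(base * np.exp(dg))
            else:
                t = float(max(base + dg, 0.1))
            thresholds[(kind, ctx)] = t
            spreads[(kind, ctx)] = default_spread(kind, t)
    offsets = np.array(hearing.COMFORT_OFFSETS)
    probs = np.array(hearing.COMFORT_SPLIT, dtype=float)
    comfort = float(rng.choice(offsets, p=probs / probs.sum()))
    return SimulatedListener(
        listener_id=listener_id,
        group=group,
        audiogram=aud,
        thresholds=thresholds,
        spreads=spreads,
        lapse_rate=lapse_rate,
        comfort_offset=comfort,
    )


def generate_cohort(
    n_per_group: int, groups: tuple[str, ...] = ("ON1", "ON3"), seed: int = 0
) -> list[SimulatedListener]:
    """Seed-deterministic cohort; 12 per group matches the study shape.

    Audiograms jitter around the Bisgaard N1/N3 prototypes (asymmetry
    <= 10 dB by construction); thresholds couple to the individual PTA so
    that masked-context thresholds are ordered ON3 > ON1 at the group
    level; comfort offsets follow the observed 14:8:2 split.
    """
    if n_per_group < 1:
        raise ValueError("need at least one listener per group")
    ss = np.random.SeedSequence(seed)
    cohort = []
    lid = 0
    for group in groups:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        for child in ss.spawn(n_per_group):
            cohort.append(make_listener(lid, group, int(child.generate_state(1)[0] % 2**31)))
            lid += 1
    return cohort
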