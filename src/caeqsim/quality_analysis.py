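"""Quality-rating sessions and derived statistics.

Rating sessions follow a MUSHRA-like protocol: listeners score the
difference between each test item and an unprocessed reference on a
0-100 scale (0 = very strong difference, 100 = no difference); every
session contains a hidden reference and a strongly degraded anchor.
Derived statistics: the signal distortion-to-detection ratio (SDDR =
applied suprathreshold distortion amount over the individual detection
threshold; 1 = at threshold), Pearson test-retest reliability, and
Pearson correlations between better-ear pure-tone averages and
detection thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import hearing
from .distortions import DISTORTION_KINDS
from .simulated_listener import SimulatedListener, simulate_rating

#: Suprathreshold low/high distortion amounts per target stimulus:
#: ripple depth (dB), saturation alpha, intensity (dB), azimuth (deg).
SUPRATHRESHOLD_AMOUNTS = {
    "speech": {
        "ripple": (12.0, 18.0),
        "saturation": (0.18, 0.45),
        "intensity": (1.5, 4.5),
        "spatial": (8.0, 30.0),
    },
    "noise": {
        "ripple": (2.5, 5.0),
        "saturation": (0.22, 0.44),
        "intensity": (1.0, 4.0),
        "spatial": (8.0, 30.0),
    },
}

#: Amounts used with normal-hearing listeners in the predecessor setup,
#: kept for cross-group comparisons.
SUPRATHRESHOLD_AMOUNTS_YNH = {
    "speech": {
        "ripple": (12.0, 18.0),
        "saturation": (0.11, 0.175),
        "intensity": (1.5, 4.0),
        "spatial": (4.0, 30.0),
    },
    "noise": {
        "ripple": (2.5, 5.0),
        "saturation": (0.18, 0.37),
        "intensity": (1.0, 4.0),
        "spatial": (4.0, 30.0),
    },
}


def sddr(amount: float, threshold: float) -> float:
    """Signal distortion-to-detection ratio (dimensionless).

    Ratio of the applied suprathreshold distortion amount to the
    individual detection threshold; >1 above threshold, <1 below.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return amount / threshold


@dataclass(frozen=True)
class RatingItem:
    """One stimulus of a rating session."""

    kind: str  # distortion kind, or "reference"/"anchor"
    level: str  # "ref" | "anchor" | "low" | "high"
    amount: float
    room: str = "LRL"
    masker_config: str = "0M"

    def __post_init__(self):
        if self.level not in ("ref", "anchor", "low", "high"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level in ("low", "high") and self.kind not in DISTORTION_KINDS:
            raise ValueError(f"unknown distortion kind {self.kind!r}")


def build_rating_items(
    stimulus: str = "speech", room: str = "LRL", masker_config: str = "0M"
) -> list[RatingItem]:
    """Standard session item set: hidden reference, anchor, 4 kinds x 2 levels."""
    amounts = SUPRATHRESHOLD_AMOUNTS[stimulus]
    items = [
        RatingItem("reference", "ref", 0.0, room, masker_config),
        RatingItem("anchor", "anchor", 0.0, room, masker_config),
    ]
    for kind in DISTORTION_KINDS:
        lo, hi = amounts[kind]
        items.append(RatingItem(kind, "low", lo, room, masker_config))
        items.append(RatingItem(kind, "high", hi, room, masker_config))
    return items


@dataclass(frozen=True)
class RatingSession:
    """Scores of one listener over one item set (test or retest)."""

    listener_id: int
    items: tuple[RatingItem, ...]
    scores: tuple[int, ...]
    tag: str = "test"

    def __post_init__(self):
        if len(self.items) != len(self.scores):
            raise ValueError("one score per item required")
        if any(not 0 <= s <= 100 for s in self.scores):
            raise ValueError("scores must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "listener": self.listener_id,
                "kind": [i.kind for i in self.items],
                "level": [i.level for i in self.items],
                "room": [i.room for i in self.items],
                "masker_config": [i.masker_config for i in self.items],
                "score": self.scores,
                "tag": self.tag,
            }
        )


def run_rating_session(
    listener: SimulatedListener,
    items: list[RatingItem],
    seed: int,
    tag: str = "test",
) -> RatingSession:
    """Score every item via the listener's rating model.

    Test and retest use independent seed streams; the item set must
    contain the hidden reference and the anchor.
    """
    levels = {i.level for i in items}
    if "ref" not in levels or "anchor" not in levels:
        raise ValueError("session items must include hidden reference and anchor")
    rng = np.random.default_rng(seed)
    scores = tuple(simulate_rating(listener, item, rng) for item in items)
    return RatingSession(listener.listener_id, tuple(items), scores, tag)


def test_retest_pcc(a: RatingSession, b: RatingSession) -> float:
    """Pearson correlation between paired test/retest scores."""
    if a.items != b.items:
        raise ValueError("sessions must share the same item set")
    xa, xb = np.asarray(a.scores, float), np.asarray(b.scores, float)
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("zero-variance session: correlation undefined")
    return float(stats.pearsonr(xa, xb).statistic)


def significance_stars(p: float) -> str:
    """Reporting convention: * for p<.05, ** for p<.01."""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def threshold_pta_correlation(
    thresholds: np.ndarray, ptas: np.ndarray
) -> tuple[float, float, str]:
    """Pearson r (with two-sided p and stars) between detection
    thresholds and better-ear pure-tone averages across a cohort."""
    thresholds = np.asarray(thresholds, float)
    ptas = np.asarray(ptas, float)
    if len(thresholds) != len(ptas) or len(ptas) < 4:
        raise ValueError("need paired samples, n >= 4")
    if np.std(thresholds) == 0 or np.std(ptas) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    res = stats.pearsonr(thresholds, ptas)
    return float(res.statistic), float(res.pvalue), significance_stars(res.pvalue)


def sddr_quality_relationship(
    cohort: list[SimulatedListener],
    stimulus: str = "speech",
    room: str = "LRL",
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Group-level SDDR versus quality score across kind x level cells.

    For every distortion kind and level, compute per group the mean SDDR
    (amount over each listener's detection threshold in the room) and
    the mean rated score; return the Spearman rank correlation over all
    (cell, group) points (expected negative: groups that resolve the
    distortions better rate them lower) plus the cell table.
    """
    amounts = SUPRATHRESHOLD_AMOUNTS[stimulus]
    items = build_rating_items(stimulus, room)
    rng_seed = np.random.SeedSequence(seed)
    rows = []
    groups = sorted({l.group for l in cohort})
    sessions = {
        l.listener_id: run_rating_session(l, items, int(s.generate_state(1)[0] % 2**31))
        for l, s in zip(cohort, rng_seed.spawn(len(cohort)))
    }
    for kind in DISTORTION_KINDS:
        for li, level in enumerate(("low", "high")):
            amount = amounts[kind][li]
            idx = next(
                i for i, it in enumerate(items)
                if it.kind == kind and it.level == level
            )
            for group in groups:
                members = [l for l in cohort if l.group == group]
                ratios = [sddr(amount, l.threshold(kind, room)) for l in members]
                scores = [sessions[l.listener_id].scores[idx] for l in members]
                rows.append(
                    {
                        "kind": kind,
                        "level": level,
                        "group": group,
                        "mean_sddr": float(np.mean(ratios)),
                        "mean_score": float(np.mean(scores)),
                    }
                )
    table = pd.DataFrame(rows)
    rho = float(
        stats.spearmanr(table["mean_sddr"], table["mean_score"]).statistic
    )
    return rho, table


def cohort_threshold_pta_table(
    cohort: list[SimulatedListener], context: str
) -> pd.DataFrame:
    """Per-kind PTA-threshold correlations for a cohort in one context."""
    ptas = np.array([hearing.pta_better_ear(l.audiogram) for l in cohort])
    rows = []
    for kind in DISTORTION_KINDS:
        th = np.array([l.threshold(kind, context) for l in cohort])
        r, p, star = threshold_pta_correlation(th, ptas)
        rows.append({"kind": kind, "context": context, "r": r, "p": p, "stars": star})
    return pd.DataFrame(rows)
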