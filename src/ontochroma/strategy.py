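"""Antipredator color strategies: cryptic / ambiguous / contrasting.

A species' strategy at a stage is read off its area-weighted RGB distance to
natural green and brown backgrounds: species close to backgrounds are
cryptic, species far from both are contrasting (the classic black + bright
combinations widely treated as warning coloration), the middle band is
ambiguous.  Cut points default to equal-width thirds of the observed score
range; explicit thresholds reproduce any published split.  The module also
builds larval x adult transition tables and tests whether species that are
contrasting at both stages advertise with the *same* bright color.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterModel, DEFAULT_DARKNESS_THRESHOLD
from .datamodel import AREA_WEIGHTS, ColorPatch, ColorPattern, StageDataset, ValidationError

__all__ = [
    "StrategyCall",
    "TransitionTable",
    "classify",
    "transition_table",
    "bright_element",
    "shared_warning_color",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("cryptic", "ambiguous", "contrasting")


@dataclass(frozen=True)
class StrategyCall:
    species_id: str
    stage: str
    score: float
    category: str


def _terciles(scores: np.ndarray) -> tuple[float, float]:
    lo, hi = float(scores.min()), float(scores.max())
    r = hi - lo
    if r <= 0:
        raise ValidationError("all scores equal; cannot derive thresholds")
    return lo + r / 3.0, lo + 2.0 * r / 3.0


def classify(
    scores: dict[str, float],
    stage: str,
    thresholds: tuple[float, float] | str = "equal_width_terciles",
) -> list[StrategyCall]:
    """Assign each species a strategy from its background-distance score.

    ``thresholds`` is either an explicit ``(t1, t2)`` pair or the string
    ``"equal_width_terciles"``, which cuts the observed score range into
    three equal-width bands.  score < t1 -> cryptic, score >= t2 ->
    contrasting, otherwise ambiguous.  Classification is monotone in score.
    """
    if isinstance(thresholds, str):
        if thresholds != "equal_width_terciles":
            raise ValidationError(f"unknown threshold rule {thresholds!r}")
        if len(scores) < 3:
            raise ValidationError(
                "need >= 3 species to derive automatic thresholds"
            )
        t1, t2 = _terciles(np.array(list(scores.values()), float))
    else:
        t1, t2 = float(thresholds[0]), float(thresholds[1])
    if t1 >= t2:
        raise ValidationError(f"thresholds must satisfy t1 < t2, got {t1} >= {t2}")
    calls = []
    for sp in sorted(scores):
        s = float(scores[sp])
        if s < t1:
            cat = "cryptic"
        elif s >= t2:
            cat = "contrasting"
        else:
            cat = "ambiguous"
        calls.append(StrategyCall(species_id=sp, stage=stage, score=s, category=cat))
    return calls


@dataclass
class TransitionTable:
    """3 x 3 larval-category x adult-category counts and percentages."""

    counts: np.ndarray  # rows: larval category, cols: adult category
    n_species: int

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.n_species

    def cell(self, larval: str, adult: str) -> int:
        return int(self.counts[CATEGORIES.index(larval), CATEGORIES.index(adult)])


def transition_table(
    larval: list[StrategyCall], adult: list[StrategyCall]
) -> TransitionTable:
    """Cross-tabulate strategies over species classified at both stages."""
    lmap = {c.species_id: c.category for c in larval}
    amap = {c.species_id: c.category for c in adult}
    common = sorted(set(lmap) & set(amap))
    if not common:
        raise ValidationError("no species classified at both stages")
    dropped = (set(lmap) | set(amap)) - set(common)
    if dropped:
        logger.info("species classified at one stage only, excluded: %s", sorted(dropped))
    counts = np.zeros((3, 3), int)
    for sp in common:
        counts[CATEGORIES.index(lmap[sp]), CATEGORIES.index(amap[sp])] += 1
    return TransitionTable(counts=counts, n_species=len(common))


def bright_element(
    pattern: ColorPattern,
    darkness_threshold: float = DEFAULT_DARKNESS_THRESHOLD,
) -> ColorPatch:
    """The bright color of a contrasting (black + bright) pattern.

    Among patches with R+G+B at or above the darkness threshold, pick the
    one occupying the largest area; if areas tie (same category), the
    brightest wins.  A contrasting pattern with no non-dark patch is a data
    error.
    """
    bright = [p for p in pattern.patches if p.brightness >= darkness_threshold]
    if not bright:
        raise ValidationError(
            f"species {pattern.species_id!r}: no patch above the darkness "
            f"threshold ({darkness_threshold})"
        )
    bright.sort(
        key=lambda p: (AREA_WEIGHTS[p.area_category], p.brightness, p.r, p.g, p.b),
        reverse=True,
    )
    return bright[0]


def shared_warning_color(
    cat_calls: list[StrategyCall],
    adult_calls: list[StrategyCall],
    cats: StageDataset,
    adults: StageDataset,
    model: ClusterModel,
    darkness_threshold: float = DEFAULT_DARKNESS_THRESHOLD,
) -> tuple[dict[str, bool], float | None, int]:
    """Do species contrasting at both stages keep the same warning color?

    For every species called contrasting at both stages, the bright element
    of each stage's pattern is mapped to its nearest palette center; the
    species "shares" its warning color when both stages land on the same
    center.  Returns (per-species flags, percentage TRUE, n eligible); the
    percentage is None when no species is eligible.
    """
    contrasting_cat = {c.species_id for c in cat_calls if c.category == "contrasting"}
    contrasting_adult = {c.species_id for c in adult_calls if c.category == "contrasting"}
    eligible = sorted(
        contrasting_cat & contrasting_adult & set(cats.patterns) & set(adults.patterns)
    )
    flags: dict[str, bool] = {}
    for sp in eligible:
        bc = bright_element(cats[sp], darkness_threshold)
        ba = bright_element(adults[sp], darkness_threshold)
        ic = int(model.nearest(np.array([bc.rgb], float))[0])
        ia = int(model.nearest(np.array([ba.rgb], float))[0])
        flags[sp] = ic == ia
    if not flags:
        return flags, None, 0
    pct = 100.0 * sum(flags.values()) / len(flags)
    return flags, pct, len(flags)
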