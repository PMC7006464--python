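"""Core domain types: color patches, per-species color patterns, stage datasets.

A *color pattern* is the set of colors scored for one species at one life
stage (and, for adults, one sex and wing side): an ordered list of 1-4 RGB
patches, each tagged with an ordinal area category describing how much of the
animal it covers (1: >80%, 2: two primaries sharing 30-50% each, 3: 10-30%,
4: <10%).  All downstream statistics consume either the 6-D primary-color
vector of a pattern or its area-weighted color distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AREA_WEIGHTS",
    "ColorPatch",
    "ColorPattern",
    "StageDataset",
    "ValidationError",
    "pattern_vector",
    "normalized_weights",
]

logger = logging.getLogger(__name__)

#: Raw (pre-normalization) weight assigned to each area category: midpoints
#: of the coverage ranges ">80%", "30-50% (shared primary)", "10-30%", "<10%".
#: Per-pattern weights are these values renormalized to sum to 1.
AREA_WEIGHTS: dict[int, float] = {1: 0.85, 2: 0.40, 3: 0.20, 4: 0.05}

STAGES = ("caterpillar", "adult")
SEXES = ("male", "female", "unspecified")
SIDES = ("upperside", "underside", "unspecified")

MAX_PATCHES = 4
PRIMARY_CATEGORIES = (1, 2)


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


@dataclass(frozen=True)
class ColorPatch:
    """One sampled color: RGB in 0-255 plus an area category in 1-4."""

    r: int
    g: int
    b: int
    area_category: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValidationError(
                    f"channel {name}={v} outside [0, 255]"
                )
        if self.area_category not in AREA_WEIGHTS:
            raise ValidationError(
                f"area_category={self.area_category} not in {{1,2,3,4}}"
            )

    @property
    def rgb(self) -> tuple[int, int, int]:
        return (self.r, self.g, self.b)

    @property
    def brightness(self) -> int:
        """Sum of the three channels; the field's coarse luminance proxy."""
        return self.r + self.g + self.b

    @property
    def is_primary(self) -> bool:
        return self.area_category in PRIMARY_CATEGORIES


@dataclass(frozen=True)
class ColorPattern:
    """Colors of one species at one stage/sex/side; 1-4 patches, >=1 primary."""

    species_id: str
    stage: str
    patches: tuple[ColorPatch, ...]
    sex: str = "unspecified"
    side: str = "unspecified"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage {self.stage!r} not in {STAGES}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {SEXES}")
        if self.side not in SIDES:
            raise ValidationError(f"side {self.side!r} not in {SIDES}")
        if not (1 <= len(self.patches) <= MAX_PATCHES):
            raise ValidationError(
                f"species {self.species_id!r}: {len(self.patches)} patches; "
                f"expected between 1 and {MAX_PATCHES}"
            )
        if not any(p.is_primary for p in self.patches):
            raise ValidationError(
                f"species {self.species_id!r}: no primary patch "
                f"(area category 1 or 2)"
            )

    @property
    def primaries(self) -> tuple[ColorPatch, ...]:
        return tuple(p for p in self.patches if p.is_primary)

    def with_patches(self, patches: tuple[ColorPatch, ...]) -> "ColorPattern":
        return replace(self, patches=patches)


def normalized_weights(pattern: ColorPattern) -> np.ndarray:
    """Area weights of a pattern's patches, renormalized to sum to 1."""
    w = np.array([AREA_WEIGHTS[p.area_category] for p in pattern.patches], float)
    return w / w.sum()


def _brightness_key(p: ColorPatch) -> tuple[int, int, int, int]:
    # Descending brightness; ties broken lexicographically on (R, G, B)
    # descending so vectorization is deterministic.
    return (p.brightness, p.r, p.g, p.b)


def pattern_vector(pattern: ColorPattern) -> np.ndarray:
    """Map a pattern to the 6-D vector (R1,G1,B1,R2,G2,B2) of its primaries.

    The first triple is the brightest primary (highest R+G+B) and the second
    the darkest.  A species with a single primary color contributes that
    color twice, so single-color species occupy the diagonal of the duplicated
    space rather than being dropped.  If more than two primaries are present
    (messy real tables), the two with the largest area weight are kept, ties
    going to the brighter patch, and a warning is logged.
    """
    primaries = list(pattern.primaries)
    if not primaries:
        raise ValidationError(
            f"species {pattern.species_id!r}: cannot vectorize without a "
            f"primary patch"
        )
    if len(primaries) > 2:
        logger.warning(
            "species %r has %d primary patches; keeping the two with the "
            "largest area weight",
            pattern.species_id,
            len(primaries),
        )
        primaries.sort(
            key=lambda p: (AREA_WEIGHTS[p.area_category], *_brightness_key(p)),
            reverse=True,
        )
        primaries = primaries[:2]
    if len(primaries) == 1:
        primaries = [primaries[0], primaries[0]]
    first, second = sorted(primaries, key=_brightness_key, reverse=True)
    return np.array(
        [first.r, first.g, first.b, second.r, second.g, second.b], float
    )


@dataclass
class StageDataset:
    """Species-indexed collection of patterns sharing one stage/sex/side."""

    label: str
    patterns: dict[str, ColorPattern] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = {(p.stage, p.sex, p.side) for p in self.patterns.values()}
        if len(keys) > 1:
            raise ValidationError(
                f"dataset {self.label!r} mixes stage/sex/side combinations: "
                f"{sorted(keys)}"
            )
        for sp, p in self.patterns.items():
            if sp != p.species_id:
                raise ValidationError(
                    f"dataset {self.label!r}: key {sp!r} != pattern species "
                    f"{p.species_id!r}"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.patterns

    def __getitem__(self, species_id: str) -> ColorPattern:
        return self.patterns[species_id]

    def add(self, pattern: ColorPattern) -> None:
        if pattern.species_id in self.patterns:
            raise ValidationError(
                f"dataset {self.label!r}: duplicate species "
                f"{pattern.species_id!r}"
            )
        self.patterns[pattern.species_id] = pattern
        self.__post_init__()

    def subset(self, species: list[str]) -> "StageDataset":
        missing = [s for s in species if s not in self.patterns]
        if missing:
            raise KeyError(f"species not in dataset {self.label!r}: {missing}")
        return StageDataset(
            label=self.label,
            patterns={s: self.patterns[s] for s in species},
        )

    def vector_matrix(self, species: list[str] | None = None) -> np.ndarray:
        """Stack pattern vectors into an N x 6 matrix in the given order."""
        order = self.species if species is None else species
        return np.vstack([pattern_vector(self.patterns[s]) for s in order])
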