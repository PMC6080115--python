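"""Device trend-arrow taxonomies and rate-of-change classification.

Each CGM system displays an ordinal set of trend arrows defined by its user
manual as bands of the glucose rate of change in mg/(dL.min).  The Dexcom G5
(DG5) has seven arrows with cut points at 1, 2 and 3 mg/(dL.min); the
FreeStyle Libre (FL) has five arrows with cut points at 1 and 2 mg/(dL.min)
and no double arrows.  Categories are coded as signed integers: negative =
falling, 0 = steady, positive = rising, with larger magnitude meaning a
steeper band.

Boundary convention: a rate exactly on a cut point (|rate| = 1, 2 or 3) is
assigned to the *less extreme* category for both devices, so the steady band
is the closed interval |rate| <= 1.  The two manuals word the boundary
inconsistently ("not changing >1" vs "<1"); using one closed convention for
both devices keeps them comparable and only affects a measure-zero set of
rates.  The convention is echoed in analysis output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ProfileMismatchError, TrendParseError

__all__ = [
    "TrendCategory",
    "DeviceProfile",
    "DEXCOM_G5",
    "FREESTYLE_LIBRE",
    "PROFILES",
    "classify_rate",
    "category_difference",
    "parse_arrow_symbol",
    "arrow_symbol",
]


@dataclass(frozen=True)
class TrendCategory:
    """One ordinal trend-arrow category of a device profile."""

    code: int
    label: str
    profile_name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label} ({self.code:+d})" if self.code else f"{self.label} (0)"


@dataclass(frozen=True)
class DeviceProfile:
    """A device's arrow taxonomy plus its nominal storage cadence.

    Parameters
    ----------
    name:
        Short device identifier ("DG5" or "FL").
    thresholds:
        Strictly increasing positive rate cut points in mg/(dL.min).
        ``len(thresholds)`` rising bands mirror into as many falling bands,
        so the profile has ``2 * len(thresholds) + 1`` categories.
    labels:
        Category labels ordered from the most negative code to the most
        positive, length ``2 * len(thresholds) + 1``.
    storage_interval:
        Minutes between stored sensor readings (DG5: 5; FL: 15).
    """

    name: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]
    storage_interval: float
    categories: tuple[TrendCategory, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        k = len(self.thresholds)
        if len(self.labels) != 2 * k + 1:
            raise ValueError(
                f"expected {2 * k + 1} labels for {k} thresholds, got {len(self.labels)}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique within a profile")
        cats = tuple(
            TrendCategory(code=code, label=lab, profile_name=self.name)
            for code, lab in zip(range(-k, k + 1), self.labels)
        )
        object.__setattr__(self, "categories", cats)

    @property
    def max_code(self) -> int:
        return len(self.thresholds)

    def category(self, code: int) -> TrendCategory:
        """Return the category with the given ordinal code."""
        k = self.max_code
        if not -k <= code <= k:
            raise ValueError(f"code {code} outside profile {self.name} range -{k}..+{k}")
        return self.categories[code + k]


DEXCOM_G5 = DeviceProfile(
    name="DG5",
    thresholds=(1.0, 2.0, 3.0),
    labels=(
        "rapid fall",
        "fall",
        "slow fall",
        "steady",
        "slow rise",
        "rise",
        "rapid rise",
    ),
    storage_interval=5.0,
)

FREESTYLE_LIBRE = DeviceProfile(
    name="FL",
    thresholds=(1.0, 2.0),
    labels=(
        "quick fall",
        "fall",
        "slow change",
        "rise",
        "quick rise",
    ),
    storage_interval=15.0,
)

PROFILES: dict[str, DeviceProfile] = {"DG5": DEXCOM_G5, "FL": FREESTYLE_LIBRE}

# ASCII aliases for arrows; diary files cannot be relied on to carry glyphs.
# The FL alias table has no double-arrow entries (those arrows do not exist
# on the device).
_DG5_ALIASES = {
    "up2": 3,
    "up": 2,
    "upright": 1,
    "up1": 1,
    "flat": 0,
    "downright": -1,
    "down1": -1,
    "down": -2,
    "down2": -3,
}
_FL_ALIASES = {
    "up": 2,
    "upright": 1,
    "flat": 0,
    "downright": -1,
    "down": -2,
}
_ALIASES: dict[str, dict[str, int]] = {"DG5": _DG5_ALIASES, "FL": _FL_ALIASES}

# Canonical spelling used when writing diary files.
_CANONICAL = {3: "up2", 2: "up", 1: "upright", 0: "flat", -1: "downright", -2: "down", -3: "down2"}


def classify_rate(rate: float, profile: DeviceProfile) -> TrendCategory:
    """Map a glucose rate of change onto the profile's trend category.

    Parameters
    ----------
    rate:
        Glucose rate of change in mg/(dL.min); must be finite.
    profile:
        The device profile whose bands to use.

    Returns
    -------
    TrendCategory
        The unique category whose band contains ``rate``.  Cut-point values
        go to the less-extreme category, so e.g. +1.2 mg/(dL.min) on DG5 is
        "slow rise" (+1) and exactly +1.0 mg/(dL.min) is "steady" (0) on
        both devices.
    """
    if not math.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate!r}")
    magnitude = sum(1 for t in profile.thresholds if abs(rate) > t)
    sign = 1 if rate > 0 else -1 if rate < 0 else 0
    return profile.category(sign * magnitude if magnitude else 0)


def category_difference(a: TrendCategory, b: TrendCategory) -> int:
    """Absolute ordinal distance |a.code - b.code| within one profile."""
    if a.profile_name != b.profile_name:
        raise ProfileMismatchError(
            f"cannot compare categories from profiles {a.profile_name!r} and {b.profile_name!r}"
        )
    return abs(a.code - b.code)


def parse_arrow_symbol(symbol: str, profile: DeviceProfile) -> TrendCategory:
    """Resolve an ASCII arrow alias (case-insensitive) to a category.

    Raises :class:`TrendParseError` for unknown tokens, including double
    arrows given to the FL profile (the device has none).
    """
    token = symbol.strip().lower()
    aliases = _ALIASES[profile.name]
    if token not in aliases:
        raise TrendParseError(
            f"unknown arrow symbol {symbol!r} for profile {profile.name}"
        )
    return profile.category(aliases[token])


def arrow_symbol(category: TrendCategory) -> str:
    """Canonical ASCII spelling of a category, inverse of parse_arrow_symbol."""
    return _CANONICAL[category.code]
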