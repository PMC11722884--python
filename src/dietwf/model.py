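"""Core domain types and elementary water-footprint arithmetic.

The water footprint (WF) of a food is the freshwater volume consumed or
polluted over its full production chain, split into three components:

* green — rainwater evapotranspired by the crop or feed,
* blue — surface and groundwater consumed (irrigation, incorporation),
* grey — the volume needed to dilute pollutant loads to quality standards.

Per-kg values refer to *production weight* (the raw product leaving
agriculture); dietary serving sizes refer to *edible weight*, so pattern
construction converts between the two (see :mod:`dietwf.pattern`).

All quantities are litres; the total WF is always derived as
``green + blue + grey``, never stored independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class WFVector:
    """A (green, blue, grey) water-footprint triple.

    Units are L/kg for per-product values and L/week (or L/day) for
    aggregated diet values; arithmetic never mixes units.
    """

    green: float
    blue: float
    grey: float

    def __post_init__(self) -> None:
        for name in ("green", "blue", "grey"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"WFVector.{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.green + self.blue + self.grey

    def __add__(self, other: "WFVector") -> "WFVector":
        return WFVector(self.green + other.green, self.blue + other.blue, self.grey + other.grey)

    def __sub__(self, other: "WFVector") -> "SignedWFDelta":
        return SignedWFDelta(
            self.green - other.green, self.blue - other.blue, self.grey - other.grey
        )

    def __mul__(self, k: float) -> "WFVector":
        return wf_scale(self, k)

    __rmul__ = __mul__

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.green, self.blue, self.grey)

    def isclose(self, other: "WFVector", abs_tol: float = 1e-9) -> bool:
        return all(
            math.isclose(a, b, rel_tol=0.0, abs_tol=abs_tol)
            for a, b in zip(self.as_tuple(), other.as_tuple())
        )


ZERO_WF = WFVector(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SignedWFDelta:
    """Componentwise difference of two WFVectors; components may be negative.

    Positive values mean water *saved* under the savings sign convention
    used by :mod:`dietwf.scenarios`.
    """

    green: float
    blue: float
    grey: float

    @property
    def total(self) -> float:
        return self.green + self.blue + self.grey

    def __neg__(self) -> "SignedWFDelta":
        return SignedWFDelta(-self.green, -self.blue, -self.grey)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.green, self.blue, self.grey)


@dataclass(frozen=True)
class FoodRecord:
    """One food product: per-kg WF (production weight) plus conversion data.

    edible_fraction is the edible share of production weight, in (0, 1].
    kcal_per_100g / protein_per_100g refer to 100 g of *edible* weight and
    are optional (needed only for energy rescaling and equal-protein swaps).
    aquaculture_fraction, when set, marks the food as seafood: only that
    share of consumed mass is charged against the (aquaculture) WF, the
    wild-caught remainder carrying 0 L/kg.
    """

    name: str
    wf_per_kg: WFVector
    edible_fraction: float = 1.0
    kcal_per_100g: Optional[float] = None
    protein_per_100g: Optional[float] = None
    aquaculture_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("FoodRecord.name must be non-empty")
        if not (0.0 < self.edible_fraction <= 1.0):
            raise ValidationError(
                f"edible_fraction must be in (0, 1], got {self.edible_fraction!r} for {self.name}"
            )
        for attr in ("kcal_per_100g", "protein_per_100g"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValidationError(f"{attr} must be >= 0, got {v!r} for {self.name}")
        if self.aquaculture_fraction is not None and not (0.0 <= self.aquaculture_fraction <= 1.0):
            raise ValidationError(
                f"aquaculture_fraction must be in [0, 1], got {self.aquaculture_fraction!r}"
            )


class WeightingMode(str, Enum):
    SIMPLE_MEAN = "simple_mean"
    SERVING_WEIGHTED = "serving_weighted"
    CONSUMPTION_WEIGHTED = "consumption_weighted"


@dataclass(frozen=True)
class GroupWeighting:
    """How member foods are averaged into a food-group WF.

    * simple_mean — unweighted componentwise mean of member WF/kg.
    * serving_weighted — mean per-serving WF divided by mean serving mass
      (weights are serving masses in g); this is how guideline groups whose
      members have different serving sizes (e.g. dairy cup equivalents:
      244 g milk vs 43 g cheese) are averaged.
    * consumption_weighted — weights are consumption shares summing to 1.
    """

    mode: WeightingMode = WeightingMode.SIMPLE_MEAN
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if isinstance(self.mode, str) and not isinstance(self.mode, WeightingMode):
            object.__setattr__(self, "mode", WeightingMode(self.mode))
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))


@dataclass(frozen=True)
class Conversions:
    """Conversion constants used in pattern construction.

    Defaults are the values the guideline patterns are built with:
    cooked legumes are 2.5x their dry weight; 50% of consumed seafood is
    assumed farmed (wild-caught fish carries 0 L/kg); jam is modelled as
    35% fruit and 40% sugar by mass.
    """

    legume_cooked_to_dry: float = 2.5
    aquaculture_fraction: float = 0.5
    jam_fruit_fraction: float = 0.35
    jam_sugar_fraction: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "legume_cooked_to_dry",
            "aquaculture_fraction",
            "jam_fruit_fraction",
            "jam_sugar_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Conversions.{name} must be positive")


DEFAULT_CONVERSIONS = Conversions()


def wf_scale(v: WFVector, k: float) -> WFVector:
    """Scale a WF vector by a nonnegative factor (e.g. L/kg -> L/week)."""
    if k < 0:
        raise ValidationError(f"scale factor must be >= 0, got {k!r}")
    return WFVector(v.green * k, v.blue * k, v.grey * k)


def wf_add(a: WFVector, b: WFVector) -> WFVector:
    """Componentwise sum of two WF vectors in the same unit."""
    return a + b


def wf_sum(vectors: Sequence[WFVector]) -> WFVector:
    total = ZERO_WF
    for v in vectors:
        total = total + v
    return total


def group_wf(
    members: Sequence[tuple[FoodRecord, float]],
    weighting: GroupWeighting = GroupWeighting(),
) -> WFVector:
    """Average member foods into a single food-group WF in L/kg.

    ``members`` pairs each food with a weight whose meaning depends on the
    mode: ignored for simple_mean, a serving mass in g for
    serving_weighted, a consumption share for consumption_weighted.
    Explicit weights in ``weighting.weights`` override the per-member ones.
    """
    if not members:
        raise ValidationError("group_wf requires at least one member")
    foods = [m[0] for m in members]
    weights = [m[1] for m in members]
    if weighting.weights is not None:
        if len(weighting.weights) != len(members):
            raise ValidationError("weighting.weights length must match members")
        weights = list(weighting.weights)

    n = len(foods)
    if weighting.mode is WeightingMode.SIMPLE_MEAN:
        return wf_scale(wf_sum([f.wf_per_kg for f in foods]), 1.0 / n)

    if weighting.mode is WeightingMode.SERVING_WEIGHTED:
        if any(w is None or w <= 0 for w in weights):
            raise ValidationError("serving_weighted needs a positive serving mass per member")
        # mean per-serving WF over mean serving mass keeps the result in L/kg
        per_serving = wf_sum(
            [wf_scale(f.wf_per_kg, w / 1000.0) for f, w in zip(foods, weights)]
        )
        mean_serving_kg = sum(weights) / n / 1000.0
        return wf_scale(per_serving, 1.0 / n / mean_serving_kg)

    if weighting.mode is WeightingMode.CONSUMPTION_WEIGHTED:
        if any(w is None or w < 0 for w in weights):
            raise ValidationError("consumption_weighted needs nonnegative shares")
        if not math.isclose(sum(weights), 1.0, rel_tol=0.0, abs_tol=1e-9):
            raise ValidationError("consumption shares must sum to 1 within 1e-9")
        return wf_sum([wf_scale(f.wf_per_kg, w) for f, w in zip(foods, weights)])

    raise ValidationError(f"unknown weighting mode {weighting.mode!r}")


def jam_wf(
    fruit: WFVector,
    sugar: WFVector,
    conversions: Conversions = DEFAULT_CONVERSIONS,
) -> WFVector:
    """WF/kg of jam from its fruit and sugar content (default 35% / 40%)."""
    return wf_add(
        wf_scale(fruit, conversions.jam_fruit_fraction),
        wf_scale(sugar, conversions.jam_sugar_fraction),
    )


def cooked_to_dry_mass(
    mass_cooked_g: float, conversions: Conversions = DEFAULT_CONVERSIONS
) -> float:
    """Convert a cooked-legume mass to dry weight (WF databases price dry)."""
    if mass_cooked_g < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_cooked_g!r}")
    return mass_cooked_g / conversions.legume_cooked_to_dry


def effective_seafood_mass(mass_suggested_g: float, aquaculture_fraction: float) -> float:
    """Mass of seafood charged against the aquaculture WF.

    Wild-caught fish carries 0 L/kg, so only the farmed share of consumed
    mass counts; the discount applies to mass, not to the per-kg WF.
    """
    if not (0.0 <= aquaculture_fraction <= 1.0):
        raise ValidationError(
            f"aquaculture_fraction must be in [0, 1], got {aquaculture_fraction!r}"
        )
    if mass_suggested_g < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_suggested_g!r}")
    return mass_suggested_g * aquaculture_fraction


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention of printed report cells)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
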