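"""Stepwise construction of a total / added / free sugar food-composition database.

Many national food-composition tables report per-saccharide contents for only a
fraction of their items.  The engine in this module fills the gap with an
ordered cascade of assignment rules: for **total sugar** a 7-step cascade
(analytical saccharides, carbohydrate-is-all-sugar items, literature values,
dry-weight borrowing from a raw/cooked reference, borrowing from a biologically
similar item, foreign composition tables, and a terminal zero assignment); for
**added and free sugar** an 11-step cascade built on top of the assigned totals
(definitional zero/full assignments, label values, recipe decomposition,
similar-item borrowing, subtraction rules, a fixed-proportion fallback, foreign
values, and a terminal zero).

Every assignment records the step that produced it, so the resulting database
carries full provenance and can be audited step by step.

Definitions used throughout:

* total sugar — the sum of the six common mono- and disaccharides (glucose,
  fructose, galactose, sucrose, lactose, maltose), g/100 g edible portion;
* added sugar — sugars and syrups added during processing or preparation,
  excluding naturally occurring sugars;
* free sugar — added sugar plus the sugars naturally present in honey, syrups
  and fruit juice (WHO definition); intrinsic sugar of intact fruit and milk
  lactose are *not* free sugar;
* available carbohydrate — carbohydrate minus dietary fiber.

Missing data are a distinct state from zero: only the terminal cascade steps
convert absence of information into a 0 g assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: The ten food groups used for reporting and for intake aggregation.
FOOD_GROUPS: tuple[str, ...] = (
    "Cereals and potatoes",
    "Sugars and jams",
    "Pulses and nuts",
    "Fruits and vegetables",
    "Protein rich animal foods",
    "Confectionaries",
    "Fruit and vegetable juices",
    "Sugar-sweetened beverages",
    "Seasonings",
    "Other foods",
)

SACCHARIDES = ("glucose", "fructose", "galactose", "sucrose", "lactose", "maltose")
MONOSACCHARIDES = ("glucose", "fructose", "galactose")
DISACCHARIDES = ("sucrose", "lactose", "maltose")

#: Numerical tolerance for the added <= free <= total <= available-carbohydrate chain.
CAP_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for malformed food data (negative contents, broken invariants)."""


class CyclicReferenceError(CompositionError):
    """Raised when cross-references between food items form a cycle."""


@dataclass
class SaccharideProfile:
    """Per-saccharide contents, g/100 g edible portion; ``None`` marks missing data."""

    glucose: Optional[float] = None
    fructose: Optional[float] = None
    galactose: Optional[float] = None
    sucrose: Optional[float] = None
    lactose: Optional[float] = None
    maltose: Optional[float] = None

    def __post_init__(self) -> None:
        present = [v for v in self.values() if v is not None]
        if any(v < 0 for v in present):
            raise CompositionError(f"negative saccharide content in {self!r}")
        if sum(present) > 100 + CAP_TOL:
            raise CompositionError(f"saccharides sum to more than 100 g/100 g: {self!r}")

    def values(self) -> tuple[Optional[float], ...]:
        return tuple(getattr(self, name) for name in SACCHARIDES)

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values())


def sum_saccharides(profile: SaccharideProfile) -> Optional[float]:
    """Total sugar as the sum of the six saccharides, or ``None`` if any is missing.

    A missing field signals "not analysed", which must drive the cascade to the
    next step rather than raise, hence the ``None`` return instead of an error.
    """
    if not profile.complete:
        return None
    return float(sum(v for v in profile.values() if v is not None))


@dataclass
class ForeignTableRef:
    """Pre-resolved link to one foreign composition-table entry for the same food.

    ``disaccharide_as_monosaccharide_equivalent`` marks sources (notably the UK
    table) that print disaccharides as monosaccharide equivalents; such values
    are deflated by the configured factor (default 0.95) before summing.
    """

    source_country: str
    saccharides: SaccharideProfile = field(default_factory=SaccharideProfile)
    disaccharide_as_monosaccharide_equivalent: bool = False
    added_sugar: Optional[float] = None
    free_sugar: Optional[float] = None


@dataclass
class FoodItem:
    """One food of the composition table: identity, macronutrients, saccharides,
    assignment flags and cross-reference links used by the rule cascades."""

    food_code: str
    name: str
    group: str
    energy: float  # kcal/100 g
    carbohydrate: float  # g/100 g
    dietary_fiber: float = 0.0
    water: float = 0.0
    protein: float = 0.0
    fat: float = 0.0
    saturated_fat: float = 0.0
    saccharides: SaccharideProfile = field(default_factory=SaccharideProfile)
    # flags driving individual cascade steps (explicit inputs, never inferred)
    carbohydrate_is_all_sugar: bool = False
    no_added_sugar: bool = False
    all_sugar_added: bool = False
    is_fruit_juice_or_honey_or_syrup: bool = False
    assume_half_added: bool = False
    # optional direct values
    literature_total_sugar: Optional[float] = None
    natural_sugar: Optional[float] = None  # naturally occurring, non-free sugar (e.g. milk lactose)
    added_sugar_label: Optional[float] = None
    free_sugar_label: Optional[float] = None
    # cross-references
    raw_form_ref: Optional[str] = None
    similar_ref: Optional[str] = None
    unsweetened_ref: Optional[str] = None
    foreign: Optional[ForeignTableRef] = None
    recipe: Optional[list[tuple[str, float]]] = None  # (ingredient code, proportion of 100 g)

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise CompositionError(
                f"{self.food_code}: unknown food group {self.group!r}"
            )
        if self.carbohydrate is None or (isinstance(self.carbohydrate, float) and math.isnan(self.carbohydrate)):
            raise CompositionError(f"{self.food_code}: carbohydrate content missing")
        if self.energy < 0:
            raise CompositionError(f"{self.food_code}: negative energy")
        if not (0 <= self.dietary_fiber and self.carbohydrate <= 100):
            raise CompositionError(
                f"{self.food_code}: carbohydrate/fiber out of range "
                f"(carb={self.carbohydrate}, fiber={self.dietary_fiber})"
            )
        if self.recipe is not None and any(p < 0 for _, p in self.recipe):
            raise CompositionError(f"{self.food_code}: negative recipe proportion")


@dataclass
class SugarAssignment:
    """Assigned sugar contents (g/100 g) plus the step that produced each one."""

    food_code: str
    total_sugar: float
    total_step: int
    added_sugar: float = 0.0
    free_sugar: float = 0.0
    free_step: int = 0


@dataclass
class RuleSet:
    """Configuration of the two cascades.

    ``monosaccharide_equivalent_factor`` deflates disaccharide values printed as
    monosaccharide equivalents (hydrolysis adds one water per glycosidic bond,
    hence the conventional 0.95).  ``fallback_proportion`` is the share of total
    sugar assumed added when a processed food reaches the fixed-proportion step
    with no better information.
    """

    monosaccharide_equivalent_factor: float = 0.95
    fallback_proportion: float = 0.5
    total_step_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    free_step_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)

    def __post_init__(self) -> None:
        for ids, n in ((self.total_step_ids, 7), (self.free_step_ids, 11)):
            if len(ids) != n or list(ids) != sorted(ids):
                raise CompositionError("step ids must be strictly increasing and complete")


def available_carbohydrate(item: FoodItem) -> float:
    """Available carbohydrate = carbohydrate - dietary fiber, g/100 g, clamped at 0."""
    value = item.carbohydrate - item.dietary_fiber
    if value < 0:
        logger.warning(
            "%s: dietary fiber (%.3g) exceeds carbohydrate (%.3g); "
            "available carbohydrate clamped to 0",
            item.food_code, item.dietary_fiber, item.carbohydrate,
        )
        return 0.0
    return float(value)


def monosaccharide_equivalent_adjust(value: float, factor: float = 0.95) -> float:
    """Deflate a disaccharide value printed as monosaccharide equivalents."""
    if value < 0:
        raise CompositionError(f"negative disaccharide value {value}")
    return value * factor


def dry_weight_adjust(referred_value: float, referred: FoodItem, target: FoodItem) -> float:
    """Transfer a sugar content between two forms of a food via their dry-weight ratio.

    The referred value is scaled by (100 - water_target)/(100 - water_referred)
    and capped at the target's available carbohydrate, so e.g. drying a fruit
    concentrates its sugar and reconstituting dilutes it.
    """
    if referred.water >= 100:
        raise CompositionError(
            f"{referred.food_code}: water content {referred.water} >= 100, dry weight undefined"
        )
    ratio = (100.0 - target.water) / (100.0 - referred.water)
    return min(referred_value * ratio, available_carbohydrate(target))


class SugarDatabaseBuilder:
    """Applies both cascades to a collection of foods, resolving cross-references.

    Assignments are computed by memoised recursion over the reference graph, so
    the order of the input rows never influences any result.  A genuine cycle of
    references raises :class:`CyclicReferenceError`.
    """

    def __init__(self, items: Iterable[FoodItem], rules: Optional[RuleSet] = None):
        self.rules = rules or RuleSet()
        self.items: dict[str, FoodItem] = {}
        for item in items:
            if item.food_code in self.items:
                raise CompositionError(f"duplicate food code {item.food_code}")
            self.items[item.food_code] = item
        self._totals: dict[str, tuple[float, int]] = {}
        self._frees: dict[str, tuple[float, float, int]] = {}

    # ---------------------------------------------------------------- totals

    def total_sugar(self, code: str) -> tuple[float, int]:
        """Assigned total sugar and the step (1-7) that produced it."""
        return self._total(code, ())

    def _total(self, code: str, stack: tuple[str, ...]) -> tuple[float, int]:
        if code in self._totals:
            return self._totals[code]
        if code in stack:
            raise CyclicReferenceError(
                "cyclic total-sugar reference: " + " -> ".join(stack + (code,))
            )
        item = self.items[code]
        stack = stack + (code,)
        cap = available_carbohydrate(item)
        s = self.rules.total_step_ids

        result: Optional[tuple[float, int]] = None
        # step 1: full analytical saccharide profile
        analytic = sum_saccharides(item.saccharides)
        if analytic is not None:
            result = (min(analytic, cap), s[0])
        # step 2: carbohydrate consists entirely of sugar
        elif item.carbohydrate_is_all_sugar:
            result = (cap, s[1])
        # step 3: literature value
        elif item.literature_total_sugar is not None:
            result = (min(item.literature_total_sugar, cap), s[2])
        if result is None:
            # step 4: raw/cooked (dried) form of the same food, dry-weight adjusted
            result = self._borrow_total(item, item.raw_form_ref, stack, s[3], cap)
        if result is None:
            # step 5: similar item (same family or order), dry-weight adjusted
            result = self._borrow_total(item, item.similar_ref, stack, s[4], cap)
        if result is None and item.foreign is not None:
            value = self._foreign_total(item.foreign)
            if value is not None:
                result = (min(value, cap), s[5])
        if result is None:
            # step 7: nothing known -- assign 0 g
            result = (0.0, s[6])
        self._totals[code] = result
        return result

    def _borrow_total(
        self, item: FoodItem, ref: Optional[str], stack: tuple[str, ...], step: int, cap: float
    ) -> Optional[tuple[float, int]]:
        if ref is None:
            return None
        if ref not in self.items:
            logger.warning(
                "%s: reference %r not in database; falling through to next step",
                item.food_code, ref,
            )
            return None
        ref_total, _ = self._total(ref, stack)
        value = dry_weight_adjust(ref_total, self.items[ref], item)
        return (min(value, cap), step)

    def _foreign_total(self, foreign: ForeignTableRef) -> Optional[float]:
        values = foreign.saccharides.values()
        if all(v is None for v in values):
            return None
        factor = (
            self.rules.monosaccharide_equivalent_factor
            if foreign.disaccharide_as_monosaccharide_equivalent
            else 1.0
        )
        total = 0.0
        for name in MONOSACCHARIDES:
            v = getattr(foreign.saccharides, name)
            if v is not None:
                total += v
        for name in DISACCHARIDES:
            v = getattr(foreign.saccharides, name)
            if v is not None:
                total += monosaccharide_equivalent_adjust(v, factor)
        return total

    # ---------------------------------------------------------- added / free

    def added_free(self, code: str) -> tuple[float, float, int]:
        """Assigned (added, free) sugar and the step (1-11) that produced them."""
        return self._free(code, ())

    def _free(self, code: str, stack: tuple[str, ...]) -> tuple[float, float, int]:
        if code in self._frees:
            return self._frees[code]
        if code in stack:
            raise CyclicReferenceError(
                "cyclic added/free reference: " + " -> ".join(stack + (code,))
            )
        item = self.items[code]
        stack = stack + (code,)
        total, _ = self._total(code, ())
        s = self.rules.free_step_ids

        added: float
        free: float
        step: int
        # step 1: unprocessed food with no added sugar -- all sugar intrinsic
        if item.no_added_sugar and not item.is_fruit_juice_or_honey_or_syrup:
            added, free, step = 0.0, 0.0, s[0]
        # step 2: fruit juice / honey / syrup with nothing added -- all sugar free
        elif item.no_added_sugar and item.is_fruit_juice_or_honey_or_syrup:
            added, free, step = 0.0, total, s[1]
        # step 3: the food *is* sugar (or all its sugar was added)
        elif item.all_sugar_added:
            added, free, step = total, total, s[2]
        # step 4: analytical / label value
        elif item.added_sugar_label is not None or item.free_sugar_label is not None:
            a = item.added_sugar_label
            f = item.free_sugar_label
            added = a if a is not None else (f if f is not None else 0.0)
            free = f if f is not None else added
            step = s[3]
        # step 5: recipe decomposition over assigned ingredients
        elif item.recipe:
            added, free = 0.0, 0.0
            for ing_code, prop in item.recipe:
                if ing_code not in self.items:
                    raise CompositionError(
                        f"{code}: recipe ingredient {ing_code!r} not in database"
                    )
                ing_added, ing_free, _ = self._free(ing_code, stack)
                added += prop * ing_added
                free += prop * ing_free
            step = s[4]
        # step 6: borrow added/free *fractions* of a similar item
        elif item.similar_ref is not None and item.similar_ref in self.items:
            sim_added, sim_free, _ = self._free(item.similar_ref, stack)
            sim_total, _ = self._total(item.similar_ref, ())
            if sim_total > 0:
                added = total * sim_added / sim_total
                free = total * sim_free / sim_total
            else:
                added = free = 0.0
            step = s[5]
        # step 7: subtract the unsweetened equivalent of the same food
        elif item.unsweetened_ref is not None and item.unsweetened_ref in self.items:
            base_total, _ = self._total(item.unsweetened_ref, stack)
            added = free = max(total - base_total, 0.0)
            step = s[6]
        # step 8: subtract the naturally occurring sugar (e.g. lactose in sweetened dairy)
        elif item.natural_sugar is not None:
            added = free = max(total - item.natural_sugar, 0.0)
            step = s[7]
        # step 9: fixed-proportion fallback for processed foods without better data
        elif item.assume_half_added:
            added = free = self.rules.fallback_proportion * total
            step = s[8]
        # step 10: foreign-table added/free values
        elif item.foreign is not None and (
            item.foreign.added_sugar is not None or item.foreign.free_sugar is not None
        ):
            fa, ff = item.foreign.added_sugar, item.foreign.free_sugar
            added = fa if fa is not None else 0.0
            free = ff if ff is not None else added
            step = s[9]
        # step 11: nothing known -- assign 0 g
        else:
            added, free, step = 0.0, 0.0, s[10]

        added, free = self._clamp_chain(code, added, free, total)
        self._frees[code] = (added, free, step)
        return self._frees[code]

    def _clamp_chain(self, code: str, added: float, free: float, total: float) -> tuple[float, float]:
        if free > total + CAP_TOL or added > free + CAP_TOL:
            logger.warning(
                "%s: clamping added/free chain (added=%.6g, free=%.6g, total=%.6g)",
                code, added, free, total,
            )
        free = min(max(free, 0.0), total)
        added = min(max(added, 0.0), free)
        return added, free

    # ----------------------------------------------------------------- build

    def build(self) -> dict[str, SugarAssignment]:
        """Assign every item; result keyed (and iterated) by food code."""
        out: dict[str, SugarAssignment] = {}
        for code in self.items:
            total, total_step = self.total_sugar(code)
            added, free, free_step = self.added_free(code)
            out[code] = SugarAssignment(
                food_code=code,
                total_sugar=total,
                total_step=total_step,
                added_sugar=added,
                free_sugar=free,
                free_step=free_step,
            )
        return out


def build_database(
    items: Iterable[FoodItem], rules: Optional[RuleSet] = None
) -> dict[str, SugarAssignment]:
    """Convenience wrapper: run both cascades over ``items``."""
    return SugarDatabaseBuilder(items, rules).build()


@dataclass
class ValidationReport:
    """Invariant violations plus per-step item counts in the layout of the
    published step-count tables (food groups x steps)."""

    violations: list[str]
    total_step_counts: "object"  # pandas DataFrame: group x step 1-7
    free_step_counts: "object"  # pandas DataFrame: group x step 1-11

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_database(
    items: Mapping[str, FoodItem] | Sequence[FoodItem],
    assignments: Mapping[str, SugarAssignment],
    rules: Optional[RuleSet] = None,
) -> ValidationReport:
    """Check every assignment against the sugar-chain invariants and tabulate steps."""
    import pandas as pd

    rules = rules or RuleSet()
    if not isinstance(items, Mapping):
        items = {it.food_code: it for it in items}
    violations: list[str] = []
    total_counts = pd.DataFrame(
        0, index=list(FOOD_GROUPS), columns=list(rules.total_step_ids)
    )
    free_counts = pd.DataFrame(
        0, index=list(FOOD_GROUPS), columns=list(rules.free_step_ids)
    )
    for code, a in assignments.items():
        item = items[code]
        cap = available_carbohydrate(item)
        for label, value in (
            ("total", a.total_sugar), ("added", a.added_sugar), ("free", a.free_sugar)
        ):
            if value < -CAP_TOL:
                violations.append(f"{code}: negative {label} sugar ({value})")
        if a.added_sugar > a.free_sugar + CAP_TOL:
            violations.append(f"{code}: added sugar exceeds free sugar")
        if a.free_sugar > a.total_sugar + CAP_TOL:
            violations.append(f"{code}: free sugar exceeds total sugar")
        if a.total_sugar > cap + CAP_TOL:
            violations.append(f"{code}: total sugar exceeds available carbohydrate")
        if a.total_step not in rules.total_step_ids:
            violations.append(f"{code}: unknown total step {a.total_step}")
        else:
            total_counts.loc[item.group, a.total_step] += 1
        if a.free_step not in rules.free_step_ids:
            violations.append(f"{code}: unknown free step {a.free_step}")
        else:
            free_counts.loc[item.group, a.free_step] += 1
    return ValidationReport(violations, total_counts, free_counts)
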