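"""The three-component framework for specifying a drug-count measure.

A measure is a complete configuration of three components:

* **scope** — which products qualify as drugs (prescription status, drug
  type, route, dosage form, common use);
* **uniqueness** — how duplicates are merged: product-based (a
  combination product counts once) or ingredient-based (dissected into
  ingredients), at one of four key levels from bare ingredient up to
  ingredient-route-form-strength;
* **timeframe** — over what time fills are attributed to the regimen:
  cross-sectional around an index date (with an allowable index gap,
  optional post-index rescue, optional cabinet-supply and
  hospitalization adjustments, optional per-drug-class overrides) or
  longitudinal over a window.

The preset registry ships a default plus fourteen single-component
variations of it — each variant alters exactly one framework component —
so sensitivity of the count to each methodological choice can be probed
directly.

Configs are JSON documents; a config may name a ``preset`` and override
fields of it. Validation errors carry a JSON-pointer-style path.
"""

from __future__ import annotations

import json
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_serializer, model_validator
from pydantic import ValidationError as _PydanticValidationError

from .model import COMMON_USES, DOSAGE_FORMS, DRUG_TYPES, ROUTES, RX_STATUSES

_PRODUCT_FIELDS = frozenset({
    "route", "dosage_form", "rx_status", "drug_type", "common_use",
    "is_supply", "is_metered_dose_inhaler",
})


class MeasureConfigError(ValueError):
    """A measure config failed schema validation; message includes /json/pointer paths."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class ScopeSpec(_Frozen):
    """Which products are considered drugs. Defaults admit all prescription products."""

    rx_statuses: frozenset[str] = frozenset({"prescription"})
    drug_types: frozenset[str] = DRUG_TYPES
    routes_include: Union[Literal["all"], frozenset[str]] = "all"
    routes_exclude: frozenset[str] = frozenset()
    dosage_forms: Union[Literal["all"], frozenset[str]] = "all"
    common_uses: frozenset[str] = COMMON_USES

    @field_serializer(
        "rx_statuses", "drug_types", "routes_exclude", "common_uses",
        "routes_include", "dosage_forms",
    )
    def _sorted(self, v):
        return v if isinstance(v, str) else sorted(v)

    @model_validator(mode="after")
    def _check(self) -> "ScopeSpec":
        for name, vals, vocab in [
            ("rx_statuses", self.rx_statuses, RX_STATUSES),
            ("drug_types", self.drug_types, DRUG_TYPES),
            ("routes_exclude", self.routes_exclude, ROUTES),
            ("common_uses", self.common_uses, COMMON_USES),
        ]:
            bad = vals - vocab
            if bad:
                raise ValueError(f"{name}: unknown token(s) {sorted(bad)}")
        if self.routes_include != "all":
            if self.routes_include - ROUTES:
                raise ValueError(
                    f"routes_include: unknown token(s) {sorted(self.routes_include - ROUTES)}"
                )
            if self.routes_exclude:
                raise ValueError(
                    "use either routes_include or routes_exclude, not both"
                )
        if self.dosage_forms != "all" and self.dosage_forms - DOSAGE_FORMS:
            raise ValueError(
                f"dosage_forms: unknown token(s) {sorted(self.dosage_forms - DOSAGE_FORMS)}"
            )
        return self


UniquenessLevel = Literal[
    "ingredient", "ingredient_route", "ingredient_route_form",
    "ingredient_route_form_strength",
]


class UniquenessSpec(_Frozen):
    """How duplicate drugs merge into one counted key."""

    basis: Literal["product", "ingredient"] = "product"
    level: UniquenessLevel = "ingredient_route_form"


class IndexGapRule(_Frozen):
    """Allowable index gap: flexible (multiplier x days supply) or fixed days."""

    mode: Literal["flexible", "fixed"] = "flexible"
    multiplier: Optional[float] = 1.0
    fixed_days: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "IndexGapRule":
        if self.mode == "flexible":
            if self.multiplier is None or self.multiplier <= 0:
                raise ValueError("flexible mode requires multiplier > 0")
            if self.fixed_days is not None:
                raise ValueError("flexible mode must not set fixed_days")
        else:
            if self.fixed_days is None or self.fixed_days <= 0:
                raise ValueError("fixed mode requires fixed_days > 0")
            if self.multiplier is not None:
                raise ValueError("fixed mode must not set multiplier")
        return self

    @model_validator(mode="before")
    @classmethod
    def _drop_default_multiplier(cls, data):
        # a bare {"mode": "fixed", "fixed_days": n} should not inherit the
        # flexible-mode multiplier default
        if isinstance(data, dict) and data.get("mode") == "fixed":
            data = dict(data)
            data.setdefault("multiplier", None)
        return data

    def allowable_days(self, days_supply: int) -> float:
        if self.mode == "flexible":
            return self.multiplier * days_supply
        return float(self.fixed_days)


class PostIndexRule(_Frozen):
    """Rescue via post-index fills: a drug failing the index-gap test still
    counts if the gap between its last pre-index and first post-index fill
    is under the allowable pre-post fill gap."""

    enabled: bool = False
    gap_mode: Literal["flexible", "fixed"] = "flexible"
    multiplier: Optional[float] = 2.0
    fixed_days: Optional[int] = None

    @model_validator(mode="before")
    @classmethod
    def _drop_default_multiplier(cls, data):
        if isinstance(data, dict) and data.get("gap_mode") == "fixed":
            data = dict(data)
            data.setdefault("multiplier", None)
        return data

    @model_validator(mode="after")
    def _check(self) -> "PostIndexRule":
        if self.gap_mode == "flexible":
            if self.multiplier is None or self.multiplier <= 0:
                raise ValueError("flexible gap_mode requires multiplier > 0")
            if self.fixed_days is not None:
                raise ValueError("flexible gap_mode must not set fixed_days")
        else:
            if self.fixed_days is None or self.fixed_days <= 0:
                raise ValueError("fixed gap_mode requires fixed_days > 0")
            if self.multiplier is not None:
                raise ValueError("fixed gap_mode must not set multiplier")
        return self

    def allowable_days(self, days_supply: int) -> float:
        if self.gap_mode == "flexible":
            return self.multiplier * days_supply
        return float(self.fixed_days)


class CabinetSupplyRule(_Frozen):
    """Add estimated on-hand (stockpiled) supply at the last pre-index fill,
    accumulated over a lookback window, to the allowable index gap."""

    enabled: bool = False
    lookback_days: int = 180

    @model_validator(mode="after")
    def _check(self) -> "CabinetSupplyRule":
        if self.enabled and self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive when enabled")
        return self


class OverrideRule(_Frozen):
    """An alternative index-gap rule for products matching an attribute
    predicate (e.g. a wider gap for as-needed drugs or metered-dose
    inhalers). A matching drug counts if it satisfies EITHER the base
    rule or the override rule."""

    predicate: dict[str, Union[str, bool]]
    rule: IndexGapRule

    @model_validator(mode="after")
    def _check(self) -> "OverrideRule":
        if not self.predicate:
            raise ValueError("predicate must name at least one product attribute")
        bad = set(self.predicate) - _PRODUCT_FIELDS
        if bad:
            raise ValueError(
                f"predicate references non-product field(s) {sorted(bad)}"
            )
        return self


class TimeframeSpec(_Frozen):
    orientation: Literal["cross_sectional", "longitudinal"] = "cross_sectional"
    index_gap: Optional[IndexGapRule] = IndexGapRule()
    post_index: PostIndexRule = PostIndexRule()
    cabinet: CabinetSupplyRule = CabinetSupplyRule()
    hospitalization_adjustment: bool = False
    overrides: tuple[OverrideRule, ...] = ()
    longitudinal_window: Optional[tuple[int, int]] = None

    @model_validator(mode="after")
    def _check(self) -> "TimeframeSpec":
        if self.orientation == "cross_sectional" and self.index_gap is None:
            raise ValueError("cross_sectional orientation requires index_gap")
        if self.orientation == "longitudinal":
            if self.longitudinal_window is None:
                raise ValueError("longitudinal orientation requires longitudinal_window")
            lo, hi = self.longitudinal_window
            if lo > hi:
                raise ValueError("longitudinal_window start must be <= end")
        return self


class MeasureSpec(_Frozen):
    measure_id: str
    scope: ScopeSpec = ScopeSpec()
    uniqueness: UniquenessSpec = UniquenessSpec()
    timeframe: TimeframeSpec = TimeframeSpec()
    description: str = ""

    def components(self) -> dict[str, dict]:
        """The three framework components in serialized form, for comparing
        which component a variant altered."""
        d = serialize_measure(self)
        return {k: d[k] for k in ("scope", "uniqueness", "timeframe")}


# ---------------------------------------------------------------------------
# Preset registry: the default and its fourteen single-component variants.

def _build_presets() -> dict[str, MeasureSpec]:
    default = MeasureSpec(
        measure_id="default",
        description=(
            "Prescription products; product-based uniqueness at the "
            "ingredient(s)-route-form level; cross-sectional with flexible "
            "allowable index gap of the days supply"
        ),
    )
    upd = default.model_copy  # field-wise variant construction
    presets = {
        "default": default,
        "v1": upd(update=dict(
            measure_id="v1",
            scope=ScopeSpec(rx_statuses=RX_STATUSES),
            description="Rx and OTC products",
        )),
        "v2": upd(update=dict(
            measure_id="v2",
            scope=ScopeSpec(routes_include=frozenset({"oral"})),
            description="Oral Rx products",
        )),
        "v3": upd(update=dict(
            measure_id="v3",
            scope=ScopeSpec(routes_exclude=frozenset({"topical"})),
            description="Non-topical Rx products",
        )),
        "v4": upd(update=dict(
            measure_id="v4",
            scope=ScopeSpec(common_uses=frozenset({"regular"})),
            description="Regularly used Rx products (as-needed excluded)",
        )),
        "v5": upd(update=dict(
            measure_id="v5",
            uniqueness=UniquenessSpec(basis="ingredient", level="ingredient"),
            description="Ingredient-based at ingredient level",
        )),
        "v6": upd(update=dict(
            measure_id="v6",
            uniqueness=UniquenessSpec(basis="ingredient", level="ingredient_route"),
            description="Ingredient-based at ingredient-route level",
        )),
        "v7": upd(update=dict(
            measure_id="v7",
            timeframe=TimeframeSpec(index_gap=IndexGapRule(multiplier=1.2)),
            description="Flexible allowable index gap of 1.2 x days supply",
        )),
        "v8": upd(update=dict(
            measure_id="v8",
            timeframe=TimeframeSpec(index_gap=IndexGapRule(mode="fixed", fixed_days=90)),
            description="Fixed allowable index gap of 90 days",
        )),
        "v9": upd(update=dict(
            measure_id="v9",
            timeframe=TimeframeSpec(index_gap=IndexGapRule(mode="fixed", fixed_days=180)),
            description="Fixed allowable index gap of 180 days",
        )),
        "v10": upd(update=dict(
            measure_id="v10",
            timeframe=TimeframeSpec(
                post_index=PostIndexRule(enabled=True, multiplier=2.0),
            ),
            description="Post-index fills: pre-post fill gap under 2 x days supply",
        )),
        "v11": upd(update=dict(
            measure_id="v11",
            timeframe=TimeframeSpec(
                cabinet=CabinetSupplyRule(enabled=True, lookback_days=180),
            ),
            description="Prior fill history: 180-day cabinet supply",
        )),
        "v12": upd(update=dict(
            measure_id="v12",
            timeframe=TimeframeSpec(hospitalization_adjustment=True),
            description="Hospitalization adjustment during the index gap",
        )),
        "v13": upd(update=dict(
            measure_id="v13",
            timeframe=TimeframeSpec(overrides=(
                OverrideRule(
                    predicate={"common_use": "as_needed"},
                    rule=IndexGapRule(mode="fixed", fixed_days=180),
                ),
            )),
            description="As-needed drugs: fixed allowable index gap of 180 days",
        )),
        "v14": upd(update=dict(
            measure_id="v14",
            timeframe=TimeframeSpec(overrides=(
                OverrideRule(
                    predicate={"is_metered_dose_inhaler": True},
                    rule=IndexGapRule(mode="fixed", fixed_days=180),
                ),
            )),
            description="Metered-dose inhalers: fixed allowable index gap of 180 days",
        )),
    }
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> MeasureSpec:
    """Return one of the registered measures (``default``, ``v1``..``v14``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise MeasureConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def serialize_measure(measure: MeasureSpec) -> dict:
    """JSON-ready dict; ``parse_measure`` inverts it."""
    return measure.model_dump(mode="json", exclude_none=True)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if (
            isinstance(val, dict)
            and isinstance(out.get(key), dict)
            # a rule whose mode changes is replaced wholesale, not merged,
            # so stale mode-specific fields don't linger
            and not (
                ("mode" in val and val["mode"] != out[key].get("mode"))
                or ("gap_mode" in val and val["gap_mode"] != out[key].get("gap_mode"))
            )
        ):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def parse_measure(config: Union[dict, str]) -> MeasureSpec:
    """Build a MeasureSpec from a config document (dict or JSON text).

    The document may reference a ``preset`` by name and override any of
    its fields; overrides merge field-wise into the preset. Schema
    violations raise :class:`MeasureConfigError` with a
    JSON-pointer-style path to each offending field.
    """
    if isinstance(config, str):
        config = json.loads(config)
    if not isinstance(config, dict):
        raise MeasureConfigError("measure config must be a JSON object")
    config = dict(config)
    preset_name = config.pop("preset", None)
    if preset_name is not None:
        base = serialize_measure(preset(preset_name))
        config = _deep_merge(base, config)
    if "measure_id" not in config:
        raise MeasureConfigError("/measure_id: field required")
    try:
        return MeasureSpec.model_validate(config)
    except _PydanticValidationError as exc:
        paths = "; ".join(
            "/" + "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise MeasureConfigError(paths) from None


def load_measure(name_or_path: str) -> MeasureSpec:
    """Resolve a preset name or a path to a JSON measure config."""
    if name_or_path in _PRESETS:
        return _PRESETS[name_or_path]
    from pathlib import Path

    p = Path(name_or_path)
    if p.exists():
        return parse_measure(p.read_text())
    raise MeasureConfigError(
        f"{name_or_path!r} is neither a preset ({', '.join(PRESET_NAMES)}) "
        "nor an existing config file"
    )
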