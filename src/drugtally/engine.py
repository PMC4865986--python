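"""The drug-counting engine.

Cross-sectional counting asks: which drugs were in the patient's regimen
on the index date, given only dispensing records? The engine answers per
drug key:

1. Fills whose product fails the scope filter are dropped.
2. Remaining fills are grouped into drug keys per the uniqueness spec.
3. The *anchor* is the last fill of the key strictly before the index
   date; the *observed index gap* is the days from the anchor to index.
4. The *allowable index gap* comes from the base rule — flexible
   (multiplier x anchor days supply) or fixed — optionally extended by
   the estimated cabinet (on-hand) supply at the anchor and/or by
   inpatient days falling inside the gap (hospital days don't consume
   the home supply).
5. The key counts iff observed gap < allowable gap (strict: a supply
   that runs out exactly on the index date does not count). A key whose
   anchor product matches an override predicate counts if it passes
   EITHER the base rule or the override's gap rule.
6. If post-index rescue is enabled and the key failed, it still counts
   when the gap from the anchor to the first post-index fill is under
   the allowable pre-post fill gap.

Longitudinal counting simply counts distinct keys among in-scope fills
inside the window.

Gap arithmetic is exact calendar-day subtraction; flexible allowable
gaps may be non-integral and are compared as real numbers without
rounding. A fill dated on the index day is post-index, not prior. Fills
of one key on one date are treated as split fills of a single
prescription: their days supplies are summed into one anchor event.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .measures import IndexGapRule, MeasureSpec, OverrideRule, ScopeSpec, UniquenessSpec
from .model import DrugProduct, FillRecord, Hospitalization, PatientHistory

STAY_CONVENTIONS = ("admit_inclusive", "both_inclusive", "both_exclusive")


def in_scope(product: DrugProduct, scope: ScopeSpec) -> bool:
    """True iff the product passes every scope subcomponent filter."""
    if product.rx_status not in scope.rx_statuses:
        return False
    if product.drug_type not in scope.drug_types:
        return False
    if scope.routes_include != "all" and product.route not in scope.routes_include:
        return False
    if product.route in scope.routes_exclude:
        return False
    if scope.dosage_forms != "all" and product.dosage_form not in scope.dosage_forms:
        return False
    if product.common_use not in scope.common_uses:
        return False
    return True


def _key_suffix(product: DrugProduct, level: str) -> str:
    parts = []
    if level in ("ingredient_route", "ingredient_route_form",
                 "ingredient_route_form_strength"):
        parts.append(product.route)
    if level in ("ingredient_route_form", "ingredient_route_form_strength"):
        parts.append(product.dosage_form)
    if level == "ingredient_route_form_strength":
        parts.append(product.strength.lower())
    return ("-" + "-".join(parts)) if parts else ""


def drug_keys(product: DrugProduct, uniq: UniquenessSpec) -> frozenset[str]:
    """Canonical counting key(s) for a product.

    Product basis yields one key per product (ingredients joined, sorted
    and lower-cased, so key identity is order-independent); ingredient
    basis yields one key per ingredient. Route/form/strength are
    appended as the level demands.
    """
    suffix = _key_suffix(product, uniq.level)
    names = sorted(i.lower() for i in product.ingredients)
    if uniq.basis == "product":
        return frozenset({"/".join(names) + suffix})
    return frozenset({name + suffix for name in names})


def observed_index_gap(anchor_fill: FillRecord, index_date: date) -> int:
    """Whole days between the last pre-index fill and the index date."""
    if anchor_fill.fill_date >= index_date:
        raise ValueError(
            f"anchor fill {anchor_fill.fill_date} is not prior to index {index_date}"
        )
    return (index_date - anchor_fill.fill_date).days


def cabinet_days_on_hand(
    key_fills_before_anchor: Sequence[tuple[date, int]],
    anchor_date: date,
    lookback_days: int,
) -> float:
    """Estimated leftover days of supply on hand on the anchor date.

    ``key_fills_before_anchor`` are (fill_date, days_supply) pairs of the
    same drug key, all strictly before the anchor. Fills within
    ``lookback_days`` of the anchor are replayed chronologically: supply
    is consumed one day per calendar day, refills stack on top of any
    remainder, and the balance floors at zero (a patient cannot be
    negative days ahead). The carry is uncapped — stockpiling may
    accumulate across the window. Example: one prior fill of 30 days
    supply, 27 days before the anchor, leaves 3 days on hand.
    """
    window_start = anchor_date - timedelta(days=lookback_days)
    fills = sorted(
        (d, ds) for d, ds in key_fills_before_anchor
        if window_start <= d < anchor_date
    )
    carry = 0.0
    for (d, ds), next_date in zip(fills, [f[0] for f in fills[1:]] + [anchor_date]):
        carry = max(0.0, carry + ds - (next_date - d).days)
    return carry


def inpatient_days_in_gap(
    hospitalizations: Iterable[Hospitalization],
    anchor_date: date,
    index_date: date,
    stay_convention: str = "admit_inclusive",
) -> int:
    """Distinct inpatient calendar days strictly inside (anchor, index).

    Overlapping stays are unioned before counting. The default
    convention treats a stay as [admit, discharge): the admission day is
    an inpatient day, the discharge day is not. ``both_inclusive`` and
    ``both_exclusive`` are offered as dialects since claims sources
    differ on this.
    """
    if stay_convention not in STAY_CONVENTIONS:
        raise ValueError(
            f"stay_convention must be one of {STAY_CONVENTIONS}, got {stay_convention!r}"
        )
    days: set[date] = set()
    for h in hospitalizations:
        start = h.admit_date
        end = h.discharge_date  # exclusive bound under admit_inclusive
        if stay_convention == "both_inclusive":
            end = end + timedelta(days=1)
        elif stay_convention == "both_exclusive":
            start = start + timedelta(days=1)
        d = start
        while d < end:
            if anchor_date < d < index_date:
                days.add(d)
            d += timedelta(days=1)
    return len(days)


@dataclass(frozen=True)
class DrugEvidence:
    """Per-key audit trail: why a drug did or did not count."""

    key: str
    counted: bool
    rule_fired: str  # base_gap | override_gap | post_index | none
    anchor_fill_date: date
    days_supply: int
    observed_index_gap: int
    allowable_index_gap: float
    cabinet_days: float = 0.0
    inpatient_days_in_gap: int = 0
    observed_pre_post_gap: Optional[int] = None


@dataclass(frozen=True)
class CountResult:
    patient_id: str
    measure_id: str
    count: int
    evidence: tuple[DrugEvidence, ...] = ()


def _matching_override(
    product: DrugProduct, overrides: Sequence[OverrideRule]
) -> Optional[IndexGapRule]:
    for ov in overrides:
        if all(getattr(product, k) == v for k, v in ov.predicate.items()):
            return ov.rule
    return None


def _evaluate_group(
    group_events: Sequence[tuple[date, int, DrugProduct]],
    history: PatientHistory,
    measure: MeasureSpec,
    stay_convention: str,
) -> Optional[dict]:
    """Timeframe evaluation for one drug's fill timeline.

    Returns evidence fields, or None when the drug has no pre-index
    anchor (only post-index fills: it cannot count under a
    cross-sectional rule anchored at the last prior fill).
    """
    tf = measure.timeframe
    index_date = history.index.index_date
    # collapse same-date fills (split fills of one prescription)
    by_date: dict[date, int] = {}
    product_by_date: dict[date, DrugProduct] = {}
    for d, ds, prod in group_events:
        by_date[d] = by_date.get(d, 0) + ds
        product_by_date[d] = prod
    events = sorted(by_date.items())
    pre = [(d, ds) for d, ds in events if d < index_date]
    if not pre:
        return None
    anchor_date, anchor_ds = pre[-1]
    anchor_product = product_by_date[anchor_date]
    observed = (index_date - anchor_date).days

    allowable = tf.index_gap.allowable_days(anchor_ds)
    cabinet = 0.0
    if tf.cabinet.enabled:
        cabinet = cabinet_days_on_hand(pre[:-1], anchor_date, tf.cabinet.lookback_days)
        allowable += cabinet
    inpatient = 0
    if tf.hospitalization_adjustment:
        inpatient = inpatient_days_in_gap(
            history.hospitalizations, anchor_date, index_date, stay_convention
        )
        allowable += inpatient

    rule_fired = "none"
    if observed < allowable:
        rule_fired = "base_gap"
    else:
        override_rule = _matching_override(anchor_product, tf.overrides)
        if override_rule is not None and observed < override_rule.allowable_days(anchor_ds):
            rule_fired = "override_gap"

    pre_post_gap: Optional[int] = None
    if tf.post_index.enabled:
        post = [d for d, _ in events if d > index_date]
        if post:
            pre_post_gap = (post[0] - anchor_date).days
            if rule_fired == "none" and pre_post_gap < tf.post_index.allowable_days(anchor_ds):
                rule_fired = "post_index"

    return dict(
        counted=rule_fired != "none",
        rule_fired=rule_fired,
        anchor_fill_date=anchor_date,
        days_supply=anchor_ds,
        observed_index_gap=observed,
        allowable_index_gap=allowable,
        cabinet_days=cabinet,
        inpatient_days_in_gap=inpatient,
        observed_pre_post_gap=pre_post_gap,
    )


def count_drugs(
    history: PatientHistory,
    measure: MeasureSpec,
    dictionary: Mapping[str, DrugProduct],
    stay_convention: str = "admit_inclusive",
) -> CountResult:
    """Count the drugs in one patient's regimen under one measure.

    Under product basis, fills group directly by their configured-level
    key and each key is evaluated once. Under ingredient basis,
    eligibility is evaluated per product first (each product's own fill
    chain defines its anchor and gaps) and an ingredient key counts if
    ANY product containing it satisfied the timeframe rule; evidence per
    ingredient key is taken from a counting product when there is one,
    else from the product with the latest anchor.
    """
    if measure.timeframe.orientation == "longitudinal":
        return _count_longitudinal(history, measure, dictionary)

    scoped = [
        (f, dictionary[f.product_id]) for f in history.fills
        if in_scope(dictionary[f.product_id], measure.scope)
    ]
    uniq = measure.uniqueness
    index_date = history.index.index_date

    if uniq.basis == "product":
        groups: dict[str, list[tuple[date, int, DrugProduct]]] = {}
        for f, prod in scoped:
            (key,) = drug_keys(prod, uniq)
            groups.setdefault(key, []).append((f.fill_date, f.days_supply, prod))
        evidence = []
        for key in sorted(groups):
            ev = _evaluate_group(groups[key], history, measure, stay_convention)
            if ev is not None:
                evidence.append(DrugEvidence(key=key, **ev))
    else:
        # evaluate per product signature, then project onto ingredient keys
        sig_groups: dict[tuple, list[tuple[date, int, DrugProduct]]] = {}
        for f, prod in scoped:
            sig = (tuple(sorted(i.lower() for i in prod.ingredients)),
                   prod.route, prod.dosage_form, prod.strength.lower())
            sig_groups.setdefault(sig, []).append((f.fill_date, f.days_supply, prod))
        per_key: dict[str, list[dict]] = {}
        for sig in sorted(sig_groups):
            events = sig_groups[sig]
            ev = _evaluate_group(events, history, measure, stay_convention)
            if ev is None:
                continue
            prod = events[-1][2]
            for key in drug_keys(prod, uniq):
                per_key.setdefault(key, []).append(ev)
        evidence = []
        for key in sorted(per_key):
            candidates = per_key[key]
            counting = [ev for ev in candidates if ev["counted"]]
            pick = max(counting or candidates, key=lambda e: e["anchor_fill_date"])
            evidence.append(DrugEvidence(key=key, **pick))

    count = sum(ev.counted for ev in evidence)
    return CountResult(
        patient_id=history.patient_id,
        measure_id=measure.measure_id,
        count=count,
        evidence=tuple(evidence),
    )


def _count_longitudinal(
    history: PatientHistory,
    measure: MeasureSpec,
    dictionary: Mapping[str, DrugProduct],
) -> CountResult:
    lo, hi = measure.timeframe.longitudinal_window
    start = history.index.index_date + timedelta(days=lo)
    end = history.index.index_date + timedelta(days=hi)
    keys: set[str] = set()
    for f in history.fills:
        prod = dictionary[f.product_id]
        if start <= f.fill_date <= end and in_scope(prod, measure.scope):
            keys |= drug_keys(prod, measure.uniqueness)
    return CountResult(
        patient_id=history.patient_id,
        measure_id=measure.measure_id,
        count=len(keys),
    )


def count_cohort(
    histories: Iterable[PatientHistory],
    measure: MeasureSpec,
    dictionary: Mapping[str, DrugProduct],
    stay_convention: str = "admit_inclusive",
) -> list[CountResult]:
    return [
        count_drugs(h, measure, dictionary, stay_convention) for h in histories
    ]
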