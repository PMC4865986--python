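"""Domain records for pharmacy-claims drug counting.

The unit of analysis is a patient's fill history from a pharmacy refill
database: dispensing events (fills) that reference products in a drug
dictionary, plus hospital stays and a single index date per patient. A
"drug count" is always computed relative to the index date.

Records are frozen dataclasses validated at construction; controlled
vocabularies are closed sets with an ``other`` escape token, since any
fixed list of routes or forms is necessarily incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

ROUTES = frozenset({
    "oral", "inhalation", "topical", "transdermal", "ophthalmic",
    "subcutaneous", "sublingual", "rectal", "other",
})
DOSAGE_FORMS = frozenset({
    "tablet", "capsule", "cream", "solution", "suspension", "patch",
    "aerosol", "other",
})
RX_STATUSES = frozenset({"prescription", "otc"})
DRUG_TYPES = frozenset({"standard", "vitamin", "herbal", "supplement", "other_cam"})
COMMON_USES = frozenset({"regular", "as_needed"})


class ValidationError(ValueError):
    """A record field violated its contract (bad token, bad date order...)."""


def _check_token(value: str, vocab: frozenset, field_name: str) -> str:
    if value not in vocab:
        raise ValidationError(
            f"{field_name}={value!r} not in vocabulary {sorted(vocab)}"
        )
    return value


@dataclass(frozen=True)
class DrugProduct:
    """One dispensable product: the unit of scope filtering and key generation.

    A combination product carries two or more active ingredients and is
    counted once under product-based uniqueness but contributes one key
    per ingredient under ingredient-based uniqueness.
    """

    product_id: str
    ingredients: tuple[str, ...]
    route: str
    dosage_form: str
    strength: str = ""
    rx_status: str = "prescription"
    drug_type: str = "standard"
    common_use: str = "regular"
    is_supply: bool = False
    is_metered_dose_inhaler: bool = False

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValidationError(f"product {self.product_id}: ingredients empty")
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        _check_token(self.route, ROUTES, "route")
        _check_token(self.dosage_form, DOSAGE_FORMS, "dosage_form")
        _check_token(self.rx_status, RX_STATUSES, "rx_status")
        _check_token(self.drug_type, DRUG_TYPES, "drug_type")
        _check_token(self.common_use, COMMON_USES, "common_use")

    @property
    def is_combination(self) -> bool:
        return len(self.ingredients) >= 2


@dataclass(frozen=True)
class FillRecord:
    """One dispensing event; the unit of timeframe eligibility."""

    patient_id: str
    product_id: str
    fill_date: date
    days_supply: int
    quantity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.days_supply <= 0:
            raise ValidationError(
                f"fill {self.patient_id}/{self.product_id}@{self.fill_date}: "
                f"days_supply must be positive, got {self.days_supply}"
            )
        if self.quantity is not None and self.quantity < 0:
            raise ValidationError("quantity must be nonnegative")


@dataclass(frozen=True)
class Hospitalization:
    patient_id: str
    admit_date: date
    discharge_date: date

    def __post_init__(self) -> None:
        if self.admit_date > self.discharge_date:
            raise ValidationError(
                f"hospitalization for {self.patient_id}: admit "
                f"{self.admit_date} after discharge {self.discharge_date}"
            )


@dataclass(frozen=True)
class IndexEvent:
    """The anchor date for a cross-sectional count (e.g. hospital admission)."""

    patient_id: str
    index_date: date


@dataclass(frozen=True)
class PatientHistory:
    """All of one patient's claims, fills sorted ascending by date."""

    patient_id: str
    fills: tuple[FillRecord, ...]
    hospitalizations: tuple[Hospitalization, ...] = ()
    index: IndexEvent = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fills", tuple(sorted(
            self.fills, key=lambda f: (f.fill_date, f.product_id))))
        object.__setattr__(self, "hospitalizations", tuple(
            sorted(self.hospitalizations,
                   key=lambda h: (h.admit_date, h.discharge_date))))
        if self.index is None:
            raise ValidationError(f"patient {self.patient_id}: missing index event")
        for rec in (*self.fills, *self.hospitalizations, self.index):
            if rec.patient_id != self.patient_id:
                raise ValidationError(
                    f"record patient_id {rec.patient_id!r} != history "
                    f"patient_id {self.patient_id!r}"
                )
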