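"""Readers, writers and preprocessing filters for the four claims tables.

Input tables are plain CSV with fixed headers (see column constants).
Preprocessing mirrors standard claims hygiene for refill data: fills for
medical supplies are dropped, fills whose days-supply value is 0 or 999
(common sentinel codes for unknown) are dropped, and fills that do not
resolve in the product dictionary are dropped. Rejections are counted by
reason and reported, never fatal: in large claims extracts these losses
are a tiny fraction of events and should not abort a run.

Dates are ISO 8601 (YYYY-MM-DD). Ingredient lists inside a CSV cell are
pipe-delimited (``ezetimibe|simvastatin``).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import (
    DrugProduct,
    FillRecord,
    Hospitalization,
    IndexEvent,
    PatientHistory,
    ValidationError,
)

DICTIONARY_COLUMNS = [
    "product_id", "ingredients", "route", "dosage_form", "strength",
    "rx_status", "drug_type", "common_use", "is_supply", "is_mdi",
]
FILL_COLUMNS = ["patient_id", "product_id", "fill_date", "days_supply", "quantity"]
HOSPITALIZATION_COLUMNS = ["patient_id", "admit_date", "discharge_date"]
INDEX_COLUMNS = ["patient_id", "index_date"]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


class SchemaError(ValueError):
    """A table is missing required columns."""


def _open_reader(path, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    handle = open(path, newline="")
    reader = csv.DictReader(handle)
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        handle.close()
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return reader, handle


def read_dictionary(path) -> dict[str, DrugProduct]:
    """Load the drug product dictionary, validating every vocabulary token.

    Raises :class:`SchemaError` for a bad header and
    :class:`~drugtally.model.ValidationError` naming the offending row for
    a token outside the controlled vocabularies.
    """
    reader, handle = _open_reader(path, DICTIONARY_COLUMNS)
    products: dict[str, DrugProduct] = {}
    with handle:
        for i, row in enumerate(reader, start=2):
            try:
                product = DrugProduct(
                    product_id=row["product_id"],
                    ingredients=tuple(
                        p.strip() for p in row["ingredients"].split("|") if p.strip()
                    ),
                    route=row["route"],
                    dosage_form=row["dosage_form"],
                    strength=row["strength"],
                    rx_status=row["rx_status"],
                    drug_type=row["drug_type"],
                    common_use=row["common_use"],
                    is_supply=_BOOL[row["is_supply"].strip().lower()],
                    is_metered_dose_inhaler=_BOOL[row["is_mdi"].strip().lower()],
                )
            except (ValidationError, KeyError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
            if product.product_id in products:
                raise ValidationError(
                    f"{path} row {i}: duplicate product_id {product.product_id!r}"
                )
            products[product.product_id] = product
    return products


def read_fills(
    path, dictionary: Mapping[str, DrugProduct]
) -> tuple[list[FillRecord], dict[str, int]]:
    """Load fill records, dropping and tallying invalid rows.

    Returns ``(retained_fills, report)`` where ``report`` counts rejected
    rows by reason: ``unmatched_product``, ``days_supply_0``,
    ``days_supply_999``, ``is_supply``, ``bad_row``. Counts always sum to
    input rows minus retained rows.
    """
    reader, handle = _open_reader(path, FILL_COLUMNS)
    fills: list[FillRecord] = []
    report: Counter[str] = Counter()
    with handle:
        for row in reader:
            try:
                fill_date = date.fromisoformat(row["fill_date"].strip())
                days_supply = int(row["days_supply"])
                qty_raw = (row.get("quantity") or "").strip()
                quantity = float(qty_raw) if qty_raw else None
            except (ValueError, KeyError):
                report["bad_row"] += 1
                continue
            if days_supply == 0:
                report["days_supply_0"] += 1
                continue
            if days_supply == 999:
                report["days_supply_999"] += 1
                continue
            product = dictionary.get(row["product_id"])
            if product is None:
                report["unmatched_product"] += 1
                continue
            if product.is_supply:
                report["is_supply"] += 1
                continue
            try:
                fills.append(FillRecord(
                    patient_id=row["patient_id"],
                    product_id=row["product_id"],
                    fill_date=fill_date,
                    days_supply=days_supply,
                    quantity=quantity,
                ))
            except ValidationError:
                report["bad_row"] += 1
    return fills, dict(report)


def read_hospitalizations(path) -> list[Hospitalization]:
    reader, handle = _open_reader(path, HOSPITALIZATION_COLUMNS)
    with handle:
        return [
            Hospitalization(
                patient_id=row["patient_id"],
                admit_date=date.fromisoformat(row["admit_date"].strip()),
                discharge_date=date.fromisoformat(row["discharge_date"].strip()),
            )
            for row in reader
        ]


def read_index_events(path) -> list[IndexEvent]:
    reader, handle = _open_reader(path, INDEX_COLUMNS)
    with handle:
        return [
            IndexEvent(
                patient_id=row["patient_id"],
                index_date=date.fromisoformat(row["index_date"].strip()),
            )
            for row in reader
        ]


def assemble_histories(
    fills: Iterable[FillRecord],
    hospitalizations: Iterable[Hospitalization],
    index_events: Iterable[IndexEvent],
) -> list[PatientHistory]:
    """Group records into one :class:`PatientHistory` per indexed patient.

    Patients with an index event but no fills are retained (their count
    is 0). Fills or stays for patients without an index event are
    silently dropped — the index event defines the analytic cohort.
    Duplicate index events for one patient are an error.
    """
    index_by_patient: dict[str, IndexEvent] = {}
    for ev in index_events:
        if ev.patient_id in index_by_patient:
            raise ValidationError(
                f"duplicate index event for patient {ev.patient_id!r}"
            )
        index_by_patient[ev.patient_id] = ev
    fills_by_patient: dict[str, list[FillRecord]] = {p: [] for p in index_by_patient}
    for f in fills:
        if f.patient_id in fills_by_patient:
            fills_by_patient[f.patient_id].append(f)
    stays_by_patient: dict[str, list[Hospitalization]] = {
        p: [] for p in index_by_patient
    }
    for h in hospitalizations:
        if h.patient_id in stays_by_patient:
            stays_by_patient[h.patient_id].append(h)
    return [
        PatientHistory(
            patient_id=pid,
            fills=tuple(fills_by_patient[pid]),
            hospitalizations=tuple(stays_by_patient[pid]),
            index=index_by_patient[pid],
        )
        for pid in sorted(index_by_patient)
    ]


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)

def write_dictionary(products: Mapping[str, DrugProduct], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(DICTIONARY_COLUMNS)
        for p in products.values():
            writer.writerow([
                p.product_id, "|".join(p.ingredients), p.route, p.dosage_form,
                p.strength, p.rx_status, p.drug_type, p.common_use,
                str(p.is_supply).lower(), str(p.is_metered_dose_inhaler).lower(),
            ])


def write_fills(fills: Iterable[FillRecord], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(FILL_COLUMNS)
        for f in fills:
            qty = "" if f.quantity is None else format(f.quantity, "g")
            writer.writerow([
                f.patient_id, f.product_id, f.fill_date.isoformat(),
                f.days_supply, qty,
            ])


def write_hospitalizations(stays: Iterable[Hospitalization], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(HOSPITALIZATION_COLUMNS)
        for h in stays:
            writer.writerow([
                h.patient_id, h.admit_date.isoformat(), h.discharge_date.isoformat(),
            ])


def write_index_events(events: Iterable[IndexEvent], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(INDEX_COLUMNS)
        for ev in events:
            writer.writerow([ev.patient_id, ev.index_date.isoformat()])


def write_rejection_report(report: Mapping[str, int], path) -> None:
    Path(path).write_text(json.dumps(dict(report), indent=2, sort_keys=True) + "\n")
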