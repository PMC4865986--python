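"""Seedable synthetic pharmacy-claims generator, plus the worked-example fixture.

The generator emulates the structure of refill-database extracts that
drug-count measures are sensitive to: chronic regimens refilled with
imperfect adherence (a random delay beyond supply exhaustion), drugs
discontinued before the index date, sparse as-needed (PRN) drugs,
combination products, OTC products, varied routes and dosage forms
(including metered-dose inhalers and topicals), hospital stays, and
post-index refills. It does not emulate pricing, pharmacy switching,
dose changes, or real-world drug names — counts computed on it exercise
the counting rules, not any particular therapeutic area.

``table3_fixture`` builds the hypothetical patient used throughout the
docs and tests: four chronic drugs (an estradiol patch, metoprolol, an
ezetimibe/simvastatin combination tablet, and as-needed sublingual
nitroglycerin filled once), an index admission on 2008-07-01 with
discharge on 2008-07-03, and a new post-discharge drug (lisinopril).
"""

from __future__ import annotations

import json
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as dio
from .model import (
    DrugProduct,
    FillRecord,
    Hospitalization,
    IndexEvent,
    PatientHistory,
)


class SimulationConfig(BaseModel):
    """Knobs for the cohort generator; defaults sketch an elderly chronic-disease
    cohort observed for a year before an index hospitalization."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 100
    seed: int = 0
    n_products: int = 60
    chronic_drugs_per_patient: float = 4.0  # Poisson mean
    days_supply_choices: dict[int, float] = {30: 0.6, 90: 0.25, 28: 0.15}
    refill_delay_mean: float = 5.0  # mean extra days past supply exhaustion
    early_refill_days: int = 5  # refills may come up to this many days early
    prn_probability: float = 0.3
    prn_product_fraction: float = 0.15
    discontinue_probability: float = 0.2
    combo_fraction: float = 0.15
    otc_fraction: float = 0.10
    hospitalization_rate: float = 0.5  # stays per patient-year
    observation_days_before_index: int = 365
    post_index_days: int = 60
    index_date: date = date(2008, 7, 1)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("prn_probability", "prn_product_fraction",
                     "discontinue_probability", "combo_fraction", "otc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients <= 0 or self.n_products <= 0:
            raise ValueError("n_patients and n_products must be positive")
        if self.observation_days_before_index <= 0:
            raise ValueError("observation window must be positive")
        if self.refill_delay_mean < 0:
            raise ValueError("refill_delay_mean must be nonnegative")
        if self.early_refill_days < 0:
            raise ValueError("early_refill_days must be nonnegative")
        if not self.days_supply_choices or any(
            w < 0 for w in self.days_supply_choices.values()
        ) or sum(self.days_supply_choices.values()) <= 0:
            raise ValueError("days_supply_choices needs positive total weight")
        if any(ds <= 0 or ds == 999 for ds in self.days_supply_choices):
            raise ValueError("days supply choices must be valid positive values")
        return self


# (route, form, is_mdi) drawn with these weights; oral tablets dominate as
# they do in real Part D fills
_ROUTE_FORMS = [
    (("oral", "tablet", False), 0.55),
    (("oral", "capsule", False), 0.15),
    (("inhalation", "aerosol", True), 0.08),
    (("inhalation", "solution", False), 0.03),
    (("topical", "cream", False), 0.07),
    (("transdermal", "patch", False), 0.04),
    (("sublingual", "tablet", False), 0.04),
    (("ophthalmic", "solution", False), 0.02),
    (("subcutaneous", "solution", False), 0.02),
]
assert abs(sum(w for _, w in _ROUTE_FORMS) - 1.0) < 1e-9


def _make_dictionary(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> dict[str, DrugProduct]:
    ingredient_pool = [f"ing{i:03d}" for i in range(cfg.n_products * 2)]
    rf_idx = rng.choice(
        len(_ROUTE_FORMS), size=cfg.n_products,
        p=[w for _, w in _ROUTE_FORMS],
    )
    products: dict[str, DrugProduct] = {}
    pool_cursor = 0
    for i in range(cfg.n_products):
        route, form, is_mdi = _ROUTE_FORMS[rf_idx[i]][0]
        n_ing = 2 if rng.random() < cfg.combo_fraction else 1
        ingredients = tuple(ingredient_pool[pool_cursor:pool_cursor + n_ing])
        pool_cursor += n_ing
        pid = f"P{i:04d}"
        products[pid] = DrugProduct(
            product_id=pid,
            ingredients=ingredients,
            route=route,
            dosage_form=form,
            strength=f"{int(rng.integers(1, 100))} mg",
            rx_status="otc" if rng.random() < cfg.otc_fraction else "prescription",
            drug_type="standard",
            common_use="as_needed" if rng.random() < cfg.prn_product_fraction
            else "regular",
            is_supply=False,
            is_metered_dose_inhaler=is_mdi,
        )
    return products


def _refill_chain(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    start: date,
    stop: date,
    days_supply: int,
) -> list[tuple[date, int]]:
    """Fill dates from `start` until `stop`. Each refill is delayed past
    supply exhaustion by a discretized-exponential adherence lapse, or
    brought forward up to ``early_refill_days`` (early refills are what
    builds up a cabinet/stockpile of unused supply)."""
    fills = []
    d = start
    while d < stop:
        fills.append((d, days_supply))
        delay = int(round(rng.exponential(cfg.refill_delay_mean))) \
            if cfg.refill_delay_mean > 0 else 0
        early = int(rng.integers(0, cfg.early_refill_days + 1)) \
            if cfg.early_refill_days > 0 else 0
        d = d + timedelta(days=max(1, days_supply + delay - early))
    return fills


def generate(config: SimulationConfig) -> tuple[
    dict[str, DrugProduct], list[FillRecord],
    list[Hospitalization], list[IndexEvent],
]:
    """Draw a full synthetic claims extract; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    dictionary = _make_dictionary(config, rng)
    regular_ids = [p for p, d in dictionary.items() if d.common_use == "regular"]
    prn_ids = [p for p, d in dictionary.items() if d.common_use == "as_needed"]
    ds_values = sorted(config.days_supply_choices)
    ds_weights = np.array([config.days_supply_choices[v] for v in ds_values], float)
    ds_weights /= ds_weights.sum()

    index_date = config.index_date
    window_start = index_date - timedelta(days=config.observation_days_before_index)
    horizon = index_date + timedelta(days=config.post_index_days)

    fills: list[FillRecord] = []
    stays: list[Hospitalization] = []
    index_events: list[IndexEvent] = []
    for i in range(config.n_patients):
        pid = f"pt{i:05d}"
        index_events.append(IndexEvent(pid, index_date))
        n_chronic = min(int(rng.poisson(config.chronic_drugs_per_patient)),
                        len(regular_ids))
        chosen = rng.choice(len(regular_ids), size=n_chronic, replace=False)
        for j in chosen:
            prod_id = regular_ids[int(j)]
            ds = int(rng.choice(ds_values, p=ds_weights))
            start = window_start + timedelta(days=int(rng.integers(0, 45)))
            stop = horizon
            if rng.random() < config.discontinue_probability:
                # drug dropped somewhere in the observation window
                stop = window_start + timedelta(
                    days=int(rng.integers(30, config.observation_days_before_index))
                )
            for d, supply in _refill_chain(rng, config, start, stop, ds):
                fills.append(FillRecord(pid, prod_id, d, supply, float(supply)))
        if prn_ids and rng.random() < config.prn_probability:
            prod_id = prn_ids[int(rng.integers(0, len(prn_ids)))]
            n_prn = int(rng.integers(1, 4))
            offsets = rng.integers(0, config.observation_days_before_index, n_prn)
            for off in sorted(set(int(o) for o in offsets)):
                fills.append(FillRecord(
                    pid, prod_id, window_start + timedelta(days=off), 10, 25.0,
                ))
        years = config.observation_days_before_index / 365.25
        for _ in range(rng.poisson(config.hospitalization_rate * years)):
            admit = window_start + timedelta(
                days=int(rng.integers(0, config.observation_days_before_index))
            )
            stays.append(Hospitalization(
                pid, admit, admit + timedelta(days=int(rng.integers(2, 8)))
            ))

    fills.sort(key=lambda f: (f.patient_id, f.fill_date, f.product_id))
    stays.sort(key=lambda h: (h.patient_id, h.admit_date))
    return dictionary, fills, stays, index_events


def write_cohort(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate and write the four CSVs plus a provenance JSON; file contents
    are byte-identical across runs with the same config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary, fills, stays, index_events = generate(config)
    paths = {
        "dictionary": out / "dictionary.csv",
        "fills": out / "fills.csv",
        "hospitalizations": out / "hospitalizations.csv",
        "index": out / "index.csv",
        "provenance": out / "provenance.json",
    }
    dio.write_dictionary(dictionary, paths["dictionary"])
    dio.write_fills(fills, paths["fills"])
    dio.write_hospitalizations(stays, paths["hospitalizations"])
    dio.write_index_events(index_events, paths["index"])
    paths["provenance"].write_text(
        json.dumps({"config": config.model_dump(mode="json")},
                   indent=2, sort_keys=True) + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# The packaged hypothetical-patient fixture.

def table3_dictionary() -> dict[str, DrugProduct]:
    products = [
        DrugProduct("EST", ("estradiol",), "transdermal", "patch",
                    "0.025 mg/24 h"),
        DrugProduct("MET", ("metoprolol succinate",), "oral", "tablet",
                    "50 mg extended-release"),
        DrugProduct("EZS", ("ezetimibe", "simvastatin"), "oral", "tablet",
                    "10/10 mg"),
        DrugProduct("NTG", ("nitroglycerin",), "sublingual", "tablet",
                    "0.4 mg", common_use="as_needed"),
        DrugProduct("LIS", ("lisinopril",), "oral", "tablet", "10 mg"),
    ]
    return {p.product_id: p for p in products}


def table3_fixture() -> tuple[PatientHistory, dict[str, DrugProduct]]:
    """The hypothetical patient: 14 fills, index 2008-07-01, one hospital stay.

    Three chronic drugs refilled monthly (estradiol patch with 28-day
    supplies; metoprolol and ezetimibe/simvastatin with 30-day
    supplies), one as-needed nitroglycerin fill 73 days before index
    with a 9-day supply, and lisinopril started at discharge.
    """
    pid = "hypo"
    rows = [
        ("2008-04-19", "EST", 4, 28),
        ("2008-04-19", "MET", 30, 30),
        ("2008-04-19", "EZS", 30, 30),
        ("2008-04-19", "NTG", 25, 9),
        ("2008-05-20", "EST", 4, 28),
        ("2008-05-20", "MET", 30, 30),
        ("2008-05-20", "EZS", 30, 30),
        ("2008-06-18", "EST", 4, 28),
        ("2008-06-18", "MET", 30, 30),
        ("2008-06-18", "EZS", 30, 30),
        ("2008-07-03", "LIS", 30, 30),
        ("2008-07-19", "EST", 4, 28),
        ("2008-07-19", "MET", 30, 30),
        ("2008-07-19", "EZS", 30, 30),
    ]
    fills = tuple(
        FillRecord(pid, prod, date.fromisoformat(d), ds, float(qty))
        for d, prod, qty, ds in rows
    )
    history = PatientHistory(
        patient_id=pid,
        fills=fills,
        hospitalizations=(Hospitalization(pid, date(2008, 7, 1), date(2008, 7, 3)),),
        index=IndexEvent(pid, date(2008, 7, 1)),
    )
    return history, table3_dictionary()


def write_table3(out_dir) -> dict[str, Path]:
    """Write the hypothetical-patient fixture as the four standard CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history, dictionary = table3_fixture()
    paths = {
        "dictionary": out / "dictionary.csv",
        "fills": out / "fills.csv",
        "hospitalizations": out / "hospitalizations.csv",
        "index": out / "index.csv",
    }
    dio.write_dictionary(dictionary, paths["dictionary"])
    dio.write_fills(history.fills, paths["fills"])
    dio.write_hospitalizations(history.hospitalizations, paths["hospitalizations"])
    dio.write_index_events([history.index], paths["index"])
    return paths
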