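"""Independent brute-force oracles used by unit and acceptance tests."""

from __future__ import annotations

from datetime import date, timedelta


def cabinet_oracle(fills, anchor_date: date, lookback_days: int) -> float:
    """Day-by-day supply replay: refills add to the balance on their fill
    date, one day of supply is consumed per calendar day, the balance
    floors at zero. Returns the balance on the anchor date."""
    window_start = anchor_date - timedelta(days=lookback_days)
    in_window = sorted(
        (d, ds) for d, ds in fills if window_start <= d < anchor_date
    )
    if not in_window:
        return 0.0
    balance = 0.0
    day = in_window[0][0]
    while day < anchor_date:
        balance += sum(ds for d, ds in in_window if d == day)
        balance = max(0.0, balance - 1.0)
        day += timedelta(days=1)
    return balance


def inpatient_days_oracle(stays, anchor_date: date, index_date: date) -> int:
    """Enumerate calendar days strictly between anchor and index that fall
    in any [admit, discharge) stay interval."""
    count = 0
    day = anchor_date + timedelta(days=1)
    while day < index_date:
        if any(h.admit_date <= day < h.discharge_date for h in stays):
            count += 1
        day += timedelta(days=1)
    return count
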