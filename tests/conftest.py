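import numpy as np
import pandas as pd
import pytest

from policymatch.quarters import QuarterWindow

CLAIM_DEFAULTS = dict(
    patient_id="P1",
    state="S01",
    days_supply=30,
    quantity=90.0,
    strength_per_unit=10.0,
    mme_factor=1.5,
    drug_class="opioid",
    prescriber_id="D1",
    pharmacy_id="F1",
)


def mk_claims(*rows):
    """Claims frame from partial dicts; fill_date accepts strings."""
    recs = []
    for row in rows:
        rec = {**CLAIM_DEFAULTS, **row}
        rec["fill_date"] = pd.Timestamp(rec["fill_date"])
        recs.append(rec)
    cols = ["fill_date", *CLAIM_DEFAULTS]
    return pd.DataFrame(recs, columns=cols) if recs else pd.DataFrame(columns=cols)


def mk_diagnoses(*rows):
    recs = []
    for row in rows:
        rec = {"patient_id": "P1", "date": "2007-06-01", "code": "F11.20",
               "icd_version": 10, **row}
        rec["date"] = pd.Timestamp(rec["date"])
        recs.append(rec)
    cols = ["patient_id", "date", "code", "icd_version"]
    return pd.DataFrame(recs, columns=cols) if recs else pd.DataFrame(columns=cols)


def random_claims(rng, n, window, patient_id="P1", state="S01"):
    """A messy random opioid claim stream inside the window."""
    days = rng.integers(0, window.n_days - 40, n)
    return mk_claims(*[
        dict(
            patient_id=patient_id,
            state=state,
            fill_date=window.start_date + pd.Timedelta(days=int(d)),
            days_supply=int(rng.integers(1, 35)),
            quantity=float(rng.integers(10, 180)),
            strength_per_unit=float(rng.choice([5, 10, 20, 30])),
            mme_factor=float(rng.choice([1.0, 1.5, 4.0])),
            prescriber_id=f"D{rng.integers(1, 7)}",
            pharmacy_id=f"F{rng.integers(1, 7)}",
        )
        for d in days
    ])


@pytest.fixture(scope="session")
def window12():
    return QuarterWindow(2007, 12)


@pytest.fixture(scope="session")
def window8():
    return QuarterWindow(2007, 8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
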