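"""Small builders for hand-written service/calving fixtures."""

import pandas as pd


def make_services(rows):
    """rows: list of dicts; missing fields get defaults."""
    defaults = {
        "record_id": None,
        "herd_id": "H01",
        "animal_id": "A1",
        "birth_date": "2011-02-01",
        "service_number": 1,
        "sire_id": "S001",
        "breed": "FR",
        "civ_pta": 0.0,
        "outcome": "unknown",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if rec["record_id"] is None:
            rec["record_id"] = f"R{i:03d}"
        out.append(rec)
    df = pd.DataFrame(out)
    for col in ("birth_date", "service_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_calvings(rows):
    df = pd.DataFrame(
        [{"animal_id": "A1", "is_abortion": False, **r} for r in rows],
        columns=["animal_id", "calving_date", "is_abortion"],
    )
    if len(df):
        df["calving_date"] = pd.to_datetime(df["calving_date"])
    return df
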