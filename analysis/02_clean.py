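#!/usr/bin/env python
"""Confirm service outcomes from calvings and remove invalid events.

Reads results/data/, writes cleaned.csv plus the cleaning audit, and
checks the audit against the planted-defect ledger (they must agree
exactly when defect classes are disjoint).
"""

import argparse
import json
from pathlib import Path

from heifersim.cleaning import clean_pipeline
from heifersim.records import parse_service_table, write_services


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    parsed = parse_service_table(args.data / "services.csv", args.data / "calvings.csv")
    cleaned, audit = clean_pipeline(parsed.services, parsed.calvings)
    write_services(cleaned, args.data / "cleaned.csv")
    (args.data / "cleaning_audit.json").write_text(json.dumps(audit.as_dict(), indent=2))

    print(f"cleaned {audit.n_input} -> {audit.n_output} records")
    for field, value in audit.as_dict().items():
        print(f"  {field}: {value}")

    ledger = json.loads((args.data / "defect_ledger.json").read_text())
    pairs = [
        ("n_removed_same_oestrus", "duplicates"),
        ("n_reassigned_short_gestation", "reassignment_extras"),
        ("n_removed_long_gestation", "embryonic_long_extras"),
        ("n_corrected_negative_finals", "negative_final_flips"),
        ("n_removed_problem_seasons", "problem_seasons"),
        ("n_removed_carryover", "carryovers"),
    ]
    ok = all(audit.as_dict()[a] == ledger[b] for a, b in pairs)
    print("audit matches planted ledger exactly" if ok else "AUDIT/LEDGER MISMATCH")


if __name__ == "__main__":
    main()
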