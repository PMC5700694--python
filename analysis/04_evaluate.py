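#!/usr/bin/env python
"""Two-pronged held-out evaluation of the fitted conception models.

Discrimination (confusion metrics at 50% and at the ROC-optimal
threshold, MCC, AUC) and calibration (Hosmer-Lemeshow, 15-bin
calibration table with exact intervals, unreliability test, binned
residuals / MACE) on the 30% test split.  Writes results/evaluation.json
and plot-ready bin/ROC tables.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from heifersim.evaluation import calibration_bins
from heifersim.model import model_frame, predict_probabilities
from heifersim.pipeline import evaluate_fit, fit_family
from heifersim.records import derive_covariates, read_services


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    train = model_frame(derive_covariates(read_services(args.data / "train.csv")))
    test = model_frame(derive_covariates(read_services(args.data / "test.csv")))

    report = {}
    for family in ("LR", "MLR", "GAM"):
        fit = fit_family(family, train)
        report[family] = evaluate_fit(fit, test)
        p = predict_probabilities(fit, test)
        yv = (test["outcome"] == "positive").to_numpy(float)
        calibration_bins(p, yv).to_csv(args.out / f"calibration_bins_{family.lower()}.csv", index=False)
        pts = np.asarray(report[family]["discrimination"]["0.5"]["roc_points"])
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
            args.out / f"roc_{family.lower()}.csv", index=False
        )
        d = report[family]["discrimination"]["0.5"]
        c = report[family]["calibration"]
        print(f"{family}: sens {d['sensitivity']:.1f}%  spec {d['specificity']:.1f}%  "
              f"acc {d['accuracy']:.1f}%  MCC {d['mcc']:.2f}  AUC {d['auc']:.2f}  "
              f"HL p {c['hl_p']:.2f}  MACE {c['mace']:.2f}%")

    for family in report:
        report[family]["calibration"].pop("bins", None)
        for rep in report[family]["discrimination"].values():
            rep.pop("roc_points", None)
    (args.out / "evaluation.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
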