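#!/usr/bin/env python
"""Reproduction experiments built on the packaged published parameters.

Recovers (i) the per-day calving-interval-PTA odds ratio, (ii) the
herd-year random-intercept SD, and (iii) measures the held-out MACE of a
correctly specified mixed-model fit.  This is a lighter-weight driver
around the same library functions `scripts/acceptance.py` runs in full.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from heifersim.reproduce import civ_or_replicate, heldout_mace_replicate, re_sd_replicate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    or_hat = civ_or_replicate(args.seed)
    print(f"recovered CIV odds ratio per day: {or_hat:.3f} (generative value 0.93)")

    sds = [re_sd_replicate(args.seed + k) for k in range(3)]
    print(f"recovered herd-year random-intercept SD: median {np.median(sds):.3f} "
          f"(generative value 0.78; replicates {[round(s, 3) for s in sds]})")

    maces = [heldout_mace_replicate(args.seed + k)[0] for k in range(3)]
    print(f"held-out MACE of refitted mixed model: median {np.median(maces):.2f}% "
          f"(floor(sqrt(n)) groups at n~600; see docs/methods.md on why this "
          f"sits near 6-7% even for a perfectly calibrated model)")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "reproduction.json").write_text(json.dumps({
        "civ_odds_ratio": or_hat,
        "random_intercept_sd_median": float(np.median(sds)),
        "heldout_mace_median_pct": float(np.median(maces)),
    }, indent=2))


if __name__ == "__main__":
    main()
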