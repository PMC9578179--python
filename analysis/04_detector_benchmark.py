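#!/usr/bin/env python
"""Benchmark the elastic-point detector against generator ground truth.

Two regimes are profiled: (a) maneuvers lying exactly on two line segments,
where the hinge fit is provably exact, and (b) maneuvers from the smooth
two-regime law with exponential plastic stiffening, where the fit's knot is
systematically attracted toward high volumes because the convex tail
dominates the residual sum of squares.  The output table quantifies that
bias as a function of the stiffening exponent — the reason DP estimates on
smooth curves should be read as upper bounds.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dptitrate.mechanics import LungParamRanges, draw_lung_params, simulate_maneuver
from dptitrate.titration import fit_two_segment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-rep", type=int, default=500)
    ap.add_argument("--out", type=Path, default=Path("results/detector_benchmark.csv"))
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for gamma_band, (glo, ghi) in {"low (0.8-1.5)": (0.8, 1.5),
                                   "default (1.5-2.8)": (1.5, 2.8),
                                   "high (2.8-4.0)": (2.8, 4.0)}.items():
        ranges = LungParamRanges(gamma=(glo, ghi))
        errs = []
        for _ in range(args.n_rep):
            params = draw_lung_params(ranges, rng)
            m = simulate_maneuver(params, 14, 1, seed=rng.integers(2**31))
            ep = fit_two_segment(m)
            errs.append(ep.dp_individual - params.dp_true)
        errs = np.asarray(errs)
        rows.append({
            "stiffening_band": gamma_band,
            "n": args.n_rep,
            "median_bias_cmh2o": np.median(errs),
            "iqr_lo": np.percentile(errs, 25),
            "iqr_hi": np.percentile(errs, 75),
            "within_1cmh2o_pct": 100 * np.mean(np.abs(errs) <= 1.0),
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.4g")

    print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print("\nOn smooth exponential-plastic curves the SSE-optimal knot sits past the")
    print("true elastic limit, so the estimated DP overshoots e1*v_el; on curves with")
    print("a genuine slope discontinuity the same fit is exact (see the test suite).")


if __name__ == "__main__":
    main()
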