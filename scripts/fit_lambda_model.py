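#!/usr/bin/env python
"""Calibration harness for the regularization-parameter model.

For a given scan protocol, sweeps noise levels, measures delta_G from the
infinite-regularization pass, grid-searches the lambda that maximizes SNR
of the second pass, and fits a piecewise-quadratic delta_G -> lambda map
that can replace the shipped coefficients (see LambdaModel).

This is a research tool: expect long runtimes at full problem sizes.

Usage:
    python scripts/fit_lambda_model.py --image-n 128 --seed 0 --out model.json
"""

from __future__ import annotations

import argparse
import json
import warnings

import numpy as np

import dictsir as ds
from dictsir.lambda_model import delta_at_infinity
from dictsir.reconstruct import ReconConfig, run_reconstruction, sart_reconstruct


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--image-n", type=int, default=128)
    ap.add_argument("--views", type=int, default=120)
    ap.add_argument("--step-deg", type=float, default=3.0)
    ap.add_argument("--detectors", type=int, default=512)
    ap.add_argument("--noise-pcts", type=str, default="0,0.05,0.1,0.15,0.2")
    ap.add_argument("--lambdas", type=str,
                    default="0.1,0.3,1,3,10,30,100,300")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--threshold", type=float, default=1.96,
                    help="delta_G branch switch point of the fitted model")
    ap.add_argument("--out", type=str, required=True)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    mu = 0.07 * ds.make_shepp_logan(args.image_n)
    geom = ds.build_geometry(args.views, args.step_deg, args.detectors,
                             args.image_n, 2.0)
    A = ds.build_system_matrix(geom)
    config = ReconConfig()
    lambdas = [float(x) for x in args.lambdas.split(",")]

    points = []
    for pct in (float(x) for x in args.noise_pcts.split(",")):
        sino = ds.simulate_scan(mu, geom, pct / 100.0, seed=args.seed, A=A)
        warm = sart_reconstruct(sino, A, config).image
        d_inf, res1 = delta_at_infinity(sino, A, "adaptive", config,
                                        init_image=warm)
        best = None
        for lam in lambdas:
            from dataclasses import replace
            cfg = replace(config, lam=lam, dictionary=res1.dictionary)
            res = run_reconstruction(sino, A, "adaptive", cfg,
                                     init_image=warm)
            score = ds.snr(res.image, mu)
            if best is None or score > best[1]:
                best = (lam, score)
        points.append({"noise_pct": pct, "delta_g": 1e6 * d_inf,
                       "lambda_best": best[0], "snr": best[1]})
        print(points[-1], flush=True)

    dg = np.array([p["delta_g"] for p in points])
    lb = np.array([p["lambda_best"] for p in points])
    low = dg <= args.threshold
    model = {"scale": 1e6, "threshold": args.threshold, "points": points}
    for name, mask in (("low", low), ("high", ~low)):
        if mask.sum() >= 3:
            model[name] = list(np.polyfit(dg[mask], lb[mask], 2))
        else:
            model[name] = None  # not enough points for this branch
    with open(args.out, "w") as fh:
        json.dump(model, fh, indent=2)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
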