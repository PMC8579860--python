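#!/usr/bin/env python
"""Sweep the observer-noise augmentation factor for SVR and the network.

Each training fold is enlarged with Gaussian replicas drawn from the
inter-observer law before fitting; held-out folds stay untouched.  The
sweep tabulates the LOOCV mean and SD of the 3-D error against the
multiplicity factor; the network is swept over a reduced factor list to
keep its training cost proportionate.
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np

from vimtarget.augmentation import augmentation_sweep
from vimtarget.io import read_variability
from vimtarget.metamodels import DNNConfig, DNNRegressor, SVRRegressor, grid_search

_spec = importlib.util.spec_from_file_location(
    "model_comparison", Path(__file__).with_name("03_model_comparison.py"))
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_dataset = _mod.load_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--factors", default="0,1,2,5,10")
    parser.add_argument("--dnn-factors", default="0,10")
    args = parser.parse_args()

    ds = load_dataset(args.results_dir / "cohort")
    var = read_variability(args.results_dir / "variability_inter.json")
    svr = grid_search(ds.X, ds.Y, ds.patient_ids, kind="svr").best_params

    factors = [int(f) for f in args.factors.split(",")]
    table = augmentation_sweep(
        ds, factors,
        lambda: SVRRegressor(sigma=svr["sigma"], epsilon=svr["epsilon"], C=svr["C"]),
        var, seed=args.seed,
    )
    out = args.results_dir / "augmentation_sweep_svr.csv"
    table.to_csv(out, index=False)
    best = table.loc[table["mean_error_mm"].idxmin()]
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"SVR: best factor {int(best['factor'])} "
          f"({best['mean_error_mm']:.3f} +/- {best['sd_error_mm']:.3f} mm) -> {out}")

    dnn_factors = [int(f) for f in args.dnn_factors.split(",")]
    dnn_table = augmentation_sweep(
        ds, dnn_factors,
        lambda: DNNRegressor(DNNConfig(seed=args.seed, epochs=300)),
        var, seed=args.seed,
    )
    dnn_out = args.results_dir / "augmentation_sweep_dnn.csv"
    dnn_table.to_csv(dnn_out, index=False)
    print(dnn_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"DNN sweep -> {dnn_out}")


if __name__ == "__main__":
    main()
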