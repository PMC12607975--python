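"""Variable selection on the smoothed calibration data.

Runs CARS, UVE and VCPA-IRIV per pigment on the Smooth-preprocessed
calibration samples, reports subset sizes, compression rates and recovery of
the planted informative cells, and persists each selection (indices, scores
summary, trace) to ``results/selection/``.
"""

import json
import sys
from pathlib import Path

import numpy as np

from teapigments.core_data import pigment_vector, read_dataset
from teapigments.preprocess import (
    PreprocessSpec,
    apply_preprocessor,
    fit_preprocessor,
)
from teapigments.varselect import SelectorConfig, select

DATA = Path("results/data")
OUT = Path("results/selection")


def main() -> None:
    ds, recs = read_dataset(DATA / "full_features.csv",
                            DATA / "full_reference.csv")
    truth = json.loads((DATA / "ground_truth.json").read_text())
    planted = set(truth["full"]["informative_indices"])
    with open("results/split.json") as fh:
        split = json.load(fh)
    cal = np.array(split["calibration"])

    prep = fit_preprocessor(ds.matrix[cal], PreprocessSpec(method="smooth"))
    Xc = apply_preprocessor(ds.matrix[cal], prep)
    OUT.mkdir(parents=True, exist_ok=True)

    print(f"{'pigment':8s} {'algorithm':10s} {'n_vars':>6s} {'compression':>11s} "
          f"{'planted hit':>11s}")
    for pigment in ("TF", "TR", "TB"):
        y = pigment_vector(recs, pigment)[cal]
        for alg in ("CARS", "UVE", "VCPA_IRIV"):
            cfg = SelectorConfig(algorithm=alg, seed=1)
            res = select(Xc, y, cfg)
            hit = len(set(res.selected) & planted)
            comp = 1 - len(res.selected) / ds.n_variables
            print(f"{pigment:8s} {alg:10s} {len(res.selected):6d} "
                  f"{comp:10.0%} {hit:8d}/{len(planted)}")
            doc = {
                "pigment": pigment, "algorithm": alg,
                "selected": res.selected,
                "selected_names": [ds.keys[j].name for j in res.selected],
                "best_rmsecv": res.best_rmsecv,
                "trace": res.trace,
            }
            with open(OUT / f"{pigment}_{alg}.json", "w") as fh:
                json.dump(doc, fh, indent=1)


if __name__ == "__main__":
    sys.exit(main())
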