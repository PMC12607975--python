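"""Kennard-Stone partition and preprocessing comparison.

Splits the 150 samples 100/50 (Mahalanobis K-S), then fits full-variable
PLSR models for each pigment under the four preprocessing options (raw, MSC,
Min-Max, Smooth).  Writes the comparison to
``results/preprocessing_comparison.csv`` and the split to
``results/split.json``.
"""

import json
import sys
from pathlib import Path

from teapigments.calibrate import PipelineSpec, reports_frame, run_pipeline
from teapigments.core_data import read_dataset
from teapigments.preprocess import kennard_stone_split

DATA = Path("results/data")


def main() -> None:
    ds, recs = read_dataset(DATA / "full_features.csv",
                            DATA / "full_reference.csv")
    split = kennard_stone_split(ds.matrix, 2.0 / 3.0, metric="mahalanobis")
    Path("results").mkdir(exist_ok=True)
    with open("results/split.json", "w") as fh:
        json.dump({"calibration": list(split.calibration_indices),
                   "prediction": list(split.prediction_indices),
                   "metric": split.metric}, fh)
    print(f"K-S split: {len(split.calibration_indices)} calibration / "
          f"{len(split.prediction_indices)} prediction")

    spec = PipelineSpec(
        combos=(("none", "none", "PLSR"), ("msc", "none", "PLSR"),
                ("minmax", "none", "PLSR"), ("smooth", "none", "PLSR")),
        seed=1,
    )
    reports, _ = run_pipeline(ds, recs, spec)
    df = reports_frame(reports)
    df.to_csv("results/preprocessing_comparison.csv", index=False,
              float_format="%.6f")
    print(df.to_string(index=False))
    best = df.loc[df.groupby("pigment").RPD.idxmax()]
    print("\nbest preprocessing per pigment (by RPD):")
    print(best[["pigment", "preprocess", "RPD"]].to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
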