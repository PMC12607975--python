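"""Generate the synthetic rolling-run datasets used by the analysis.

Writes a 30-sample quick-look fixture and the full 150-sample x 210-variable
dataset (10 time points x 15 replicates), their pigment reference tables, the
inverted absorbance quads, and the planted ground truth, under
``results/data/``.
"""

import sys
from pathlib import Path

import pandas as pd

from teapigments.assay import assay_table
from teapigments.core_data import pigment_frame, read_dataset
from teapigments.synthetic import make_fixture_suite, simulate_absorbances

OUT = Path("results/data")


def main() -> None:
    paths = make_fixture_suite(OUT)
    ds, recs = read_dataset(paths["full_features"], paths["full_reference"])
    print(f"full dataset: {ds.n_samples} samples x {ds.n_variables} variables")
    print(f"small dataset + ground truth at {OUT}/")

    # absorbance quads consistent with the reference pigments, and the
    # round-trip check through the assay formulas
    quads = simulate_absorbances(recs, seed=0)
    pd.DataFrame(
        {"sample_id": [q.sample_id for q in quads],
         "EA": [q.EA for q in quads], "EB": [q.EB for q in quads],
         "EC": [q.EC for q in quads], "ED": [q.ED for q in quads]}
    ).to_csv(OUT / "full_absorbances.csv", index=False)
    back = assay_table(quads)
    drift = (back[["TF", "TR", "TB"]].to_numpy()
             - pigment_frame(recs)[["TF", "TR", "TB"]].to_numpy())
    print(f"assay round-trip max |error|: {abs(drift).max():.3g} (expected ~0)")


if __name__ == "__main__":
    sys.exit(main())
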