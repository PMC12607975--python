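"""Colorimetric systematic analysis of black-tea pigments.

Pigment contents are computed from the absorbances at 380 nm (1 cm path) of
the four fractions A-D produced by the classical solvent-partition workup:

    TF% = 2.25 * EC
    TR% = 7.06 * (2*EA + 2*ED - 2*EB - EC)
    TB% = 7.06 * 2*EB

The formulas are linear in the absorbance quad, so they are applied to
single (already replicate-averaged) readings; averaging is the caller's
concern.  A negative TR arithmetic result (possible on noisy readings) is
preserved and reported with a warning rather than clamped, so that synthetic
round-trips stay exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_data import PigmentRecord

__all__ = ["AbsorbanceQuad", "pigments_from_absorbance", "assay_table",
           "assay_csv"]

TF_COEF = 2.25
TR_COEF = 7.06
TB_COEF = 7.06


@dataclass(frozen=True)
class AbsorbanceQuad:
    """Absorbances of solutions A-D at 380 nm for one sample."""

    EA: float
    EB: float
    EC: float
    ED: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ("EA", "EB", "EC", "ED"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"absorbance {name} must be >= 0, got {v}")


def pigments_from_absorbance(q: AbsorbanceQuad) -> PigmentRecord:
    """Apply the three pigment formulas to one absorbance quad."""
    tf = TF_COEF * q.EC
    tr = TR_COEF * (2.0 * q.EA + 2.0 * q.ED - 2.0 * q.EB - q.EC)
    tb = TB_COEF * 2.0 * q.EB
    if tr < 0:
        warnings.warn(
            f"negative TR ({tr:.4g}%) for sample {q.sample_id or '<unnamed>'}; "
            "value preserved",
            UserWarning,
            stacklevel=2,
        )
    return PigmentRecord(q.sample_id, tf, tr, tb)


def assay_csv(absorbance_path, reference_path) -> None:
    """Convert an absorbance CSV (sample_id, EA, EB, EC, ED) into a pigment
    reference CSV (sample_id, TF, TR, TB)."""
    df = pd.read_csv(absorbance_path, float_precision="round_trip")
    for col in ("sample_id", "EA", "EB", "EC", "ED"):
        if col not in df.columns:
            raise ValueError(f"absorbance file is missing column {col!r}")
    quads = [
        AbsorbanceQuad(float(r.EA), float(r.EB), float(r.EC), float(r.ED),
                       str(r.sample_id))
        for r in df.itertuples()
    ]
    assay_table(quads).to_csv(reference_path, index=False)


def assay_table(quads: Sequence[AbsorbanceQuad]) -> pd.DataFrame:
    """Batch conversion: absorbance quads -> reference-CSV-shaped frame."""
    records = [pigments_from_absorbance(q) for q in quads]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "TF": [r.TF for r in records],
            "TR": [r.TR for r in records],
            "TB": [r.TB for r in records],
        }
    )
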