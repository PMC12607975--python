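"""Domain types and CSV I/O for rolling-leaf electrical feature tables.

The measurement layout is a wide matrix: one row per leaf sample, one column
per (electrical parameter, test frequency) pair.  Seven LCR parameters --
series equivalent inductance (Ls), capacitance (Cs), resistance (Rs), complex
impedance (Z), reactance (X), dissipation factor (D) and quality factor (Q) --
are swept over a 30-point frequency grid from 0.02 kHz to 100 kHz, giving the
canonical 210-column layout.  Columns are named ``<code>_<frequency>kHz``
(e.g. ``Cs_0.02kHz``) and ordered parameter-major: all Ls frequencies
ascending, then all Cs, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_CODES",
    "PARAMETER_UNITS",
    "DEFAULT_FREQUENCIES_KHZ",
    "FrequencyGrid",
    "VariableKey",
    "SampleMeta",
    "ElectricalDataset",
    "PigmentRecord",
    "build_keys",
    "column_name",
    "parse_column_name",
    "read_dataset",
    "write_dataset",
    "read_reference",
    "write_reference",
    "subset_columns",
    "pigment_frame",
    "pigment_vector",
]

#: LCR parameter codes in canonical (column-major) order.
PARAMETER_CODES: tuple[str, ...] = ("Ls", "Cs", "Rs", "Z", "X", "D", "Q")

#: Semantic unit of each parameter.
PARAMETER_UNITS: dict[str, str] = {
    "Ls": "H",
    "Cs": "F",
    "Rs": "ohm",
    "Z": "ohm",
    "X": "ohm",
    "D": "dimensionless",
    "Q": "dimensionless",
}

#: The 30 test frequencies (kHz) of the default acquisition sweep.
DEFAULT_FREQUENCIES_KHZ: tuple[float, ...] = (
    0.02, 0.04, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
    0.6, 0.7, 0.8, 0.9, 1, 2, 4, 6, 8, 10,
    15, 20, 30, 40, 50, 60, 70, 80, 90, 100,
)

_META_COLUMNS = ("sample_id", "time_min", "replicate")


def _format_frequency(value: float) -> str:
    """Render a kHz frequency the way it appears in column headers."""
    text = f"{value:.10g}"
    return text


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered sweep of test frequencies, in kHz."""

    values: tuple[float, ...] = DEFAULT_FREQUENCIES_KHZ

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) == 0:
            raise ValueError("frequency grid is empty")
        if any(v <= 0 for v in vals):
            raise ValueError("frequencies must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_format_frequency(v) for v in self.values)

    def rank_of(self, frequency: float) -> int:
        """Index of ``frequency`` on the grid; raises if absent."""
        target = float(frequency)
        for i, v in enumerate(self.values):
            if abs(v - target) <= 1e-9 * max(1.0, abs(v)):
                return i
        raise ValueError(f"frequency {frequency} kHz not on declared grid")


@dataclass(frozen=True)
class VariableKey:
    """One (parameter, frequency) cell of the feature layout.

    ``column_index`` is the cell's 0-based position in the *full* canonical
    layout: ``parameter_rank * len(grid) + frequency_rank``.
    """

    parameter: str
    frequency: float
    column_index: int

    @property
    def name(self) -> str:
        return column_name(self.parameter, self.frequency)

    @property
    def unit(self) -> str:
        return PARAMETER_UNITS[self.parameter]


def column_name(parameter: str, frequency: float) -> str:
    if parameter not in PARAMETER_CODES:
        raise ValueError(f"unknown parameter code: {parameter!r}")
    return f"{parameter}_{_format_frequency(frequency)}kHz"


def parse_column_name(name: str) -> tuple[str, float]:
    """Split a ``<code>_<frequency>kHz`` header into its parts."""
    if not name.endswith("kHz") or "_" not in name:
        raise ValueError(f"malformed feature column name: {name!r}")
    code, rest = name.split("_", 1)
    if code not in PARAMETER_CODES:
        raise ValueError(f"unknown parameter code: {code!r}")
    try:
        freq = float(rest[: -len("kHz")])
    except ValueError as exc:
        raise ValueError(f"malformed frequency in column name: {name!r}") from exc
    return code, freq


def column_index(parameter: str, frequency: float, grid: FrequencyGrid) -> int:
    """Canonical flat index of a (parameter, frequency) cell."""
    if parameter not in PARAMETER_CODES:
        raise ValueError(f"unknown parameter code: {parameter!r}")
    return PARAMETER_CODES.index(parameter) * len(grid) + grid.rank_of(frequency)


def build_keys(grid: FrequencyGrid | None = None) -> list[VariableKey]:
    """All 7 x len(grid) variable keys in canonical column order."""
    grid = grid or FrequencyGrid()
    keys = []
    for p_rank, code in enumerate(PARAMETER_CODES):
        for f_rank, freq in enumerate(grid.values):
            keys.append(VariableKey(code, freq, p_rank * len(grid) + f_rank))
    return keys


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    time_min: float
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class ElectricalDataset:
    """Sample x (parameter, frequency) feature matrix plus metadata."""

    meta: list[SampleMeta]
    keys: list[VariableKey]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape != (len(self.meta), len(self.keys)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.meta)} samples x {len(self.keys)} keys"
            )
        if self.matrix.size and not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def n_variables(self) -> int:
        return len(self.keys)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    @property
    def column_names(self) -> list[str]:
        return [k.name for k in self.keys]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.column_names)
        df.insert(0, "replicate", [m.replicate for m in self.meta])
        df.insert(0, "time_min", [m.time_min for m in self.meta])
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass(frozen=True)
class PigmentRecord:
    """Reference pigment contents (%) of one sample: theaflavins (TF),
    thearubigins (TR), theabrownins (TB)."""

    sample_id: str
    TF: float
    TR: float
    TB: float


def write_dataset(ds: ElectricalDataset, path) -> None:
    """Write the wide CSV dialect: sample_id, time_min, replicate, features."""
    ds.to_frame().to_csv(path, index=False)


def read_dataset(
    features_path,
    reference_path,
    grid: FrequencyGrid | None = None,
) -> tuple[ElectricalDataset, list[PigmentRecord]]:
    """Read aligned feature and reference CSVs.

    Samples are canonicalised to (time_min, replicate) order; the reference
    records are returned in the same order.  Duplicated sample ids, unknown
    parameter codes, off-grid frequencies and non-numeric cells are rejected.
    """
    grid = grid or FrequencyGrid()
    df = pd.read_csv(features_path, float_precision="round_trip")
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature file is missing column {col!r}")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicated sample_id in feature file: {dup!r}")

    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    keyed: list[tuple[int, str]] = []
    for col in feature_cols:
        code, freq = parse_column_name(col)
        keyed.append((column_index(code, freq, grid), col))
    if len({ci for ci, _ in keyed}) != len(keyed):
        raise ValueError("duplicate feature columns in file")
    keyed.sort()

    values = df[[c for _, c in keyed]].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()][0]
        raise ValueError(f"non-numeric or missing cell in column {bad!r}")

    order = np.lexsort(
        (df["replicate"].to_numpy(), df["time_min"].to_numpy())
    )
    meta = [
        SampleMeta(str(df["sample_id"].iloc[i]), float(df["time_min"].iloc[i]),
                   int(df["replicate"].iloc[i]))
        for i in order
    ]
    keys = []
    for ci, col in keyed:
        code, freq = parse_column_name(col)
        keys.append(VariableKey(code, freq, ci))
    matrix = values.to_numpy(dtype=float)[order]
    ds = ElectricalDataset(meta, keys, matrix)

    records = read_reference(reference_path)
    by_id = {r.sample_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicated sample_id in reference file")
    missing = [sid for sid in ds.sample_ids if sid not in by_id]
    extra = [sid for sid in by_id if sid not in set(ds.sample_ids)]
    if missing or extra:
        raise ValueError(
            f"sample_id mismatch between files (missing={missing[:3]}, "
            f"extra={extra[:3]})"
        )
    aligned = [by_id[sid] for sid in ds.sample_ids]
    return ds, aligned


def read_reference(path) -> list[PigmentRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sample_id", "TF", "TR", "TB"):
        if col not in df.columns:
            raise ValueError(f"reference file is missing column {col!r}")
    for col in ("TF", "TR", "TB"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"non-numeric cell in reference column {col!r}")
    return [
        PigmentRecord(str(r.sample_id), float(r.TF), float(r.TR), float(r.TB))
        for r in df.itertuples()
    ]


def write_reference(records: Sequence[PigmentRecord], path) -> None:
    pigment_frame(records).to_csv(path, index=False)


def pigment_frame(records: Sequence[PigmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "TF": [r.TF for r in records],
            "TR": [r.TR for r in records],
            "TB": [r.TB for r in records],
        }
    )


def pigment_vector(records: Sequence[PigmentRecord], which: str) -> np.ndarray:
    if which not in ("TF", "TR", "TB"):
        raise ValueError(f"unknown pigment {which!r}")
    return np.array([getattr(r, which) for r in records], dtype=float)


def subset_columns(ds: ElectricalDataset, indices: Iterable[int]) -> ElectricalDataset:
    """New dataset containing exactly the requested columns, in given order.

    ``indices`` are positions into ``ds.keys`` (not canonical layout indices);
    the retained keys keep their original canonical ``column_index``.
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate column index in subset")
    for i in idx:
        if not (0 <= i < ds.n_variables):
            raise ValueError(f"column index {i} out of range")
    keys = [ds.keys[i] for i in idx]
    matrix = ds.matrix[:, idx] if idx else np.empty((ds.n_samples, 0))
    return ElectricalDataset(list(ds.meta), keys, matrix)
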