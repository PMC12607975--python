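"""Synthetic rolling-run generator.

No measured dataset accompanies the study conditions this package targets,
so the generator emulates their statistical structure: a 90-minute rolling
run sampled every 10 minutes (10 time points x 15 replicates = 150 samples),
a scalar latent "rolling state" that increases monotonically with time and
steepens after an inflection at 70 min, pigment contents (TF/TR/TB, %) that
rise as saturating functions of that state, and a 7-parameter x 30-frequency
electrical feature matrix in which only a planted subset of (parameter,
frequency) cells is coupled to the state.

Frequency-dispersion baselines follow the qualitative shapes reported for
rolling leaves: Ls rises with frequency, Cs / Rs / D fall, Q and Z are
unimodal, X is anti-unimodal.  Each feature cell is

    baseline(parameter, frequency)
    + [informative only]  coupling * w_j * s  +  nonlinearity * v_j * s**2
    + Gaussian(noise_sd)

so with ``noise_sd = 0`` and ``nonlinearity = 0`` every informative column is
an exact affine function of the latent state.  All randomness flows from the
single ``seed``; identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .assay import AbsorbanceQuad, TB_COEF, TF_COEF, TR_COEF
from .core_data import (
    ElectricalDataset,
    FrequencyGrid,
    PARAMETER_CODES,
    PigmentRecord,
    SampleMeta,
    VariableKey,
    build_keys,
    column_index,
    write_dataset,
    write_reference,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEFAULT_INFORMATIVE_KEYS",
    "dispersion_baseline",
    "simulate",
    "simulate_absorbances",
    "make_fixture_suite",
]

#: Planted informative (parameter, frequency-kHz) cells: low-frequency Cs and
#: Rs plus Ls and X cells spread over the sweep.  A modelling choice for the
#: fixtures, not a measured ground truth.
DEFAULT_INFORMATIVE_KEYS: tuple[tuple[str, float], ...] = (
    ("Ls", 0.4), ("Ls", 4), ("Ls", 40),
    ("Cs", 0.02), ("Cs", 0.04), ("Cs", 0.06),
    ("Rs", 0.02), ("Rs", 0.08), ("Rs", 0.15),
    ("X", 10), ("X", 50), ("X", 100),
)

# linear / quadratic coupling magnitudes cycled over the informative cells
_W_CYCLE = (1.0, 0.8, 1.2)
_V_CYCLE = (1.0, -0.6, 0.3)

# sign of the rolling-time trend per parameter (Ls, Cs up; Rs, D, X down;
# Q, Z up)
_TREND_SIGN = {"Ls": 1.0, "Cs": 1.0, "Rs": -1.0, "Z": 1.0, "X": -1.0,
               "D": -1.0, "Q": 1.0}

# pigment curve family: value = lo + (hi - lo) * h(s; k), with
# h(s; k) = (1 - exp(-k s)) / (1 - exp(-k)) saturating in the latent state
_PIGMENT_CURVES = {
    "TF": (0.40, 1.25, 2.2),
    "TR": (5.0, 11.0, 1.8),
    "TB": (3.2, 7.2, 2.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_timepoints: int = 10
    minutes_per_step: int = 10
    n_replicates: int = 15
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    informative_keys: tuple[tuple[str, float], ...] = DEFAULT_INFORMATIVE_KEYS
    coupling_strength: float = 1.0
    nonlinearity: float = 0.6
    noise_sd: float = 0.02
    state_noise_sd: float = 0.03
    pigment_noise_sd: float = 0.008  # relative to each pigment's range
    inflection_min: float = 70.0
    inflection_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 time points and >= 1 replicate")
        if not self.informative_keys:
            raise ValueError("informative key set must be non-empty")
        if min(self.coupling_strength, self.nonlinearity, self.noise_sd,
               self.state_noise_sd, self.pigment_noise_sd) < 0:
            raise ValueError("noise and coupling settings must be >= 0")
        for code, freq in self.informative_keys:
            column_index(code, freq, self.grid)  # validates membership

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.n_replicates

    @property
    def time_points(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.minutes_per_step


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    latent_state: np.ndarray
    informative_keys: list[VariableKey]
    informative_indices: list[int]
    time_min: np.ndarray
    time_points: np.ndarray
    pigment_curves: dict[str, np.ndarray]  # noiseless value per time point


def _latent_schedule(config: SimConfig) -> np.ndarray:
    """Monotone state trajectory over the time points, in [0, 1], with a
    slope increase after the inflection."""
    t = config.time_points
    raw = t + (config.inflection_gain - 1.0) * np.maximum(0.0, t - config.inflection_min)
    return raw / raw[-1]


def _pigment_value(name: str, s: np.ndarray) -> np.ndarray:
    lo, hi, k = _PIGMENT_CURVES[name]
    h = (1.0 - np.exp(-k * np.asarray(s, dtype=float))) / (1.0 - np.exp(-k))
    return lo + (hi - lo) * h


def dispersion_baseline(parameter: str, grid: FrequencyGrid | None = None) -> np.ndarray:
    """Noiseless baseline value of one parameter across the frequency sweep."""
    grid = grid or FrequencyGrid()
    f = np.asarray(grid.values)
    u = np.log(f / f[0]) / np.log(f[-1] / f[0])  # 0..1 on a log-frequency axis
    if parameter == "Ls":
        return 2.0 + 3.0 * u
    if parameter == "Cs":
        return 3.0 + 5.0 * np.exp(-3.0 * u)
    if parameter == "Rs":
        return 2.0 + 6.0 * np.exp(-2.5 * u)
    if parameter == "D":
        return 1.0 + 4.0 * np.exp(-2.0 * u)
    if parameter == "Q":
        return 2.0 + 4.0 * np.exp(-(((u - 0.45) / 0.25) ** 2))
    if parameter == "Z":
        return 3.0 + 5.0 * np.exp(-(((u - 0.5) / 0.3) ** 2))
    if parameter == "X":
        return 8.0 - 5.0 * np.exp(-(((u - 0.5) / 0.3) ** 2))
    raise ValueError(f"unknown parameter code: {parameter!r}")


def simulate(config: SimConfig) -> tuple[ElectricalDataset, list[PigmentRecord], GroundTruth]:
    """Generate one synthetic rolling run."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    keys = build_keys(grid)
    n = config.n_samples
    p = len(keys)

    schedule = _latent_schedule(config)
    time_min = np.repeat(config.time_points, config.n_replicates)
    s = np.repeat(schedule, config.n_replicates)
    s = s + rng.normal(0.0, config.state_noise_sd, n)

    meta = [
        SampleMeta(f"T{int(t):02d}R{r + 1:02d}", float(t), r + 1)
        for t in config.time_points
        for r in range(config.n_replicates)
    ]

    pigment_noise = rng.normal(0.0, 1.0, (n, 3))
    records = []
    pig_values = {}
    for col, name in enumerate(("TF", "TR", "TB")):
        lo, hi, _ = _PIGMENT_CURVES[name]
        vals = _pigment_value(name, s) + config.pigment_noise_sd * (hi - lo) * pigment_noise[:, col]
        pig_values[name] = vals
    for i, m in enumerate(meta):
        records.append(
            PigmentRecord(m.sample_id, float(pig_values["TF"][i]),
                          float(pig_values["TR"][i]), float(pig_values["TB"][i]))
        )

    info_indices = [column_index(code, freq, grid) for code, freq in config.informative_keys]
    info_set = dict()
    for rank, idx in enumerate(info_indices):
        code, _ = config.informative_keys[rank]
        w = _TREND_SIGN[code] * _W_CYCLE[rank % len(_W_CYCLE)]
        v = _TREND_SIGN[code] * _V_CYCLE[rank % len(_V_CYCLE)]
        info_set[idx] = (w, v)

    matrix = np.empty((n, p))
    baselines = {code: dispersion_baseline(code, grid) for code in PARAMETER_CODES}
    noise = rng.normal(0.0, config.noise_sd, (n, p)) if config.noise_sd > 0 else np.zeros((n, p))
    for key in keys:
        col = baselines[key.parameter][grid.rank_of(key.frequency)] + noise[:, key.column_index]
        if key.column_index in info_set:
            w, v = info_set[key.column_index]
            col = col + config.coupling_strength * w * s + config.nonlinearity * v * s**2
        matrix[:, key.column_index] = col

    truth = GroundTruth(
        latent_state=s,
        informative_keys=[keys[i] for i in sorted(info_set)],
        informative_indices=sorted(info_set),
        time_min=time_min,
        time_points=config.time_points.copy(),
        pigment_curves={name: _pigment_value(name, schedule) for name in ("TF", "TR", "TB")},
    )
    return ElectricalDataset(meta, keys, matrix), records, truth


def simulate_absorbances(
    pigments: Sequence[PigmentRecord],
    seed: int = 0,
    split: float = 0.5,
    noise_sd: float = 0.0,
) -> list[AbsorbanceQuad]:
    """Invert the assay formulas to absorbance quads.

    With ``noise_sd = 0`` the forward assay recovers the input pigments
    exactly: EC = TF / 2.25, EB = TB / (2 * 7.06), and EA + ED satisfies the
    TR equation with the A/D balance set by ``split``.
    """
    if not (0.0 <= split <= 1.0):
        raise ValueError("split must be in [0, 1]")
    rng = np.random.default_rng(seed)
    quads = []
    for rec in pigments:
        if min(rec.TF, rec.TR, rec.TB) < 0:
            raise ValueError(
                f"unattainable pigment triple for {rec.sample_id!r}: "
                "negative content"
            )
        ec = rec.TF / TF_COEF
        eb = rec.TB / (2.0 * TB_COEF)
        total_ad = (rec.TR / TR_COEF + 2.0 * eb + ec) / 2.0
        if total_ad < 0:
            raise ValueError(
                f"unattainable pigment triple for {rec.sample_id!r}"
            )
        ea = split * total_ad
        ed = (1.0 - split) * total_ad
        if noise_sd > 0:
            ea, eb, ec, ed = (
                max(0.0, v + rng.normal(0.0, noise_sd)) for v in (ea, eb, ec, ed)
            )
        quads.append(AbsorbanceQuad(ea, eb, ec, ed, rec.sample_id))
    return quads


def planted_design(
    n: int = 100,
    p: int = 50,
    n_informative: int = 5,
    noise_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Independent-column benchmark for selector recovery tests.

    Columns are iid standard normal; ``n_informative`` randomly placed
    columns generate ``y`` linearly (coefficients of magnitude 0.5-1.5 with
    random signs) plus Gaussian noise of sd ``noise_fraction * sd(signal)``.
    Unlike the rolling generator -- whose informative cells are collinear by
    construction -- every planted column here carries independent signal, so
    full recall is the correct outcome.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    planted = np.sort(rng.choice(p, size=n_informative, replace=False))
    beta = rng.uniform(0.5, 1.5, n_informative) * rng.choice([-1.0, 1.0], n_informative)
    signal = X[:, planted] @ beta
    y = signal + noise_fraction * signal.std() * rng.normal(size=n)
    return X, y, [int(j) for j in planted]


def make_fixture_suite(out_dir, small_seed: int = 7, full_seed: int = 11) -> dict[str, Path]:
    """Write small (30-sample) and full-scale (150-sample) CSV fixtures plus a
    ground-truth JSON, with fixed seeds, for the test suite."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_doc: dict[str, dict] = {}
    for tag, cfg in (
        ("small", SimConfig(n_replicates=3, seed=small_seed)),
        ("full", SimConfig(seed=full_seed)),
    ):
        ds, records, truth = simulate(cfg)
        f_path = out / f"{tag}_features.csv"
        r_path = out / f"{tag}_reference.csv"
        write_dataset(ds, f_path)
        write_reference(records, r_path)
        paths[f"{tag}_features"] = f_path
        paths[f"{tag}_reference"] = r_path
        truth_doc[tag] = {
            "seed": cfg.seed,
            "informative_indices": truth.informative_indices,
            "informative_names": [k.name for k in truth.informative_keys],
            "latent_state": truth.latent_state.tolist(),
            "time_points": truth.time_points.tolist(),
            "pigment_curves": {k: v.tolist() for k, v in truth.pigment_curves.items()},
        }
    t_path = out / "ground_truth.json"
    with open(t_path, "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = t_path
    return paths
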