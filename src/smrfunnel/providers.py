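"""Provider tables: reading, validation, writing and synthetic generation.

A provider table is a delimited text file with header
``provider_id,observed,expected``: one row per institution, the observed
event count (non-negative integer) and the expected count from indirect
standardisation (positive real). The SMR is observed/expected.

The synthetic generator draws in-control providers with observed ~
Poisson(λ) and out-of-control providers with observed ~ Poisson(θ·λ),
θ ≠ 1, so classification performance can be checked against known truth.
Truth labels live only in the simulation output (``true_status, theta``
columns), never in the plain provider table, so classification code cannot
see them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProviderRecord",
    "SyntheticSpec",
    "ProviderValidationError",
    "read_providers",
    "write_providers",
    "providers_to_frame",
    "simulate_providers",
    "write_simulation",
]

PROVIDER_COLUMNS = ("provider_id", "observed", "expected")


@dataclass(frozen=True)
class ProviderRecord:
    """One institution's counts; flags are filled in by classification."""

    provider_id: str
    observed: int
    expected: float
    flag_95: "str | None" = None
    flag_998: "str | None" = None

    @property
    def smr(self) -> float:
        return self.observed / self.expected


class ProviderValidationError(ValueError):
    """Raised with one message line per offending row/field."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid provider table:\n" + "\n".join(self.problems))


def _coerce_observed(value, row: int, problems: list) -> int:
    # accepts "12" and "12.0"; rejects "12.5" and negatives
    try:
        f = float(value)
    except (TypeError, ValueError):
        problems.append(f"row {row}: observed={value!r} is not a number")
        return 0
    if not float(f).is_integer():
        problems.append(f"row {row}: observed={value!r} is not an integer count")
        return 0
    n = int(f)
    if n < 0:
        problems.append(f"row {row}: observed={n} is negative")
        return 0
    return n


def _coerce_expected(value, row: int, problems: list) -> float:
    try:
        f = float(value)
    except (TypeError, ValueError):
        problems.append(f"row {row}: expected={value!r} is not a number")
        return 1.0
    if not np.isfinite(f) or f <= 0.0:
        problems.append(f"row {row}: expected={f} must be positive")
        return 1.0
    return f


def _records_from_frame(df: pd.DataFrame) -> list:
    problems: list = []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        obs = _coerce_observed(row.observed, i, problems)
        exp = _coerce_expected(row.expected, i, problems)
        records.append(ProviderRecord(str(row.provider_id), obs, exp))
    if problems:
        raise ProviderValidationError(problems)
    return records


def read_providers(path) -> list:
    """Read and validate a provider CSV; row numbers are 1-based data rows."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PROVIDER_COLUMNS if c not in df.columns]
    if missing:
        raise ProviderValidationError(
            [f"missing required column(s): {', '.join(missing)}"]
        )
    return _records_from_frame(df[list(PROVIDER_COLUMNS)])


def providers_to_frame(records: Sequence[ProviderRecord]) -> pd.DataFrame:
    """Records → tidy frame (includes smr and any flags that are set)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=list(PROVIDER_COLUMNS))
    df["smr"] = df["observed"] / df["expected"]
    if df["flag_95"].isna().all() and df["flag_998"].isna().all():
        df = df.drop(columns=["flag_95", "flag_998"])
    return df


def write_providers(records: Sequence[ProviderRecord], path) -> None:
    """Write the plain 3-column provider table (no flags, no truth)."""
    pd.DataFrame(
        {
            "provider_id": [r.provider_id for r in records],
            "observed": [r.observed for r in records],
            "expected": [r.expected for r in records],
        }
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic provider cohort.

    ``lam`` gives the expected counts: a scalar (all providers share one λ),
    a (low, high) pair (λ_i ~ Uniform[low, high]) or an explicit sequence.
    ``theta`` is the outlier rate ratio (observed ~ Poisson(θ·λ)); the seed
    is required — simulation is always reproducible.
    """

    n_in_control: int
    n_outliers: int
    theta: float
    lam: "float | tuple | Sequence[float]"
    seed: int

    def __post_init__(self) -> None:
        if self.n_in_control < 0 or self.n_outliers < 0:
            raise ValueError("provider counts must be non-negative")
        if self.n_in_control + self.n_outliers == 0:
            raise ValueError("spec generates no providers")
        if self.theta <= 0.0:
            raise ValueError("theta must be positive")
        if self.n_outliers > 0 and self.theta == 1.0:
            raise ValueError("theta must differ from 1 when outliers are requested")


def _draw_lams(spec: SyntheticSpec, n: int, rng) -> np.ndarray:
    lam = spec.lam
    if np.isscalar(lam):
        out = np.full(n, float(lam))
    elif isinstance(lam, tuple) and len(lam) == 2:
        out = rng.uniform(float(lam[0]), float(lam[1]), size=n)
    else:
        arr = np.asarray(lam, dtype=float)
        if arr.size != n:
            raise ValueError(f"explicit lam list has {arr.size} entries, need {n}")
        out = arr
    if np.any(out <= 0.0):
        raise ValueError("expected counts must be positive")
    return out


def simulate_providers(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a provider cohort with sidecar truth columns.

    Returns a frame with columns ``provider_id, observed, expected,
    true_status, theta`` where true_status is 'in_control' or 'outlier'
    (θ applied multiplicatively to λ for outliers). Deterministic for a
    given spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_in_control + spec.n_outliers
    lams = _draw_lams(spec, n, rng)
    status = np.array(
        ["in_control"] * spec.n_in_control + ["outlier"] * spec.n_outliers
    )
    mean = np.where(status == "outlier", spec.theta * lams, lams)
    observed = rng.poisson(mean)
    return pd.DataFrame(
        {
            "provider_id": [f"P{i + 1:04d}" for i in range(n)],
            "observed": observed.astype(int),
            "expected": lams,
            "true_status": status,
            "theta": np.where(status == "outlier", spec.theta, 1.0),
        }
    )


def write_simulation(sim: pd.DataFrame, path) -> None:
    """Write a simulated cohort including the truth sidecar columns."""
    sim.to_csv(path, index=False)


def records_from_simulation(sim: pd.DataFrame) -> list:
    """Drop the truth columns and return plain provider records."""
    return [
        ProviderRecord(str(r.provider_id), int(r.observed), float(r.expected))
        for r in sim.itertuples(index=False)
    ]
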