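"""Containers and file IO shared by every other module.

Posterior draws and datasets travel as plain headered CSV, run
configurations as YAML key/value files, and LOO reports as JSON.  All
downstream modules consume only the containers defined here; nothing
else in the package touches the filesystem.

Every log-density and log-weight in the package is carried in log space;
exponentiation happens only at the self-normalization boundary, because
raw ``1/likelihood`` importance ratios overflow double precision on
unstable observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PosteriorDraws",
    "Dataset",
    "RunConfig",
    "child_seed",
    "read_draws",
    "write_draws",
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
    "write_report",
    "read_report",
]

#: default perturbation-size grid: 4^-r for r = 0..10
DEFAULT_HBAR_GRID = tuple(float(4.0**-r) for r in range(11))

#: default transformation attempt order (cheapest first: the partial
#: moment matches need no model gradients)
DEFAULT_TRANSFORM_ORDER = ("PMM1", "PMM2", "KL", "Var", "LL")


class InputError(ValueError):
    """Malformed input file or container invariant violation."""


@dataclass(frozen=True)
class PosteriorDraws:
    """An ``s x p`` matrix of posterior parameter draws.

    Parameters
    ----------
    draws
        Matrix of shape ``(s, p)``; one row per draw, one column per
        parameter.  Must be finite with ``s >= 2``.
    param_names
        Unique column names, length ``p``.
    source
        ``"mcmc"`` for draws from the posterior itself, ``"variational"``
        for draws from a variational approximation (these require the
        corrected weights of
        :func:`adaloo.adaptive_loo.variational_corrected_log_weights`).
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    source: str = "mcmc"

    def __post_init__(self):
        arr = np.asarray(self.draws, dtype=float)
        if arr.ndim != 2:
            raise InputError(f"draws must be 2-D, got shape {arr.shape}")
        s, p = arr.shape
        if s < 2:
            raise InputError(f"at least 2 draws required, got s={s}")
        if p < 1:
            raise InputError("at least 1 parameter required")
        if not np.all(np.isfinite(arr)):
            k, a = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(f"non-finite draw at row {k}, column {a}")
        names = tuple(str(n) for n in self.param_names)
        if len(names) != p:
            raise InputError(
                f"{len(names)} parameter names for {p} columns"
            )
        if len(set(names)) != len(names):
            raise InputError("parameter names must be unique")
        object.__setattr__(self, "draws", arr)
        object.__setattr__(self, "param_names", names)
        if self.source not in ("mcmc", "variational"):
            raise InputError(f"unknown draw source {self.source!r}")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_params(self) -> int:
        return self.draws.shape[1]


@dataclass(frozen=True)
class Dataset:
    """``n`` observations with covariate rows ``X`` and binary labels ``y``."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise InputError(f"X must be 2-D, got shape {X.shape}")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise InputError("y must be 1-D with one label per row of X")
        if X.shape[0] < 2:
            raise InputError("n >= 2 required")
        if not np.all(np.isfinite(X)):
            raise InputError("covariates contain missing/non-finite values")
        if not np.isin(y, (0, 1)).all():
            bad = y[~np.isin(y, (0, 1))][0]
            raise InputError(f"labels must be in {{0,1}}, found {bad!r}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.astype(np.int64))

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RunConfig:
    """Settings for an adaptive LOO run.

    ``khat_threshold`` is the Pareto-shape diagnostic cutoff above which
    importance sampling is considered unreliable and adaptation is
    attempted.  ``hbar_grid`` is the list of maximum step sizes (in units
    of posterior standard deviations) scanned per transformation.
    """

    khat_threshold: float = 0.7
    hbar_grid: tuple[float, ...] = DEFAULT_HBAR_GRID
    transform_order: tuple[str, ...] = DEFAULT_TRANSFORM_ORDER
    seed: int = 0
    tail_fraction_rule: str = "min(0.2*s, 3*sqrt(s))"
    search: str = "first_success"  # or "exhaustive"

    def __post_init__(self):
        if not self.khat_threshold > 0:
            raise InputError("khat_threshold must be > 0")
        grid = tuple(float(h) for h in self.hbar_grid)
        if any(not (0.0 < h <= 1.0) for h in grid):
            raise InputError("hbar_grid values must lie in (0, 1]")
        object.__setattr__(self, "hbar_grid", grid)
        object.__setattr__(
            self, "transform_order", tuple(self.transform_order)
        )
        if self.search not in ("first_success", "exhaustive"):
            raise InputError(f"unknown search mode {self.search!r}")


def child_seed(seed: int, *keys) -> int:
    """Derive a reproducible child seed from the global seed plus keys.

    Keys may be integers or strings (observation index, method label).
    The result is independent of iteration order and stays below 2^31.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(int.from_bytes(k.encode(), "little") % (2**31))
        else:
            ints.append(int(k) % (2**31))
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=tuple(ints))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# CSV IO


def read_draws(
    path, names: Sequence[str] | None = None, source: str = "mcmc"
) -> PosteriorDraws:
    """Read posterior draws from a headered CSV table (one row per draw)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if names is not None:
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise InputError(f"missing draw columns: {missing}")
        df = df[list(names)]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise InputError(f"non-numeric values in column {col!r}")
    bad = np.argwhere(~np.isfinite(arr.astype(float)))
    if bad.size:
        r, c = bad[0]
        raise InputError(
            f"non-finite draw value at row {r}, column {df.columns[c]!r}"
        )
    return PosteriorDraws(arr.astype(float), tuple(df.columns), source=source)


def write_draws(draws: PosteriorDraws, path) -> None:
    pd.DataFrame(draws.draws, columns=list(draws.param_names)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_dataset(path, label_column: str = "y") -> Dataset:
    """Read a dataset CSV; all non-label columns become covariates."""
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise InputError("n >= 2 required (empty file)")
    if label_column not in df.columns:
        raise InputError(f"label column {label_column!r} not found")
    y = df[label_column].to_numpy()
    X = df.drop(columns=[label_column]).to_numpy(dtype=float)
    return Dataset(X, y)


def write_dataset(data: Dataset, path, label_column: str = "y") -> None:
    df = pd.DataFrame(
        data.X, columns=[f"x{j}" for j in range(data.n_covariates)]
    )
    df[label_column] = data.y
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# config + report IO


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=False)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["hbar_grid"] = list(config.hbar_grid)
    d["transform_order"] = list(config.transform_order)
    return d


def write_report(report, path) -> None:
    """Serialize a :class:`adaloo.adaptive_loo.LOOReport` to JSON.

    Full ``repr`` float precision is kept so a read-back round-trips all
    numerics; the run configuration is echoed for provenance.
    """
    doc = report.to_dict()
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
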