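"""Readers and writers for all parameter and demographic tables.

Canonical dialect: UTF-8 comma-separated CSV with a header row, counts at
full precision, probabilities at 10 significant digits. Every reader
validates before returning (row sums, ranges, coverage) and computation
never starts from an unvalidated table.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

from .states import AGE_MAX, AGE_MIN, N_STATES, SEXES, HealthState
from .transitions import TransitionTable


class ValidationError(ValueError):
    """An input file failed schema or invariant validation."""


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_columns(df: pd.DataFrame, cols, path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# demography

def write_initial_distribution(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_initial_distribution(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "sex", "age", "state", "count"], path)
    bad = df[~df["state"].isin([s.name for s in HealthState])]
    if len(bad):
        raise ValidationError(f"{path}: unknown states {bad['state'].unique()}")
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    if not df["age"].between(AGE_MIN, AGE_MAX).all():
        raise ValidationError(f"{path}: ages outside {AGE_MIN}-{AGE_MAX}")
    return df


def write_initial_population(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_initial_population(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sex", "age", "count"], path)
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_entrants(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_entrants(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "sex", "entrants"], path)
    if (df["entrants"] < 0).any():
        raise ValidationError(f"{path}: negative entrant counts")
    return df


# ---------------------------------------------------------------------------
# transition tables

def write_transition_csv(table: TransitionTable, path: str) -> None:
    """Long-format export; probabilities at 10 significant digits."""
    df = table.to_frame()
    df["probability"] = df["probability"].map(lambda p: f"{p:.10g}")
    df.to_csv(path, index=False)


def read_transition_csv(path: str, row_sum_tol: float = 1e-6) -> TransitionTable:
    """Read and validate a long-format transition table."""
    df = pd.read_csv(path)
    _require_columns(df, ["scenario", "year", "sex", "age", "from_state",
                          "to_state", "probability"], path)
    for col in ("from_state", "to_state"):
        bad = df[~df[col].isin([s.name for s in HealthState])]
        if len(bad):
            raise ValidationError(f"{path}: unknown state names in {col}")
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        raise ValidationError(f"{path}: probabilities outside [0, 1]")

    scenario = df["scenario"].iloc[0]
    years = sorted(df["year"].unique().tolist())
    n_ages = AGE_MAX - AGE_MIN + 1
    P = np.zeros((len(years), 2, n_ages, N_STATES, N_STATES))
    yi = df["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    si = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
    ai = (df["age"] - AGE_MIN).to_numpy()
    fi = df["from_state"].map(lambda s: int(HealthState[s])).to_numpy()
    ti = df["to_state"].map(lambda s: int(HealthState[s])).to_numpy()
    P[yi, si, ai, fi, ti] = df["probability"].to_numpy(dtype=float)

    sums = P.sum(axis=-1)
    bad = np.abs(sums - 1.0) > row_sum_tol
    if bad.any():
        offenders = []
        for jy, js, ja, jf in zip(*np.nonzero(bad)):
            offenders.append(f"(year={years[jy]}, sex={SEXES[js]}, "
                             f"age={ja + AGE_MIN}, from={HealthState(jf).name}, "
                             f"sum={sums[jy, js, ja, jf]:.6f})")
            if len(offenders) >= 5:
                break
        raise ValidationError(
            f"{path}: {int(bad.sum())} rows violate sum-to-1: "
            + "; ".join(offenders))
    table = TransitionTable(scenario, years, P)
    return table


# ---------------------------------------------------------------------------
# parameters

def write_cost_parameters(params, path: str) -> None:
    params.to_frame().to_csv(path, index=False)


def read_deflators(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "index"], path)
    if (df["index"] <= 0).any():
        raise ValidationError(f"{path}: non-positive deflator index")
    return df


def write_deflators(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_historical_mortality(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cause", "sex", "age_mid", "year", "rate"], path)
    if (df["rate"] <= 0).any():
        raise ValidationError(f"{path}: non-positive rates")
    return df


def write_historical_mortality(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panel

_LIST_SEP = ";"


def write_panel(panel: pd.DataFrame, path: str) -> None:
    out = panel.copy()
    out["med_list"] = out["med_list"].map(lambda ml: _LIST_SEP.join(ml))
    out.to_csv(path, index=False)


def read_panel(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["pid", "wave", "age", "male", "state"], path)
    if "med_list" in df.columns:
        df["med_list"] = df["med_list"].fillna("").map(
            lambda s: s.split(_LIST_SEP) if s else [])
    return df


# ---------------------------------------------------------------------------
# run metadata

def write_metadata(path: str, config, input_paths: dict[str, str],
                   seed: int | None = None) -> None:
    """JSON sidecar: configuration, seed, input hashes, package version."""
    from . import __version__

    def _jsonable(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: _jsonable(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    meta = {
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "inputs": {name: {"path": p, "sha256": sha256_of(p)}
                   for name, p in input_paths.items() if os.path.exists(p)},
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
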