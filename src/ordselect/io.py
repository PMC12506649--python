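"""Delimited-text I/O for genotype matrices, ordinal phenotypes and configs.

All tables are plain text, comma- or tab-delimited (auto-detected on read):

* genotypes — header row of marker ids, first column line id, numeric
  dosage cells;
* phenotypes — header row of trait names, first column line id, integer
  category codes with ``NA`` (or empty) for missing;
* run configs — YAML mapping mirroring the dataclass field names.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_targets",
    "load_config",
    "write_manifest",
]

MISSING_TOKENS = {"NA", "NaN", "nan", ""}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") >= first.count("\t") else "\t"


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus data columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5].tolist()
        raise ValueError(f"{path}: duplicate line ids {dupes}")
    return df


def read_genotypes(path: Union[str, Path]) -> tuple:
    """Read a line-by-marker dosage matrix.

    Returns (X float array n x k, line ids list, marker ids list); rows and
    columns keep input order.  Missing or non-numeric cells raise with the
    offending row/column named.
    """
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = df.columns[1:].tolist()
    X = np.empty((len(ids), len(markers)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        vals = df[col]
        for i, v in enumerate(vals):
            if v in MISSING_TOKENS:
                raise ValueError(f"{path}: missing dosage at line {ids[i]!r}, marker {col!r}")
        try:
            X[:, j] = pd.to_numeric(vals, errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: non-numeric dosage at line {ids[bad]!r}, marker {col!r}"
            ) from None
    return X, ids, markers


def write_genotypes(path: Union[str, Path], X, ids=None, markers=None, sep: str = "\t") -> None:
    X = np.atleast_2d(np.asarray(X))
    n, k = X.shape
    ids = list(ids) if ids is not None else [f"line_{i + 1}" for i in range(n)]
    markers = list(markers) if markers is not None else [f"m{j + 1}" for j in range(k)]
    df = pd.DataFrame(X, columns=markers)
    df.insert(0, "id", ids)
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path: Union[str, Path], n_categories: Optional[Sequence[int]] = None) -> tuple:
    """Read ordinal phenotypes with optional missing entries.

    Returns (Y float array n x t with NaN for missing, line ids, trait
    names).  Codes must be integers >= 1; when ``n_categories`` is given
    each trait's codes are checked against its stated count, otherwise the
    counts are inferred from the observed maxima.
    """
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    traits = df.columns[1:].tolist()
    Y = np.full((len(ids), len(traits)), np.nan)
    for j, col in enumerate(traits):
        for i, v in enumerate(df[col]):
            if v in MISSING_TOKENS:
                continue
            try:
                num = float(v)
            except ValueError:
                raise ValueError(
                    f"{path}: unknown token {v!r} at line {ids[i]!r}, trait {col!r}"
                ) from None
            if num != int(num) or num < 1:
                raise ValueError(
                    f"{path}: invalid category code {v!r} at line {ids[i]!r}, trait {col!r} "
                    "(codes are integers starting at 1; use NA for missing)"
                )
            Y[i, j] = num
    if n_categories is not None:
        n_categories = list(n_categories)
        if len(n_categories) != len(traits):
            raise ValueError("n_categories must give one count per trait")
        for j, C in enumerate(n_categories):
            mx = np.nanmax(Y[:, j]) if np.any(np.isfinite(Y[:, j])) else 0
            if mx > C:
                raise ValueError(
                    f"{path}: trait {traits[j]!r} has code {int(mx)} > stated {C} categories"
                )
    return Y, ids, traits


def write_phenotypes(path: Union[str, Path], Y, ids=None, traits=None, sep: str = "\t") -> None:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, t = Y.shape
    ids = list(ids) if ids is not None else [f"line_{i + 1}" for i in range(n)]
    traits = list(traits) if traits is not None else [f"trait_{j + 1}" for j in range(t)]
    cells = np.where(np.isfinite(Y), Y, np.nan)
    df = pd.DataFrame(cells, columns=traits)
    df = df.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
    df.insert(0, "id", ids)
    df.to_csv(path, sep=sep, index=False)


def read_targets(path: Union[str, Path]):
    """Read per-trait target pmfs from YAML: either a list of lists or a
    mapping ``targets: [[...], ...]``."""
    from .divergence import TargetSpec

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("targets", data.get("target"))
    if data is None:
        raise ValueError(f"{path}: no 'targets' entry found")
    if np.ndim(data[0]) == 0:  # single trait given flat
        data = [data]
    return TargetSpec(tuple(np.asarray(t, float) for t in data))


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_manifest(out_dir: Union[str, Path], command: str, params: dict) -> Path:
    """Write a JSON run manifest (command, parameters, seeds, versions,
    timestamp) sufficient to reproduce the run."""
    import ordselect

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params": {k: (v if _jsonable(v) else repr(v)) for k, v in params.items()},
        "versions": {
            "ordselect": getattr(ordselect, "__version__", "unknown"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
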