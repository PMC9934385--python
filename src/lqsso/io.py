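"""Delimited-table input/output and run manifests."""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table", "write_coefficients",
           "write_metrics", "write_manifest"]

#: shortest round-trip float formatting for all table output
FLOAT_FORMAT = "%.17g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a numeric table as CSV with round-trip float precision."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table with a mandatory header row.

    The delimiter is sniffed from the extension ('.tsv' -> tab, else comma).
    Non-numeric cells raise with their row/column location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column names in {path}")
    bad = df.columns[~df.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"non-numeric value in {path} at row {row}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df[col].isna().idxmax())
        raise ValueError(f"missing value in {path} at row {row}, column {col!r}")
    return df


def write_coefficients(fit, path: str | Path, kkt=None) -> None:
    """Write a fit's coefficients (both scales) plus tuning metadata as CSV."""
    path = Path(path)
    p = fit.beta.shape[0]
    df = pd.DataFrame({
        "index": np.arange(p),
        "beta_standardized": fit.beta,
        "beta_original": fit.beta_original,
        "active": (fit.beta != 0).astype(int),
    })
    header = {
        "method": fit.method, "lambda": fit.lam, "tau": fit.tau,
        "gamma": fit.gamma, "q": fit.q, "intercept": fit.intercept,
        "objective": fit.objective, "converged": fit.converged,
        "n_iter": fit.n_iter,
    }
    if kkt is not None:
        header.update({"kkt_passed": kkt.passed,
                       "kkt_worst_active": kkt.worst_active,
                       "kkt_worst_inactive": kkt.worst_inactive})
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def write_metrics(records, path: str | Path) -> None:
    """Write MetricsRecords as a tidy CSV (one row per scenario cell/method)."""
    write_table(pd.DataFrame([r.to_dict() for r in records]), path)


def write_manifest(path: str | Path, config: dict, seed: int,
                   started: float) -> None:
    """Record the run configuration, seed, versions and wall time as JSON."""
    import lqsso

    manifest = {
        "config": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in config.items()},
        "seed": seed,
        "versions": {
            "lqsso": lqsso.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "wall_time_s": round(time.time() - started, 3),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
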