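"""CSV/JSON readers and writers for series, fits and power tables."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fit import FitResult
from .model import CountSeries, SegmentedDesign, build_design
from .power import PowerCell, PowerTable

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "write_power_outputs",
    "read_power_long",
    "fit_result_to_dict",
    "fit_result_from_dict",
]

NA_TOKEN = "-"


def read_series_csv(
    path,
    intervention_index: int | str = "auto",
    transform: str = "log",
    y0: int = 0,
    anchor: str = "transformed",
) -> CountSeries:
    """Load an observed series from a two-column table with header ``t,y``.

    The design is reconstructed from the row count plus the separately
    supplied intervention index and time transform; counts must parse as
    nonnegative integers.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "t" not in cols or "y" not in cols:
        raise ConfigError(f"series file {path} must have columns 't' and 'y'")
    df = df.sort_values(cols["t"])
    yf = df[cols["y"]].to_numpy()
    if np.any(~np.isfinite(yf.astype(float))) or np.any(yf.astype(float) < 0) or np.any(
        np.mod(yf.astype(float), 1) != 0
    ):
        raise ConfigError(f"counts in {path} must be nonnegative integers")
    design = build_design(len(df), transform, intervention_index, anchor)
    return CountSeries(design=design, y=yf.astype(np.int64), y0=y0)


def write_series_csv(series: CountSeries, path) -> None:
    """Write a simulated series with its covariates: columns t,T,X,D,mu,y."""
    d = series.design
    pd.DataFrame(
        {
            "t": np.arange(1, d.n + 1),
            "T": d.T,
            "X": d.X.astype(int),
            "D": d.D,
            "mu": series.mu if series.mu is not None else np.full(d.n, np.nan),
            "y": series.y,
        }
    ).to_csv(path, index=False)


def power_long_frame(table: PowerTable) -> pd.DataFrame:
    rows = []
    for i, g1 in enumerate(table.gamma1_grid):
        for j, n in enumerate(table.n_grid):
            c = table.cells[i][j]
            rows.append(
                {
                    "gamma1": g1,
                    "n": n,
                    "power": np.nan if c.power is None else c.power,
                    "n_generated": c.n_generated,
                    "n_converged": c.n_converged,
                    "n_rejected": c.n_rejected,
                    "status": c.status,
                }
            )
    return pd.DataFrame(rows)


def power_wide_frame(table: PowerTable) -> pd.DataFrame:
    """Human-readable layout: gamma1 first column, one column per n, NA as '-'.

    Powers are printed with 2 decimals to match the conventional table
    format; the long frame keeps full precision.
    """
    data = {"gamma1": table.gamma1_grid}
    for j, n in enumerate(table.n_grid):
        col = []
        for i in range(len(table.gamma1_grid)):
            c = table.cells[i][j]
            col.append(NA_TOKEN if c.power is None else f"{c.power:.2f}")
        data[str(n)] = col
    return pd.DataFrame(data)


def write_power_outputs(table: PowerTable, long_path, wide_path) -> None:
    power_long_frame(table).to_csv(long_path, index=False)
    power_wide_frame(table).to_csv(wide_path, index=False)


def read_power_long(path) -> pd.DataFrame:
    """Round-trip reader for the long-format power CSV."""
    return pd.read_csv(path)


def cells_from_long(df: pd.DataFrame) -> dict:
    """Reconstruct {(gamma1, n): PowerCell} from a long-format frame."""
    out = {}
    for _, row in df.iterrows():
        p = row["power"]
        out[(float(row["gamma1"]), int(row["n"]))] = PowerCell(
            power=None if (isinstance(p, float) and math.isnan(p)) else float(p),
            n_generated=int(row["n_generated"]),
            n_converged=int(row["n_converged"]),
            n_rejected=int(row["n_rejected"]),
            status=str(row["status"]),
        )
    return out


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "estimates": fit.estimates,
        "param_names": list(fit.param_names),
        "cov": None if fit.cov is None else np.asarray(fit.cov).tolist(),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "grad_norm": fit.grad_norm,
        "family": fit.family,
        "reason": fit.reason,
        "degenerate_init": fit.degenerate_init,
    }


def fit_result_from_dict(d: dict) -> FitResult:
    return FitResult(
        estimates=dict(d["estimates"]),
        param_names=list(d["param_names"]),
        cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
        loglik=float(d["loglik"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        grad_norm=float(d["grad_norm"]),
        family=str(d["family"]),
        reason=str(d.get("reason", "")),
        degenerate_init=bool(d.get("degenerate_init", False)),
    )


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))


def read_fit_json(path) -> FitResult:
    return fit_result_from_dict(json.loads(Path(path).read_text()))
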