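"""Readers and writers: plot CSV, model-spec JSON, fit JSON, comparison TSV.

Data files store only integer counts plus the per-plot sample size, never
proportions — the likelihood is defined on counts, and storing derived
proportions would invite rounding drift.  A missing census is simply an
absent row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood_fit import ComparisonTable, FitResult, PlotTimeSeries
from .popmodels import ModelSpec

__all__ = [
    "read_plots", "write_plots",
    "read_model", "write_model",
    "read_fit", "write_fit",
    "report_comparison", "read_comparison",
]

PLOT_COLUMNS = ["plot_id", "year", "count", "n_max"]


def read_plots(path) -> list[PlotTimeSeries]:
    """Read a plot CSV (columns plot_id, year, count, n_max) into series.

    Malformed rows are reported with their line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    errors = []
    for col in ("year", "count", "n_max"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals != np.floor(vals.fillna(0)))]
        errors += [f"line {i + 2}: non-integer {col} {df.loc[i, col]!r}" for i in bad]
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    over = df.index[df["count"] > df["n_max"]]
    errors += [f"line {i + 2}: count {df.loc[i, 'count']} exceeds n_max "
               f"{df.loc[i, 'n_max']}" for i in over]
    neg = df.index[df["count"] < 0]
    errors += [f"line {i + 2}: negative count" for i in neg]
    dup = df.duplicated(subset=["plot_id", "year"], keep=False)
    for i in df.index[dup]:
        errors.append(f"line {i + 2}: duplicate (plot_id, year) "
                      f"({df.loc[i, 'plot_id']}, {df.loc[i, 'year']})")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(sorted(set(errors))))
    plots = []
    for pid, grp in df.groupby("plot_id", sort=True):
        grp = grp.sort_values("year")
        n_max = grp["n_max"].unique()
        if len(n_max) != 1:
            raise ValueError(f"{path}: plot {pid} has inconsistent n_max {n_max}")
        plots.append(PlotTimeSeries(plot_id=str(pid),
                                    years=grp["year"].to_numpy(int),
                                    counts=grp["count"].to_numpy(int),
                                    n_max=int(n_max[0])))
    return plots


def write_plots(plots, path) -> None:
    """Write series to the plot CSV schema (long format, one row per census)."""
    rows = [(p.plot_id, int(y), int(c), p.n_max)
            for p in plots for y, c in zip(p.years, p.counts)]
    pd.DataFrame(rows, columns=PLOT_COLUMNS).to_csv(path, index=False)


def write_model(spec: ModelSpec, params: dict, path) -> None:
    """Serialise a model spec and its parameter values as JSON."""
    Path(path).write_text(json.dumps({"spec": spec.to_dict(), "params": params},
                                     indent=2) + "\n")


def read_model(path):
    d = json.loads(Path(path).read_text())
    return ModelSpec.from_dict(d["spec"]), {k: float(v) for k, v in d["params"].items()}


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def report_comparison(table: ComparisonTable, path=None, digits: int = 6) -> pd.DataFrame:
    """Render a comparison as TSV: one column per model, rows = parameters
    then -LL, k, AIC, dAIC, w_i, ER.  Fixed-a-priori values carry a ``*``.
    """
    universe: list[str] = []
    for spec in table.specs:
        for n in spec.param_names():
            if n not in universe:
                universe.append(n)
    cols = {}
    for i, (label, spec) in enumerate(zip(table.labels, table.specs)):
        fit = table.fits[i] if table.fits else None
        full = fit.full_params() if fit is not None else {}
        fixed = spec.fixed_values()
        col = {}
        for n in universe:
            if n not in spec.param_names():
                col[n] = ""
            elif n in fixed:
                col[n] = f"{fixed[n]:g}*"
            else:
                col[n] = f"{full.get(n, float('nan')):.{digits}g}"
        col["-LL"] = f"{table.neg_ll[i]:.{digits}g}"
        col["k"] = str(int(table.k[i]))
        col["AIC"] = f"{table.aic[i]:.{digits}g}"
        col["dAIC"] = f"{table.delta_aic[i]:.{digits}g}"
        col["w_i"] = f"{table.weights[i]:.{digits}g}"
        col["ER"] = f"{table.evidence_ratios[i]:.{digits}g}"
        col["supported"] = "yes" if table.supported[i] else "no"
        cols[label] = col
    df = pd.DataFrame(cols)
    df.index.name = "quantity"
    if path is not None:
        df.to_csv(path, sep="\t")
    return df


def read_comparison(path) -> pd.DataFrame:
    """Re-parse a comparison TSV; numeric cells become floats, ``*`` marks kept."""
    return pd.read_csv(path, sep="\t", index_col="quantity", dtype=str)
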