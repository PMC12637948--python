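"""Tabular dataset I/O and solution-pool serialization.

Dataset contract (long format, UTF-8 CSV, dot decimal separator):

* data table: columns ``dataset_id, time_min, value, value_type`` with
  ``value_type`` one of ``abs340, abs390, abs400, conc_mM``;
* setup table: columns ``dataset_id, species, initial_mM, enzyme_conc``.
  Rows with a non-null ``enzyme_conc`` assign an enzyme level to the named
  enzyme parameter (e.g. ``E_fdh``); other rows assign initial metabolite
  concentrations.

Spreadsheet workbooks (.xlsx) are accepted wherever a CSV is, one sheet per
series. Solution pools round-trip through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fit import FitSolution, SolutionPool
from .preprocess import (
    DEFAULT_PATHLENGTH_CM,
    Dataset,
    DatasetSeries,
    RawTrace,
    abs_to_conc,
)

__all__ = [
    "read_series",
    "write_series",
    "write_solutions",
    "read_solutions",
]

_VALUE_TYPES = {"abs340": 340, "abs390": 390, "abs400": 400, "conc_mM": None}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_series(
    data_path,
    setup_path,
    model_tag: str,
    pathlength: float = DEFAULT_PATHLENGTH_CM,
    kdq_range: Optional[tuple] = None,
) -> DatasetSeries:
    """Read a dataset series from a data table and a setup table."""
    data = _read_table(data_path)
    setup = _read_table(setup_path)
    for col in ("dataset_id", "time_min", "value", "value_type"):
        if col not in data.columns:
            raise ValueError(f"data table missing column {col!r}")
    for col in ("dataset_id", "species", "initial_mM", "enzyme_conc"):
        if col not in setup.columns:
            raise ValueError(f"setup table missing column {col!r}")
    dup = setup.duplicated(subset=["dataset_id", "species"])
    if dup.any():
        bad = setup.loc[dup, ["dataset_id", "species"]].values.tolist()
        raise ValueError(f"duplicated dataset_id/species rows in setup: {bad}")

    setups: dict = {}
    for row in setup.itertuples():
        entry = setups.setdefault(str(row.dataset_id), {"init": {}, "enzyme": {}})
        if pd.notna(row.enzyme_conc):
            entry["enzyme"][str(row.species)] = float(row.enzyme_conc)
        else:
            entry["init"][str(row.species)] = float(row.initial_mM)

    datasets = []
    for ds_id, grp in data.groupby("dataset_id", sort=False):
        ds_id = str(ds_id)
        if ds_id not in setups:
            raise ValueError(f"no setup rows for dataset {ds_id!r}")
        times = grp["time_min"].to_numpy(dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"non-monotone times in dataset {ds_id!r}")
        values = np.empty(len(grp))
        for i, (v, vt) in enumerate(zip(grp["value"], grp["value_type"])):
            if vt not in _VALUE_TYPES:
                raise ValueError(
                    f"unknown value_type {vt!r}; expected one of {sorted(_VALUE_TYPES)}"
                )
            wavelength = _VALUE_TYPES[vt]
            values[i] = float(v) if wavelength is None else abs_to_conc(
                float(v), wavelength, pathlength
            )
        datasets.append(
            Dataset(
                id=ds_id,
                trace=RawTrace(times=times, values=values),
                init=setups[ds_id]["init"],
                enzyme_conc=setups[ds_id]["enzyme"],
            )
        )
    return DatasetSeries(datasets=datasets, model_tag=model_tag, kdq_range=kdq_range)


def write_series(series: DatasetSeries, data_path, setup_path) -> None:
    """Write a series in the same tabular contract `read_series` consumes."""
    data_rows, setup_rows = [], []
    for ds in series:
        for t, v in zip(ds.trace.times, ds.trace.values):
            data_rows.append(
                {"dataset_id": ds.id, "time_min": t, "value": v,
                 "value_type": "conc_mM"}
            )
        for sid, conc in ds.init.items():
            setup_rows.append(
                {"dataset_id": ds.id, "species": sid, "initial_mM": conc,
                 "enzyme_conc": None}
            )
        for name, level in ds.enzyme_conc.items():
            setup_rows.append(
                {"dataset_id": ds.id, "species": name, "initial_mM": None,
                 "enzyme_conc": level}
            )
    pd.DataFrame(data_rows).to_csv(data_path, index=False)
    pd.DataFrame(setup_rows).to_csv(setup_path, index=False)


def write_solutions(pool: SolutionPool, path) -> None:
    """Serialize a solution pool (parameters, SSR, convergence, seeds) to JSON."""
    if not pool.solutions:
        raise ValueError("cannot write an empty solution pool")
    doc = {
        "solutions": [
            {
                "params": {k: float(v) for k, v in s.params.items()},
                "ssr": float(s.ssr) if np.isfinite(s.ssr) else None,
                "converged": bool(s.converged),
                "per_dataset_ssr": [float(x) for x in s.per_dataset_ssr],
                "start_index": int(s.start_index),
                "seed": int(s.seed),
            }
            for s in pool.solutions
        ],
    }
    if pool.converged:
        doc["best_ssr"] = float(pool.best.ssr)
        doc["best_params"] = {k: float(v) for k, v in pool.best.params.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def read_solutions(path) -> SolutionPool:
    with open(path) as fh:
        doc = json.load(fh)
    solutions = [
        FitSolution(
            params=d["params"],
            ssr=float("inf") if d["ssr"] is None else float(d["ssr"]),
            converged=bool(d["converged"]),
            per_dataset_ssr=list(d["per_dataset_ssr"]),
            start_index=int(d["start_index"]),
            seed=int(d["seed"]),
        )
        for d in doc["solutions"]
    ]
    return SolutionPool(solutions=solutions)
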