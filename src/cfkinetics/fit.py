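"""Kinetic parameter estimation from grouped NADH time courses.

The estimation contract is: minimize the sum of squared residuals (SSR)
between measured and predicted NADH, subject to implicit-Euler dynamics on
each dataset's measurement grid, parameter bounds, optional fixed ranges
(e.g. a pre-determined kdQ window), and an optional Haldane thermodynamic
constraint. `transcribe` exposes the discretized program (decision variables,
dynamics constraints, objective); the solver eliminates the state variables
by forward implicit-Euler simulation — single shooting — so the dynamics
constraints hold by construction and the program objective coincides with the
simulation SSR. Local solves use trust-region-reflective least squares over
log10-transformed parameters; the global strategy is randomized multi-start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .model import KineticModel, ThermoInfo, haldane_keq
from .preprocess import Dataset, DatasetSeries
from .simulate import NewtonError, simulate_trajectory

__all__ = [
    "HaldaneConfig",
    "FitProblem",
    "FitSolution",
    "SolutionPool",
    "TranscribedProblem",
    "ssr",
    "transcribe",
    "fit_kdq",
    "multistart_fit",
    "summarize_pool",
]

logger = logging.getLogger(__name__)

#: Default random-initialization / bound window for kinetic constants
#: (mM or 1/s scale); kinetic constants span orders of magnitude, so starts
#: are drawn log-uniformly.
DEFAULT_INIT_RANGE = (1e-4, 1e4)

#: Converged solutions within this factor of the best SSR form the
#: alternative-solution pool.
ALTERNATIVE_FACTOR = 1.1


def ssr(pred, meas, weights=None) -> float:
    """Weighted sum of squared residuals, mM^2. Default weights are all 1."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs meas {meas.shape}")
    r2 = (meas - pred) ** 2
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != pred.shape:
            raise ValueError("weights must match data length")
        r2 = w * r2
    return float(r2.sum())


@dataclass(frozen=True)
class HaldaneConfig:
    """Thermodynamic constraint on the BDH parameters.

    In ``equality`` mode the reverse turnover kcatr is eliminated,
    kcatr = kcatf*KMP*KMA / (Keq*KMS*KMQ), with Keq = exp(-dG0/(R*T)); the
    Haldane residual is then zero at solver precision. In ``band`` mode dG0
    becomes an additional decision variable bounded within +- dG0_sd.
    """

    thermo: ThermoInfo
    mode: str = "equality"  # "equality" | "band"

    def __post_init__(self) -> None:
        if self.mode not in ("equality", "band"):
            raise ValueError(f"unknown Haldane mode {self.mode!r}")


@dataclass
class FitProblem:
    """A dataset series plus model and solver configuration."""

    series: DatasetSeries
    model: KineticModel
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)  # name -> value, held constant
    fixed_ranges: dict = field(default_factory=dict)  # name -> (lo, hi)
    haldane: Optional[HaldaneConfig] = None
    weights: Optional[dict] = None  # dataset id -> per-point weights
    n_starts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        merged = dict(self.model.bounds)
        merged.update(self.bounds)
        for name, (lo, hi) in self.fixed_ranges.items():
            if lo > hi:
                raise ValueError(f"fixed range for {name} is empty: ({lo}, {hi})")
            merged[name] = (lo, hi)
        for name, (lo, hi) in merged.items():
            if lo < 0:
                raise ValueError(f"bounds must be non-negative, got {name}: {lo}")
        self.bounds = merged

    # -- free-parameter bookkeeping ---------------------------------------
    def free_names(self) -> list:
        """Fit parameters: bounded names minus fixed, minus eliminated kcatr."""
        names = [n for n in self.bounds if n not in self.fixed]
        if self.haldane is not None and self.haldane.mode == "equality":
            names = [n for n in names if n != "kcatr"]
        return sorted(names)

    def full_params(self, free: Mapping[str, float],
                    dg0: Optional[float] = None) -> dict:
        """Complete parameter vector from free values + fixed + elimination."""
        params = dict(self.model.params)
        params.update(self.fixed)
        params.update(free)
        if self.haldane is not None:
            th = self.haldane.thermo
            if dg0 is None:
                dg0 = th.dG0
            keq = haldane_keq(ThermoInfo(dG0=dg0, T=th.T, R=th.R))
            params["kcatr"] = (
                params["kcatf"] * params["KMP"] * params["KMA"]
                / (keq * params["KMS"] * params["KMQ"])
            )
        return params


@dataclass
class FitSolution:
    """One converged (or failed) local solve."""

    params: dict
    ssr: float
    converged: bool
    per_dataset_ssr: list
    start_index: int
    seed: int

    def __post_init__(self) -> None:
        if self.converged and not (np.isfinite(self.ssr) and self.ssr >= 0):
            raise ValueError("converged solutions must have finite non-negative SSR")


@dataclass
class SolutionPool:
    """Multi-start results with best/alternative partition."""

    solutions: list

    @property
    def converged(self) -> list:
        return [s for s in self.solutions if s.converged]

    @property
    def best(self) -> FitSolution:
        conv = self.converged
        if not conv:
            raise RuntimeError("no converged solutions in pool")
        return min(conv, key=lambda s: s.ssr)

    @property
    def alternatives(self) -> list:
        """Converged solutions with SSR within 10% of the best (includes best)."""
        best = self.best
        return [s for s in self.converged if s.ssr <= ALTERNATIVE_FACTOR * best.ssr]

    @property
    def convergence_fraction(self) -> float:
        return len(self.converged) / len(self.solutions)


# ---------------------------------------------------------------------------
# Prediction on measurement grids
# ---------------------------------------------------------------------------


def _dataset_grid(dataset: Dataset) -> tuple:
    """(simulation grid, indices of measurement times within it).

    The grid is the dataset's measurement times on the model clock, with the
    reaction start t=0 prepended when the first measurement is later (a
    nonzero lag or a trimmed trace).
    """
    times = dataset.model_times()
    if times[0] > 0:
        grid = np.concatenate([[0.0], times])
        idx = np.arange(1, len(grid))
    else:
        grid = times
        idx = np.arange(len(grid))
    return grid, idx


def _initial_state(dataset: Dataset, model: KineticModel) -> np.ndarray:
    x0 = np.zeros(len(model.species_ids))
    for sid, conc in dataset.init.items():
        if sid in model.species_ids:
            x0[model.index_of(sid)] = conc
    return x0


def predict_dataset(model: KineticModel, params: Mapping[str, float],
                    dataset: Dataset) -> np.ndarray:
    """Implicit-Euler prediction of the observed species at measurement times."""
    full = dict(params)
    full.update(dataset.enzyme_conc)
    grid, idx = _dataset_grid(dataset)
    x0 = _initial_state(dataset, model)
    traj = simulate_trajectory(model, full, x0, grid)
    return traj[dataset.observed][idx]


def _residuals(problem: FitProblem, params: Mapping[str, float]) -> np.ndarray:
    parts = []
    for ds in problem.series:
        pred = predict_dataset(problem.model, params, ds)
        r = pred - ds.trace.values
        if problem.weights is not None and ds.id in problem.weights:
            r = r * np.sqrt(np.asarray(problem.weights[ds.id], dtype=float))
        parts.append(r)
    return np.concatenate(parts)


def problem_ssr(problem: FitProblem, params: Mapping[str, float]) -> float:
    """Total SSR of a full parameter vector over the series."""
    return float((_residuals(problem, params) ** 2).sum())


# ---------------------------------------------------------------------------
# Transcription
# ---------------------------------------------------------------------------


@dataclass
class TranscribedProblem:
    """The discretized program behind the fit.

    Decision variables are the kinetic parameters plus, per dataset, the
    state trajectory at every grid point; equality constraints enforce the
    implicit-Euler recurrence on each interval and pin the initial state; the
    objective is the total SSR. `eliminate_states` performs the single-
    shooting state elimination used by the solver: for any parameter vector
    it returns states satisfying the dynamics constraints, at which point the
    objective equals the plain simulation SSR.
    """

    problem: FitProblem
    n_parameters: int
    n_state_variables: int
    n_dynamics_constraints: int
    per_dataset_shapes: list  # (n_times, n_species) per dataset

    def constraint_residuals(self, params: Mapping[str, float],
                             states: Sequence[np.ndarray]) -> np.ndarray:
        """Implicit-Euler defect x_{j+1} - x_j - dt*f(t_{j+1}, x_{j+1})."""
        from .model import assemble_rhs

        out = []
        for ds, st in zip(self.problem.series, states):
            full = dict(params)
            full.update(ds.enzyme_conc)
            rhs = assemble_rhs(self.problem.model, full)
            grid, _ = _dataset_grid(ds)
            for j in range(len(grid) - 1):
                dt = grid[j + 1] - grid[j]
                out.append(st[j + 1] - st[j] - dt * rhs(grid[j + 1], st[j + 1]))
        return np.concatenate(out)

    def eliminate_states(self, params: Mapping[str, float]) -> list:
        states = []
        for ds in self.problem.series:
            full = dict(params)
            full.update(ds.enzyme_conc)
            grid, _ = _dataset_grid(ds)
            x0 = _initial_state(ds, self.problem.model)
            traj = simulate_trajectory(self.problem.model, full, x0, grid)
            states.append(traj.states)
        return states

    def objective(self, params: Mapping[str, float],
                  states: Sequence[np.ndarray]) -> float:
        total = 0.0
        obs_idx = self.problem.model.index_of
        for ds, st in zip(self.problem.series, states):
            _, idx = _dataset_grid(ds)
            pred = st[idx, obs_idx(ds.observed)]
            w = None
            if self.problem.weights is not None:
                w = self.problem.weights.get(ds.id)
            total += ssr(pred, ds.trace.values, w)
        return total


def transcribe(problem: FitProblem) -> TranscribedProblem:
    """Build the discretized nonlinear program for a fit problem."""
    n_species = len(problem.model.species_ids)
    shapes, n_states, n_dyn = [], 0, 0
    for ds in problem.series:
        grid, _ = _dataset_grid(ds)
        shapes.append((len(grid), n_species))
        n_states += len(grid) * n_species
        n_dyn += (len(grid) - 1) * n_species
    return TranscribedProblem(
        problem=problem,
        n_parameters=len(problem.free_names()),
        n_state_variables=n_states,
        n_dynamics_constraints=n_dyn,
        per_dataset_shapes=shapes,
    )


# ---------------------------------------------------------------------------
# kdQ pre-fitting from decomposition standards
# ---------------------------------------------------------------------------


def _fit_single_decay(times: np.ndarray, values: np.ndarray) -> float:
    """First-order decay constant (1/min) of a single Q(t)=Q0*exp(-k t) trace.

    Log-linear regression when all values are positive; nonlinear fallback
    otherwise.
    """
    if np.all(values > 0):
        slope, _ = np.polyfit(times, np.log(values), 1)
        return max(-float(slope), 0.0)
    mask = values > 0
    if mask.sum() < 2:
        raise ValueError("decomposition standard has fewer than 2 positive points")
    q0 = float(values[mask][0]) if values[0] <= 0 else float(values[0])
    popt, _ = curve_fit(
        lambda t, q0, k: q0 * np.exp(-k * t),
        times, values, p0=[max(q0, 1e-6), 1e-3],
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
    )
    return float(popt[1])


def fit_kdq(standards: DatasetSeries) -> tuple:
    """Fit kdQ to each NADH-decomposition standard; return (min, max) in 1/min.

    Standards are Q-only chemistry: the model reduces to dQ/dt = -kdQ*Q with
    closed form Q(t) = Q0*exp(-kdQ*t).
    """
    rates = []
    for ds in standards:
        t = ds.model_times()
        rates.append(_fit_single_decay(t - t[0], ds.trace.values))
    return (min(rates), max(rates))


# ---------------------------------------------------------------------------
# Multi-start fitting
# ---------------------------------------------------------------------------


def _solve_one(problem: FitProblem, start_index: int) -> FitSolution:
    names = problem.free_names()
    seed = problem.seed + start_index
    rng = np.random.default_rng(seed)

    # per-parameter log10 bounds; zero lower bounds are floored for the
    # log transform (the transform requires positivity)
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, n in enumerate(names):
        b_lo, b_hi = problem.bounds[n]
        lo[i] = math.log10(max(b_lo, 1e-12))
        hi[i] = math.log10(b_hi)
    band = problem.haldane is not None and problem.haldane.mode == "band"
    if band:
        th = problem.haldane.thermo
        lo = np.append(lo, th.dG0 - th.dG0_sd)
        hi = np.append(hi, th.dG0 + th.dG0_sd)

    # log-uniform start within the default window intersected with bounds
    x0 = np.empty(len(lo))
    for i in range(len(names)):
        a = max(lo[i], math.log10(DEFAULT_INIT_RANGE[0]))
        b = min(hi[i], math.log10(DEFAULT_INIT_RANGE[1]))
        if a > b:
            a, b = lo[i], hi[i]
        x0[i] = rng.uniform(a, b)
    if band:
        x0[-1] = rng.uniform(lo[-1], hi[-1])

    def unpack(x: np.ndarray):
        free = {n: 10.0 ** x[i] for i, n in enumerate(names)}
        dg0 = float(x[-1]) if band else None
        return problem.full_params(free, dg0=dg0)

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            return _residuals(problem, unpack(x))
        except (NewtonError, ValueError):
            # infeasible corner of parameter space: return a large residual
            n_pts = sum(len(ds.trace) for ds in problem.series)
            return np.full(n_pts, 1e6)

    try:
        result = least_squares(
            fun, x0, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
        )
        params = unpack(result.x)
        per_ds = [
            ssr(predict_dataset(problem.model, {**params, **ds.enzyme_conc}, ds),
                ds.trace.values)
            for ds in problem.series
        ]
        total = float(sum(per_ds))
        converged = bool(result.success) and np.isfinite(total) and total < 1e12
        sol = FitSolution(
            params=params, ssr=total, converged=converged,
            per_dataset_ssr=per_ds, start_index=start_index, seed=seed,
        )
    except (NewtonError, ValueError, RuntimeError) as exc:
        logger.warning("start %d failed: %s", start_index, exc)
        sol = FitSolution(
            params={}, ssr=float("inf"), converged=False,
            per_dataset_ssr=[], start_index=start_index, seed=seed,
        )
    logger.info(
        "start %d: ssr=%.6g converged=%s", start_index, sol.ssr, sol.converged
    )
    return sol


def multistart_fit(problem: FitProblem) -> SolutionPool:
    """Randomized multi-start local fitting; returns the solution pool.

    Start ``i`` draws its initial parameter vector log-uniformly within the
    bounds using seed ``problem.seed + i``, so runs are reproducible and the
    best SSR over the first n starts is non-increasing in n.
    """
    solutions = [_solve_one(problem, i) for i in range(problem.n_starts)]
    pool = SolutionPool(solutions=solutions)
    if not pool.converged:
        raise RuntimeError(
            f"all {problem.n_starts} starts failed; last SSRs: "
            f"{[s.ssr for s in solutions[-3:]]}"
        )
    return pool


def summarize_pool(pool: SolutionPool) -> dict:
    """Per-parameter mean, sample std, and CoV over best + alternatives."""
    members = pool.alternatives
    if not members:
        raise RuntimeError("no converged solutions to summarize")
    names = sorted(members[0].params)
    out = {}
    for n in names:
        vals = np.array([m.params[n] for m in members], dtype=float)
        mean = float(vals.mean())
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[n] = {
            "mean": mean,
            "std": std,
            "cov": std / mean if mean != 0 else float("nan"),
            "n": len(vals),
        }
    return out
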