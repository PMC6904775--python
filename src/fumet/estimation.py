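"""Weighted-least-squares parameter estimation by Hooke–Jeeves pattern search.

The fitting protocol mirrors the study design: a derivative-free Hooke–Jeeves
search (iteration limit 50, tolerance 1e-5, step-shrink factor rho = 0.2,
standard-deviation weighting) is first used to pre-minimize the objective
below 0.15, then consecutive attempts are chained — each starting from the
previous adjustment — until the objective changes by less than 1e-6 between
attempts.  The five most accurate attempts are retained and summarized per
parameter as best-fit value (bfv), attempt average (avg), sample standard
deviation (stds) and |bfv − avg|/stds (dev_stds).

Parameters are searched in log10 space (the fitted constants span many
orders of magnitude), with bounds defaulting to ±3 decades around the start.

Weighting: each series' residuals are divided by the standard deviation of
the observed series, and the resulting per-series weights are normalized so
the largest is 1 ("scaled standard-deviation weights"):
``objective = Σ_s w_s Σ_t (model_st − obs_st)²`` with ``w_s ∝ 1/sd_s²``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .simulator import ATPModel, simulate

__all__ = ["FitProtocol", "FitResult", "HookeJeevesResult", "TimecourseObjective",
           "hooke_jeeves", "multistart_fit", "fit_quality_r2"]


@dataclass(frozen=True)
class FitProtocol:
    """Staged pattern-search protocol settings."""

    iteration_limit: int = 50
    tolerance: float = 1e-5
    rho: float = 0.2
    step0: float = 0.5                    # initial pattern step, log10 decades
    preminimization_threshold: float = 0.15
    convergence_threshold: float = 1e-6   # objective variation between attempts
    n_best_attempts: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")
        for name in ("tolerance", "step0", "preminimization_threshold",
                     "convergence_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HookeJeevesResult:
    x: np.ndarray
    fx: float
    n_iterations: int
    n_evaluations: int
    converged: bool           # pattern step shrank below tolerance
    at_bounds: np.ndarray     # per-coordinate flag: optimum on a bound


def hooke_jeeves(f, x0, bounds=None, *, rho: float = 0.2, tol: float = 1e-5,
                 it_lim: int = 50, step0: float = 0.5) -> HookeJeevesResult:
    """Hooke–Jeeves pattern search: exploratory + pattern moves, step shrink.

    Deterministic given ``x0``; returns a point no worse than the start.
    Terminates when the exploratory step falls below ``tol`` or after
    ``it_lim`` iterations.  Bounds are enforced by clipping every probe.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    if bounds is None:
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
    else:
        lo = np.asarray([b[0] for b in bounds], dtype=float)
        hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("x0 must lie within bounds")

    n_eval = 0

    def feval(x):
        nonlocal n_eval
        n_eval += 1
        return float(f(x))

    fb = feval(x0)
    if not np.isfinite(fb):
        raise ValueError(f"objective is not finite at the start point: {fb}")

    def explore(base, fbase, step):
        x = base.copy()
        fx = fbase
        for i in range(n):
            for delta in (step, -step):
                xi = min(max(x[i] + delta, lo[i]), hi[i])
                if xi == x[i]:
                    continue
                trial = x.copy()
                trial[i] = xi
                ft = feval(trial)
                if np.isfinite(ft) and ft < fx:
                    x, fx = trial, ft
                    break
        return x, fx

    base, fbase = x0.copy(), fb
    step = float(step0)
    it = 0
    converged = False
    while it < it_lim:
        it += 1
        new, fnew = explore(base, fbase, step)
        if fnew < fbase:
            # pattern move: extrapolate along the successful direction
            while True:
                cand = np.clip(new + (new - base), lo, hi)
                base, fbase = new, fnew
                cand_x, cand_f = explore(cand, feval(cand), step)
                if np.isfinite(cand_f) and cand_f < fbase:
                    new, fnew = cand_x, cand_f
                else:
                    break
        else:
            step *= rho
            if step < tol:
                converged = True
                break
    at_bounds = (base <= lo + tol) | (base >= hi - tol)
    return HookeJeevesResult(base, fbase, it, n_eval, converged, at_bounds)


class TimecourseObjective:
    """Weighted least squares between simulated observables and a data table.

    ``data`` is indexed by time (hours) with columns drawn from the network's
    observable groups (plus optionally ``totalF`` and ``atp_rel``).  Free
    parameters are (param_group, name) registry keys and/or ("init", species)
    initial concentrations, searched in log10 space.
    """

    def __init__(self, net: ReactionNetwork, data: pd.DataFrame,
                 free_parameters, atp_model: ATPModel | None = None,
                 weights: dict[str, float] | None = None,
                 sim_rtol: float = 1e-8, sim_atol: float = 1e-9):
        self.net = net
        self.data = data.sort_index()
        if np.any(self.data.index < 0):
            raise ValueError("observation times must be >= 0")
        self.free_parameters = list(free_parameters)
        self.atp_model = atp_model
        self.sim_rtol = sim_rtol
        self.sim_atol = sim_atol
        self._series = [c for c in self.data.columns if c != "atp_rel"]
        if weights is None:
            # sd floored at 5% of the series' scale so a (near-)constant
            # series — e.g. total fluorine, constant by conservation up to
            # integrator noise — cannot dominate the objective
            sds = {}
            for c in self._series + (["atp_rel"] if "atp_rel" in data.columns else []):
                col = self.data[c].to_numpy(dtype=float)
                scale = float(np.abs(col).max())
                sds[c] = max(float(np.std(col, ddof=1)), 0.05 * scale, 1e-12)
            wmax = max(1.0 / sd ** 2 for sd in sds.values())
            weights = {c: (1.0 / sd ** 2) / wmax for c, sd in sds.items()}
        self.weights = weights
        # simulation grid: t=0 start plus all observation times
        tobs = np.asarray(self.data.index, dtype=float)
        self._t_grid = np.unique(np.concatenate([[0.0], tobs]))
        self._obs_rows = np.searchsorted(self._t_grid, tobs)

    # -- parameter vector <-> registry ------------------------------------
    def current_x(self) -> np.ndarray:
        vals = []
        for key in self.free_parameters:
            if key[0] == "init":
                v = self.net.species[self.net.species_index(key[1])].initial_conc
            else:
                v = self.net.registry.get(*key)
            vals.append(np.log10(max(v, 1e-300)))
        return np.array(vals)

    def set_params(self, x: np.ndarray) -> None:
        for key, xi in zip(self.free_parameters, x):
            value = 10.0 ** float(xi)
            if key[0] == "init":
                self.net.set_initial(key[1], value)
            else:
                self.net.registry.set(*key, value)

    def predict(self, x: np.ndarray | None = None) -> pd.DataFrame:
        if x is not None:
            self.set_params(x)
        traj = simulate(self.net, None, self._t_grid, self.atp_model,
                        rtol=self.sim_rtol, atol=self.sim_atol)
        obs = traj.observables().iloc[self._obs_rows]
        out = obs[[c for c in self._series]]
        if "atp_rel" in self.data.columns:
            if self.atp_model is not None:
                rel = self.atp_model.relative(np.asarray(self.data.index))
            else:
                rel = np.ones(len(self.data))
            out = out.assign(atp_rel=rel)
        out.index = self.data.index
        return out

    def __call__(self, x: np.ndarray) -> float:
        try:
            pred = self.predict(x)
        except (RuntimeError, ValueError, OverflowError) as exc:
            warnings.warn(f"simulation failed during fitting ({exc}); "
                          "objective set to +inf")
            return np.inf
        total = 0.0
        for c in self.data.columns:
            r = pred[c].to_numpy() - self.data[c].to_numpy()
            total += self.weights[c] * float(r @ r)
        return total


@dataclass
class FitResult:
    """Best-fit values with chained-attempt statistics."""

    parameter_names: list
    bfv: np.ndarray            # log10-space best-fit vector's linear values
    avg: np.ndarray
    stds: np.ndarray
    dev_stds: np.ndarray
    objective_value: float
    attempts: list = field(default_factory=list)   # objective per attempt
    n_retained: int = 0
    seed: int | None = None
    bounds: list | None = None
    converged: bool = True
    message: str = ""

    def as_frame(self) -> pd.DataFrame:
        names = ["/".join(map(str, k)) for k in self.parameter_names]
        return pd.DataFrame({"bfv": self.bfv, "avg": self.avg,
                             "stds": self.stds, "dev_stds": self.dev_stds},
                            index=names)

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "/".join(map(str, k)): {"bfv": float(b), "avg": float(a),
                                        "stds": float(s), "dev_stds": float(d)}
                for k, b, a, s, d in zip(self.parameter_names, self.bfv,
                                         self.avg, self.stds, self.dev_stds)
            },
            "objective_value": float(self.objective_value),
            "attempts": [float(a) for a in self.attempts],
            "n_retained": int(self.n_retained),
            "seed": self.seed,
            "bounds": self.bounds,
            "converged": bool(self.converged),
            "message": self.message,
        }


def multistart_fit(objective, protocol: FitProtocol | None = None, *,
                   n_attempts: int = 20, seed: int | None = None,
                   bounds_decades: float = 3.0, start: np.ndarray | None = None,
                   bounds=None) -> FitResult:
    """Chained Hooke–Jeeves attempts with the staged study protocol.

    Stage 1 pre-minimizes the objective below the 0.15 threshold; stage 2
    chains further attempts, each starting from the previous adjustment,
    until the attempt-to-attempt objective variation drops below 1e-6.
    The five most accurate attempts feed the per-parameter statistics.
    Fully reproducible from ``seed`` (used only to draw the start point when
    none is given).
    """
    protocol = protocol or FitProtocol()
    if n_attempts < protocol.n_best_attempts:
        raise ValueError("n_attempts must be >= protocol.n_best_attempts")
    x_now = objective.current_x() if start is None else np.asarray(start, float)
    if bounds is None:
        bounds = [(x - bounds_decades, x + bounds_decades) for x in x_now]
    if start is None and seed is not None:
        rng = np.random.default_rng(seed)
        x_now = np.array([rng.uniform(lo, hi) for lo, hi in bounds])

    attempts: list[tuple[np.ndarray, float]] = []

    def run_attempt(x):
        res = hooke_jeeves(objective, x, bounds, rho=protocol.rho,
                           tol=protocol.tolerance, it_lim=protocol.iteration_limit,
                           step0=protocol.step0)
        attempts.append((res.x, res.fx))
        return res.x, res.fx

    # stage 1: pre-minimization below the threshold
    x_now, f_now = run_attempt(x_now)
    pre_budget = n_attempts
    while f_now >= protocol.preminimization_threshold and len(attempts) < pre_budget:
        x_now, f_now = run_attempt(x_now)
    premin_ok = f_now < protocol.preminimization_threshold
    if not premin_ok:
        warnings.warn(
            f"pre-minimization did not reach {protocol.preminimization_threshold} "
            f"(objective {f_now:.4g} after {len(attempts)} attempts)")

    # stage 2: chained refinement until the objective stabilizes
    converged = False
    while len(attempts) < n_attempts:
        x_new, f_new = run_attempt(x_now)
        variation = abs(f_now - f_new)
        x_now, f_now = x_new, f_new
        if variation < protocol.convergence_threshold:
            converged = True
            break

    order = np.argsort([f for _, f in attempts], kind="stable")
    retained = [attempts[i] for i in order[:protocol.n_best_attempts]]
    if len(retained) < protocol.n_best_attempts:
        warnings.warn(f"only {len(retained)} attempts available for statistics")

    X = np.array([10.0 ** x for x, _ in retained])   # linear-space values
    bfv = X[0]
    avg = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(bfv.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(bfv - avg)
        dev_stds = np.where(stds > 0, dev / np.where(stds > 0, stds, 1.0), 0.0)

    msg = "" if (premin_ok and converged) else (
        "pre-minimization threshold not reached; " if not premin_ok else ""
    ) + ("" if converged else "attempt variation did not stabilize")
    objective.set_params(np.log10(bfv))  # leave the model at the best fit
    return FitResult(list(objective.free_parameters), bfv, avg, stds, dev_stds,
                     objective_value=retained[0][1],
                     attempts=[float(f) for _, f in attempts],
                     n_retained=len(retained), seed=seed,
                     bounds=[list(map(float, b)) for b in bounds],
                     converged=premin_ok and converged, message=msg)


def fit_quality_r2(objective: TimecourseObjective, x: np.ndarray | None = None
                   ) -> float:
    """Coefficient of determination of pooled predicted-vs-observed values."""
    pred = objective.predict(x)
    p = np.concatenate([pred[c].to_numpy() for c in objective.data.columns])
    o = np.concatenate([objective.data[c].to_numpy() for c in objective.data.columns])
    ss_res = float(((p - o) ** 2).sum())
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observed data have zero variance; R² undefined")
    return 1.0 - ss_res / ss_tot
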