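"""Synthetic study-shaped data: ¹⁹F time courses, ³¹P ATP curves, dose tables.

The generators emulate the shape of the NMR observables the model is fitted
to — 17 hourly samples (1–17 h; t = 0 is unobserved) of the six
¹⁹F-indistinguishable concentration groups normalized to 1 mM total
fluorine, a relative ³¹P ATP curve starting at 1 and collapsing within a few
hours, and dose–survival tables with five replicates per dose — so every
pipeline stage is testable without any experimental download.  Noise is
relative Gaussian per point (default 5%, the order of the integration error
of a 1-h, 488-scan spectrum); every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import hill_survival
from .network import ReactionNetwork, build_network
from .simulator import ATPModel, simulate

__all__ = ["SyntheticConfig", "generate_time_course", "generate_atp_curve",
           "generate_dose_survival"]


@dataclass
class SyntheticConfig:
    """Settings for the time-course generator.

    Defaults are the study conditions: the published best-fit parameter set
    (carried by ``network``), hourly sampling over 1–17 h, 5% relative
    Gaussian noise, forced-ATP mode.  A seed is mandatory whenever
    ``noise_sd > 0``.
    """

    network: ReactionNetwork | None = None
    atp_model: ATPModel = field(default_factory=ATPModel)
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 17.0 + 1e-9, 1.0))
    noise_sd: float = 0.05          # relative sd per observable point
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for noisy output")
        if self.network is None:
            self.network = build_network()


def generate_time_course(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate, group into observables, add noise.

    Returns ``(observed, truth)``: the observed table is indexed by time
    (hours) with the six observable-group columns plus ``atp_rel``; the
    ground-truth record holds the noiseless table, the generating parameters
    and initial concentrations, for recovery tests.  The noiseless track
    conserves total fluorine exactly (to integrator tolerance).
    """
    net = cfg.network
    t = np.asarray(cfg.t_grid, dtype=float)
    traj = simulate(net, None, np.unique(np.concatenate([[0.0], t])),
                    cfg.atp_model)
    obs = traj.observables()
    noiseless = obs.loc[obs.index.isin(t)].copy()
    noiseless["atp_rel"] = cfg.atp_model.relative(noiseless.index.to_numpy())

    observed = noiseless.copy()
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0.0, cfg.noise_sd, size=observed.shape)
        observed = observed * (1.0 + noise)
        observed = observed.clip(lower=0.0)

    truth = {
        "noiseless": noiseless,
        "parameters": {f"{g}/{n}": v
                       for (g, n), v in net.registry.entries().items()},
        "initial_concentrations": {s.id: s.initial_conc for s in net.species},
        "atp_model": {"mode": cfg.atp_model.mode, "t_half": cfg.atp_model.t_half,
                      "shape": cfg.atp_model.shape},
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return observed, truth


def generate_atp_curve(cfg: SyntheticConfig, t_grid=None,
                       noise_sd: float = 0.0) -> pd.Series:
    """Relative ³¹P ATP level on ``t_grid`` (defaults to 0–17 h hourly).

    The noiseless curve is the forced decay: ATP(0) = 1, at most 0.5 by the
    half-time (1 h) and below 0.05 by 4 h under the default shape, and
    non-increasing everywhere.  Optional relative noise is applied only for
    t > 0 (the t = 0 anchor is the normalization point).
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 17.0 + 1e-9, 1.0)
    t = np.asarray(t_grid, dtype=float)
    rel = cfg.atp_model.relative(t)
    if noise_sd > 0:
        if cfg.seed is None:
            raise ValueError("a seed is mandatory for noisy output")
        rng = np.random.default_rng(cfg.seed)
        rel = np.where(t > 0,
                       np.clip(rel * (1 + rng.normal(0, noise_sd, t.shape)), 0, None),
                       rel)
    return pd.Series(rel, index=pd.Index(t, name="time"), name="atp_rel")


def generate_dose_survival(ec50: float, hill: float, doses, *,
                           replicates: int = 5, noise_sd: float = 0.1,
                           seed: int | None = None) -> pd.DataFrame:
    """Replicate survival table drawn around the Hill dose–survival curve.

    ``doses`` in µM (> 0); five replicates per dose by default (the study's
    repetition count) with relative Gaussian noise, truncated to [0, 100]%.
    Columns: dose_um, replicate, survival_pct.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is mandatory for noisy output")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mu = hill_survival(d, ec50, hill)
        for r in range(replicates):
            val = mu if noise_sd == 0 else mu * (1 + rng.normal(0, noise_sd))
            rows.append({"dose_um": d, "replicate": r + 1,
                         "survival_pct": float(np.clip(val, 0.0, 100.0))})
    return pd.DataFrame(rows)
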