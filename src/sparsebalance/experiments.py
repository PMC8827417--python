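"""Parameter sweeps over the in-degree K, power-law fits, and input-response curves.

These orchestrate the connectivity / dynamics / stats / gamma_theory modules
into the tables used to establish the regime's signature scalings: mean
response and sparsity ~ 1/sqrt(K), decorrelation rate beta ~ log K,
nonlinear population response to the bias current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import gamma_theory
from .connectivity import WeightSpec, sample_weights
from .dynamics import Nonlinearity, SimulationConfig, simulate
from .stats import summarize

__all__ = ["SweepConfig", "FitResult", "run_scaling_sweep", "fit_power_law",
           "input_response_curve", "STAT_COLUMNS"]

# fixed column order of the statistics table
STAT_COLUMNS = [
    "K", "N", "family", "nu", "J0", "g", "I0", "phi_kind", "lam", "seed",
    "phi_bar", "f", "mu", "x_bar", "var_t_x", "var_q_x", "var_t_eta",
    "var_q_eta", "tau_eta", "beta", "chi", "psi", "sync",
]


@dataclass(frozen=True)
class SweepConfig:
    """A K-sweep at fixed distribution family and dynamics settings.

    ``N = K`` for every point unless ``N_of_K`` overrides it. Default grid
    spans one decade (needed for a meaningful log-log fit).
    """

    K_grid: tuple[int, ...] = (250, 500, 1000, 2000, 4000)
    n_seeds: int = 3
    family: str = "gamma"
    J0: float = 2.0
    g: float = 2.0
    nu: float = 0.5
    I0: float = 1.0
    nl: Nonlinearity = field(default_factory=lambda: Nonlinearity("rect_tanh"))
    dt: float = 0.05
    T: float = 600.0
    burn_in: float = 100.0
    record_stride: int = 2
    base_seed: int = 0
    dtype: type = np.float32
    max_lag: float = 20.0

    def __post_init__(self) -> None:
        if len(self.K_grid) < 3:
            raise ValueError("need >= 3 K values for exponent fits")
        if max(self.K_grid) < 10 * min(self.K_grid):
            raise ValueError("K grid should span at least one decade")


@dataclass(frozen=True)
class FitResult:
    """OLS power-law fit of y ~ K^(-exponent) on log-log axes."""

    exponent: float
    intercept: float
    r_squared: float
    stderr: float


def _run_seeds(K: int, cfg: SweepConfig) -> list[dict]:
    spec = WeightSpec(family=cfg.family, J0=cfg.J0, g=cfg.g, nu=cfg.nu, K=K, N=K)
    rows = []
    ss = np.random.SeedSequence([cfg.base_seed, K])
    seeds = [int(s) for s in ss.generate_state(2 * cfg.n_seeds) % (2**31)]
    for i in range(cfg.n_seeds):
        w_seed, x_seed = seeds[2 * i], seeds[2 * i + 1]
        W = sample_weights(spec, seed=w_seed, dtype=cfg.dtype)
        sim = SimulationConfig(
            I0=cfg.I0, dt=cfg.dt, T=cfg.T, burn_in=cfg.burn_in,
            record_stride=cfg.record_stride, seed=x_seed, dtype=cfg.dtype,
        )
        traj = simulate(W, cfg.nl, sim)
        st = summarize(traj, I0=cfg.I0, max_lag=cfg.max_lag)
        row = {
            "K": K, "N": K, "family": cfg.family, "nu": cfg.nu, "J0": cfg.J0,
            "g": cfg.g, "I0": cfg.I0, "phi_kind": cfg.nl.kind, "lam": cfg.nl.lam,
            "seed": w_seed,
            "phi_bar": st.phi_bar, "f": st.f, "mu": st.mu, "x_bar": st.x_bar,
            "var_t_x": st.var_t_x, "var_q_x": st.var_q_x,
            "var_t_eta": st.var_t_eta, "var_q_eta": st.var_q_eta,
            "tau_eta": st.tau_eta, "beta": st.beta, "chi": st.chi,
            "psi": st.psi, "sync": st.sync,
        }
        if cfg.family == "gamma" and st.f > 0:
            pred = gamma_theory.predict(st.f, spec, cfg.I0)
            row.update(
                alpha_pred=pred.alpha, theta_pred=pred.theta,
                eta_mean_pred=pred.eta_mean, eta_var_pred=pred.eta_var,
                x_bar_pred=pred.x_bar_pred,
            )
        rows.append(row)
    return rows


def run_scaling_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """One row of summary statistics per (K, seed), with full provenance.

    Divergent simulations are flagged in a ``diverged`` column rather than
    dropped.
    """
    from .dynamics import SimulationDiverged

    rows: list[dict] = []
    for K in cfg.K_grid:
        try:
            new = _run_seeds(K, cfg)
            for r in new:
                r["diverged"] = False
            rows.extend(new)
        except SimulationDiverged as err:
            rows.append({"K": K, "N": K, "diverged": True, "error": str(err)})
    df = pd.DataFrame(rows)
    lead = [c for c in STAT_COLUMNS if c in df.columns]
    return df[lead + [c for c in df.columns if c not in lead]]


def fit_power_law(K: np.ndarray, y: np.ndarray) -> FitResult:
    """OLS of log y on log K. ``exponent`` is the negative slope, so a decay
    y ~ K^(-a) yields exponent a > 0."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive y")
    res = sps.linregress(np.log(K), np.log(y))
    return FitResult(
        exponent=-res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        stderr=res.stderr,
    )


def fit_sweep_exponent(df: pd.DataFrame, column: str = "phi_bar") -> FitResult:
    """Power-law exponent of a sweep statistic vs K, seed-averaged per K."""
    ok = df[~df["diverged"].astype(bool)] if "diverged" in df.columns else df
    means = ok.groupby("K")[column].mean()
    return fit_power_law(means.index.to_numpy(), means.to_numpy())


def input_response_curve(
    cfg: SweepConfig,
    I0_grid: np.ndarray,
    K: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """(I0, phi_bar, f, mu) at a fixed connectivity realization.

    The returned frame carries linearity diagnostics in ``attrs``:
    R^2 of the linear fit of phi_bar on I0 and the mean second difference
    (negative = sublinear population response).
    """
    K = K or cfg.K_grid[len(cfg.K_grid) // 2]
    seed = cfg.base_seed if seed is None else seed
    spec = WeightSpec(family=cfg.family, J0=cfg.J0, g=cfg.g, nu=cfg.nu, K=K, N=K)
    W = sample_weights(spec, seed=seed, dtype=cfg.dtype)
    rows = []
    for I0 in np.asarray(I0_grid, dtype=float):
        sim = SimulationConfig(
            I0=float(I0), dt=cfg.dt, T=cfg.T, burn_in=cfg.burn_in,
            record_stride=cfg.record_stride, seed=seed + 1, dtype=cfg.dtype,
            record_eta=False,
        )
        traj = simulate(W, cfg.nl, sim)
        st = summarize(traj, I0=float(I0))
        rows.append({"I0": float(I0), "phi_bar": st.phi_bar, "f": st.f, "mu": st.mu})
    df = pd.DataFrame(rows)
    lin = sps.linregress(df["I0"], df["phi_bar"])
    second = np.diff(df["phi_bar"].to_numpy(), n=2)
    df.attrs["linear_r2"] = float(lin.rvalue**2)
    df.attrs["mean_second_difference"] = float(second.mean()) if second.size else 0.0
    return df
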