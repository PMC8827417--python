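"""Summary statistics of network trajectories.

Conventions (all documented in the API because they matter for the exact
identities below):

* "active" means ``phi > 0`` strictly (equivalently ``x > 0`` for rectified
  F-I functions); a unit exactly at threshold is inactive.
* Variances use the population (1/n) normalization throughout, so the
  decomposition ``var_total = var_temporal + var_quenched`` is exact:
  pooling over units and times,

      var_total    = Var_{i,t}[s_i(t)]
      var_temporal = mean_i Var_t[s_i(t)]
      var_quenched = Var_i[ mean_t s_i(t) ]

  (quenched = spread of per-unit time averages, frozen by the disorder).
* The mean response factorizes exactly as ``phi_bar = f * mu`` where ``f``
  is the fraction of active (unit, time) samples and ``mu`` the mean rate
  of the active samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .dynamics import Trajectory

__all__ = [
    "SummaryStats",
    "mean_response",
    "fraction_active",
    "active_mean",
    "variance_decomposition",
    "autocorrelation",
    "correlation_time",
    "decorrelation_rate",
    "synchrony_index",
    "on_time_fraction",
    "psi",
    "balance_index",
    "gaussianity_report",
    "summarize",
]


@dataclass
class SummaryStats:
    """Scalar summary of one simulated trajectory (plus small arrays)."""

    phi_bar: float
    f: float
    mu: float
    x_bar: float
    var_t_x: float
    var_q_x: float
    var_t_eta: float | None
    var_q_eta: float | None
    tau_eta: float | None
    beta: float | None
    chi: float | None
    psi: float
    sync: float
    on_time: np.ndarray
    R_eta: np.ndarray | None = None
    R_lags: np.ndarray | None = None

    @property
    def var_total_x(self) -> float:
        return self.var_t_x + self.var_q_x

    @property
    def var_total_eta(self) -> float | None:
        if self.var_t_eta is None:
            return None
        return self.var_t_eta + self.var_q_eta


def _rates(traj: Trajectory | np.ndarray) -> np.ndarray:
    phi = traj.phi if isinstance(traj, Trajectory) else np.asarray(traj)
    if phi.size == 0:
        raise ValueError("empty trajectory")
    return phi


def mean_response(traj: Trajectory | np.ndarray) -> float:
    """Unit- and time-averaged rate, phi_bar = [<phi>]."""
    return float(np.mean(_rates(traj)))


def fraction_active(traj: Trajectory | np.ndarray) -> float:
    """Time-averaged fraction of units with phi > 0 (strict)."""
    phi = _rates(traj)
    return float(np.mean(phi > 0))


def active_mean(traj: Trajectory | np.ndarray) -> float:
    """Mean rate of active units, mu = phi_bar / f (0 when f = 0)."""
    phi = _rates(traj)
    f = float(np.mean(phi > 0))
    return float(np.mean(phi) / f) if f > 0 else 0.0


def variance_decomposition(signal: np.ndarray) -> tuple[float, float, float]:
    """(var_total, var_temporal, var_quenched) of a units x times array.

    Population (1/n) normalization; the three satisfy
    ``var_total = var_temporal + var_quenched`` to machine precision.
    """
    s = np.asarray(signal)
    if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("need a units x times array with >= 2 of each")
    unit_means = s.mean(axis=1)
    var_temporal = float(np.mean(s.var(axis=1)))
    var_quenched = float(unit_means.var())
    return var_temporal + var_quenched, var_temporal, var_quenched


def autocorrelation(
    signal: np.ndarray,
    max_lag: float,
    dt: float,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Population-averaged autocovariance of a units x times array.

    Per-unit means are subtracted; R(lag) averages the per-unit lagged
    autocovariance over units, with divisor (T - lag) per unit so that
    R(0) equals the temporal variance (1/T convention). FFT-based;
    processed in unit chunks to bound memory.

    Returns (lags, R) with lags = 0, dt, 2 dt, ..., <= max_lag.
    """
    s = np.asarray(signal, dtype=np.float64)
    if s.ndim != 2:
        raise ValueError("signal must be units x times")
    n_units, T = s.shape
    L = int(np.floor(max_lag / dt)) + 1
    if L - 1 > T // 2:
        raise ValueError("max_lag exceeds half the analysis window")
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    acc = np.zeros(L)
    for lo in range(0, n_units, chunk):
        d = s[lo : lo + chunk] - s[lo : lo + chunk].mean(axis=1, keepdims=True)
        F = np.fft.rfft(d, n=nfft, axis=1)
        ac = np.fft.irfft(F * np.conj(F), n=nfft, axis=1)[:, :L]
        acc += ac.sum(axis=0)
    counts = T - np.arange(L)
    R = acc / (n_units * counts)
    lags = np.arange(L) * dt
    return lags, R


def correlation_time(lags: np.ndarray, R: np.ndarray) -> float:
    """Correlation time tau = (1/R(0)) * integral of R(tau) d tau.

    The trapezoidal integral runs from lag 0 to the first zero crossing of
    R (the infinite upper limit is unreachable on a finite window and R
    decays into a noise floor), or to the last lag if R stays positive.
    """
    R = np.asarray(R, dtype=float)
    if R[0] <= 0:
        raise ValueError("R(0) must be positive")
    neg = np.flatnonzero(R < 0)
    end = int(neg[0]) + 1 if neg.size else len(R)
    # interpolate the crossing so the integral is continuous in the grid
    Rcut = R[:end].copy()
    if neg.size:
        Rcut[-1] = 0.0
    area = float(np.trapezoid(Rcut, np.asarray(lags)[:end]))
    return area / float(R[0])


def decorrelation_rate(lags: np.ndarray, R: np.ndarray, tau_x: float = 1.0) -> float:
    """beta = tau_x / tau_corr = R(0) / integral(R)."""
    return tau_x / correlation_time(lags, R)


def synchrony_index(x: np.ndarray) -> float:
    """Population-variance ratio (chi^2 synchrony measure) of a signal.

    Var_t of the population-averaged signal divided by the population
    average of the per-unit temporal variances. 1 for identical traces,
    ~1/N for independent units, far below 1/N when population activity is
    stabilized by the recurrence. ``summarize`` applies it to the rates
    (applying it to the currents gives a systematically larger value
    because current fluctuations retain a weakly correlated component).
    """
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 units")
    denom = float(np.mean(x.var(axis=1)))
    if denom == 0:
        raise ValueError("zero temporal variance")
    return float(x.mean(axis=0).var() / denom)


def on_time_fraction(traj: Trajectory | np.ndarray) -> np.ndarray:
    """Per-unit fraction of recorded time spent above threshold (phi > 0)."""
    phi = _rates(traj)
    return np.asarray((phi > 0).mean(axis=1), dtype=float)


def psi(traj: Trajectory | np.ndarray) -> float:
    """Second-to-first rate moment ratio, psi = mean(phi^2) / mean(phi).

    For binary (Heaviside) rates phi^2 = phi so psi = 1; for uniform
    constant rate c, psi = c.
    """
    phi = _rates(traj)
    pb = float(np.mean(phi))
    if pb == 0:
        raise ValueError("psi undefined: mean response is zero")
    return float(np.mean(phi.astype(np.float64) ** 2) / pb)


def balance_index(traj: Trajectory | np.ndarray, I0: float) -> float:
    """chi = x_bar / I0: relative contribution of the bias to the mean current."""
    if I0 == 0:
        raise ValueError("balance index undefined for I0 = 0")
    x = traj.x if isinstance(traj, Trajectory) else np.asarray(traj)
    return float(np.mean(x) / I0)


def gaussianity_report(x_samples: np.ndarray, n_test: int | None = None,
                       seed: int = 0) -> dict:
    """Shape statistics of a pooled current sample.

    Returns skewness, excess kurtosis, the D'Agostino K^2 normality statistic
    and p-value (computed on ``n_test`` subsamples when given, so that
    networks can be compared at matched sample size), and the
    supra-threshold mass P(x > 0).
    """
    x = np.asarray(x_samples, dtype=np.float64).ravel()
    if n_test is not None and n_test < x.size:
        rng = np.random.default_rng(seed)
        xt = rng.choice(x, size=n_test, replace=False)
    else:
        xt = x
    k2, p = sps.normaltest(xt)
    return {
        "mean": float(x.mean()),
        "skew": float(sps.skew(x)),
        "excess_kurtosis": float(sps.kurtosis(x)),
        "normality_stat": float(k2),
        "normality_p": float(p),
        "frac_above_threshold": float(np.mean(x > 0)),
        "n_test": int(xt.size),
    }


def summarize(
    traj: Trajectory,
    I0: float | None = None,
    max_lag: float = 20.0,
) -> SummaryStats:
    """Compute the full summary-statistic suite for one trajectory.

    The autocorrelation-based quantities (tau_eta, beta) are computed on the
    recurrent input eta when recorded (the quantity whose decorrelation
    sets the sparsity), with ``max_lag`` capped at half the window.
    """
    phi = traj.phi
    pb = float(np.mean(phi))
    f = float(np.mean(phi > 0))
    mu = pb / f if f > 0 else 0.0
    x_bar = float(np.mean(traj.x))
    _, vt_x, vq_x = variance_decomposition(traj.x)

    dt = float(traj.times[1] - traj.times[0]) if traj.times.size > 1 else 1.0
    window = traj.times[-1] - traj.times[0] if traj.times.size > 1 else 0.0
    lag = min(max_lag, window / 2)

    vt_e = vq_e = tau_eta = beta = None
    R = lags = None
    if traj.eta is not None:
        _, vt_e, vq_e = variance_decomposition(traj.eta)
        if lag > dt and vt_e > 0:
            lags, R = autocorrelation(traj.eta, lag, dt)
            tau_eta = correlation_time(lags, R)
            beta = 1.0 / tau_eta if tau_eta > 0 else np.inf

    if I0 is None:
        I0 = traj.meta.get("I0") if traj.meta else None
        if I0 is None and traj.config is not None:
            I0 = traj.config.I0
    chi = float(x_bar / I0) if I0 not in (None, 0) else None

    return SummaryStats(
        phi_bar=pb,
        f=f,
        mu=mu,
        x_bar=x_bar,
        var_t_x=vt_x,
        var_q_x=vq_x,
        var_t_eta=vt_e,
        var_q_eta=vq_e,
        tau_eta=tau_eta,
        beta=beta,
        chi=chi,
        psi=psi(phi) if pb > 0 else 0.0,
        sync=synchrony_index(phi),
        on_time=on_time_fraction(phi),
        R_eta=R,
        R_lags=lags,
    )
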