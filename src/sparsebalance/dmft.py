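"""Dynamic mean-field theory of the sparse-balance network with Gaussian weights.

The network is replaced by a self-consistent single-unit process. With
weights of mean ``J0/sqrt(K)`` and variance ``g^2/sqrt(K)``, the total
current decomposes into a mean ``u``, a static (quenched) Gaussian
component and a temporal Gaussian component:

    x(t) = u + g K^(1/4) sqrt(q) z + sqrt(sigma0 - g^2 sqrt(K) q) xi(t),

with ``m = [<phi>]``, ``q = [<phi>^2]``, ``u = I0 - J0 sqrt(K) m``, and
``sigma(tau) = [<x(t) x(t+tau)>] - u^2`` the autocorrelation of x
(``sigma0 = sigma(0)`` its total variance). Self-consistency requires

    u = I0 - J0 sqrt(K) Int Dz' phi(u + sqrt(sigma0) z')
    q = Int Dz ( Int Dxi phi(u + g K^(1/4) sqrt(q) z
                              + sqrt(sigma0 - g^2 sqrt(K) q) xi) )^2

and the autocorrelation obeys the autonomous second-order ODE

    d^2 sigma / d tau^2 = sigma - g^2 sqrt(K) [<phi(x(t)) phi(x(t+tau))>],

started from ``sigma(0) = sigma0, dsigma/dtau(0) = 0``, where the
correlator shares the quenched load ``sqrt(|sigma|) z`` between the two
time points. The admissible (chaotic) solution has ``dsigma/dtau <= 0``
and ``sigma >= 0`` for all lags; ``sigma0`` is found by bisection on the
two failure modes (upturn = too small, dropping below the quenched floor
``g^2 sqrt(K) q`` = too large). From the solution:

    f = Phi(u / sqrt(sigma0))                  (fraction active)
    R_eta(tau) = g^2 sqrt(K) ([<phi phi>](tau) - q)
    beta = R_eta(0) / integral R_eta d tau     (decorrelation rate)

Gaussian integrals use Gauss-Hermite quadrature; for the Heaviside F-I
function the inner temporal integral is replaced by its closed form (the
standard normal CDF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import ndtr  # standard normal CDF

from .dynamics import Nonlinearity, apply_nonlinearity

__all__ = [
    "DMFTParams",
    "DMFTSolution",
    "double_gaussian_average",
    "solve_uq",
    "evolve_sigma",
    "find_sigma0",
    "compare_to_simulation",
    "energy_drift",
]


@dataclass(frozen=True)
class DMFTParams:
    """Mean-field problem definition.

    ``scaling="sparse"`` is the high-variance model above. The
    ``"conventional"`` setting is a regression configuration reproducing the
    standard balanced state (weight variance g^2/K, bias of order sqrt(K)):
    the eta-variance factor becomes g^2 and the bias enters as sqrt(K) I0.
    """

    J0: float
    g: float
    K: int
    I0: float
    nl: Nonlinearity = field(default_factory=lambda: Nonlinearity("rect_tanh"))
    order: int = 64
    tau_max: float = 50.0
    scaling: str = "sparse"

    def __post_init__(self) -> None:
        if self.J0 <= 0 or self.g <= 0:
            raise ValueError("J0 and g must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.scaling not in ("sparse", "conventional"):
            raise ValueError("scaling must be 'sparse' or 'conventional'")

    @property
    def var_factor(self) -> float:
        """Coefficient of q in the quenched variance of eta."""
        return self.g**2 * (np.sqrt(self.K) if self.scaling == "sparse" else 1.0)

    @property
    def bias(self) -> float:
        return self.I0 * (1.0 if self.scaling == "sparse" else np.sqrt(self.K))


@dataclass
class DMFTSolution:
    """Converged self-consistent solution."""

    params: DMFTParams
    u: float
    m: float
    q: float
    sigma0: float
    quenched_var: float
    f: float
    beta: float
    tau: np.ndarray
    sigma: np.ndarray
    sigma_dot: np.ndarray
    R_eta: np.ndarray
    residual_u: float
    residual_q: float
    admissible: bool
    bracket: tuple[float, float]


@lru_cache(maxsize=16)
def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(Z)], Z ~ N(0,1), via Gauss-Hermite."""
    t, w = np.polynomial.hermite.hermgauss(order)
    return np.sqrt(2.0) * t, w / np.sqrt(np.pi)


@lru_cache(maxsize=16)
def _gl_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0, 1]."""
    t, w = np.polynomial.legendre.leggauss(order)
    return 0.5 * (t + 1.0), 0.5 * w

_ZCUT = 8.0  # Gaussian mass beyond 8 sd is ~6e-16


def _rect_gauss_moment(
    nl: Nonlinearity, means: np.ndarray, sd: float, order: int, power: int = 1
) -> np.ndarray:
    """E[phi(mean + sd*xi)^power] over xi ~ N(0,1), vectorized over `means`.

    Rectified phi makes the integrand kinked at threshold, where fixed
    Gauss-Hermite rules lose accuracy; instead the integral is restricted to
    the active region xi > -mean/sd (where phi is smooth and vanishes at the
    boundary) and evaluated by Gauss-Legendre with the Gaussian weight
    carried explicitly.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    if nl.kind == "heaviside" or (nl.kind == "rect_power" and nl.lam == 0):
        if sd == 0:
            return (means > 0).astype(float)
        return ndtr(means / sd)  # H^power = H
    if sd == 0:
        return apply_nonlinearity(means, nl) ** power
    lo = np.clip(-means / sd, -_ZCUT, _ZCUT)
    span = _ZCUT - lo
    t, wt = _gl_nodes(order)
    xi = lo[:, None] + span[:, None] * t[None, :]
    w = span[:, None] * wt[None, :] * np.exp(-0.5 * xi**2) / np.sqrt(2 * np.pi)
    vals = apply_nonlinearity(means[:, None] + sd * xi, nl) ** power
    return (vals * w).sum(axis=1)


def _inner_mean(nl: Nonlinearity, means: np.ndarray, tsd: float, order: int) -> np.ndarray:
    """<phi(mean + tsd * xi)> over xi ~ N(0,1), vectorized over `means`."""
    return _rect_gauss_moment(nl, means, tsd, order, power=1)


def double_gaussian_average(
    fn: Callable[[np.ndarray], np.ndarray] | Nonlinearity,
    u: float,
    quenched_sd: float,
    temporal_sd: float,
    order: int = 64,
) -> tuple[float, float]:
    """([<fn>], [<fn>^2]) over x = u + quenched_sd*z + temporal_sd*xi.

    ``z`` (quenched) and ``xi`` (temporal) are independent standard
    normals; the inner average runs over xi, the outer over z. Computed by
    Gauss-Hermite quadrature (closed-form inner integral for Heaviside).
    """
    if order < 8:
        raise ValueError("quadrature order must be >= 8")
    if quenched_sd < 0 or temporal_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    if isinstance(fn, Nonlinearity) and temporal_sd == 0:
        # inner average degenerates to phi itself (kinked): integrate over z
        # in the active region directly
        m1 = _rect_gauss_moment(fn, np.array([u]), quenched_sd, order, power=1)[0]
        m2 = _rect_gauss_moment(fn, np.array([u]), quenched_sd, order, power=2)[0]
        return float(m1), float(m2)
    z, wz = _gh_nodes(order)
    means = u + quenched_sd * z
    if isinstance(fn, Nonlinearity):
        inner = _inner_mean(fn, means, temporal_sd, order)
    elif temporal_sd == 0:
        inner = np.asarray(fn(means), dtype=float)
    else:
        xi, wxi = _gh_nodes(order)
        inner = np.asarray(fn(means[:, None] + temporal_sd * xi[None, :]), dtype=float) @ wxi
    return float(inner @ wz), float(inner**2 @ wz)


def _mean_rate(u: float, total_sd: float, p: DMFTParams) -> float:
    """Int Dz' phi(u + total_sd * z') — the single-Gaussian mean rate."""
    return float(_inner_mean(p.nl, np.array([u]), total_sd, p.order)[0])


def _solve_u(sigma0: float, p: DMFTParams) -> float:
    """Root of u = bias - J0 sqrt(K) * Int Dz' phi(u + sqrt(sigma0) z')."""
    s = np.sqrt(max(sigma0, 0.0))
    c = p.J0 * np.sqrt(p.K)

    def h(u: float) -> float:
        return u - p.bias + c * _mean_rate(u, s, p)

    hi = p.bias
    if h(hi) < 0:  # can only happen for pathological phi; expand upward
        while h(hi) < 0:
            hi += max(1.0, abs(hi))
    lo, width = p.bias - 1.0, 1.0
    while h(lo) > 0:
        width *= 2.0
        lo = p.bias - width
        if width > 1e12:
            raise RuntimeError("could not bracket the mean-current equation")
    return brentq(h, lo, hi, xtol=1e-13, rtol=1e-15)


def _q_rhs(q: float, u: float, sigma0: float, p: DMFTParams) -> tuple[float, bool]:
    """RHS of the q equation; flags clamping when sigma0 < quenched variance."""
    clamped = False
    qv = p.var_factor * q
    tv = sigma0 - qv
    if tv < 0:
        tv, clamped = 0.0, True
    _, q_new = double_gaussian_average(p.nl, u, np.sqrt(qv), np.sqrt(tv), p.order)
    return q_new, clamped


def solve_uq(
    sigma0: float,
    p: DMFTParams,
    damping: float = 0.5,
    tol: float = 1e-11,
    max_iter: int = 10_000,
) -> tuple[float, float, float, bool]:
    """Solve the u and q self-consistency at a candidate total variance sigma0.

    Returns (u, q, m, clamped). ``u`` depends on sigma0 only and is found by
    a bracketed root solve; ``q`` by damped fixed-point iteration. ``clamped``
    reports that sigma0 fell below the implied quenched variance
    ``g^2 sqrt(K) q`` during iteration (candidate inadmissible).
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    u = _solve_u(sigma0, p)
    m = (p.bias - u) / (p.J0 * np.sqrt(p.K))
    q = m**2  # Cauchy-Schwarz lower bound as starting point
    clamped_any = False
    for _ in range(max_iter):
        q_new, clamped = _q_rhs(q, u, sigma0, p)
        clamped_any |= clamped
        q_next = (1 - damping) * q + damping * q_new
        if abs(q_next - q) < tol:
            q = q_next
            break
        q = q_next
    else:
        raise RuntimeError(
            f"q fixed point did not converge: residual {abs(q_new - q):.3e}"
        )
    return u, q, m, clamped_any


def _correlator(sigma: float, u: float, sigma0: float, p: DMFTParams) -> float:
    """[<phi(x(t)) phi(x(t+tau))>] at autocorrelation value sigma.

    Shared quenched component sqrt(|sigma|) z; independent temporal parts of
    variance sigma0 - |sigma| at the two times (so the inner average is
    squared), assuming sigma >= 0.
    """
    s = abs(sigma)
    s = min(s, sigma0)
    _, second = double_gaussian_average(p.nl, u, np.sqrt(s), np.sqrt(sigma0 - s), p.order)
    return second


def evolve_sigma(
    u: float,
    q: float,
    sigma0: float,
    p: DMFTParams,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    n_grid: int = 801,
):
    """Integrate the sigma ODE from (sigma0, 0); detect admissibility violations.

    Returns a dict with the dense solution sampled on a uniform grid up to
    the stopping time and ``status`` in {"ok", "turned", "overshot"}:
    "turned" = sigma_dot became positive, "overshot" = sigma dropped below
    the quenched floor g^2 sqrt(K) q. Because u is re-solved at each
    candidate sigma0 (larger sigma0 -> more negative u -> smaller rates ->
    weaker downward pull on sigma), "overshot" indicates a sigma0 that is
    too small and "turned" one that is too large. An immediate positive
    curvature at tau = 0 is an extreme "turned" case.
    """
    floor = p.var_factor * q
    eps = 1e-7 * max(sigma0, 1e-12)

    def rhs(_t, y):
        s, sd = y
        return [sd, s - p.var_factor * _correlator(s, u, sigma0, p)]

    curv0 = sigma0 - p.var_factor * _correlator(sigma0, u, sigma0, p)
    if curv0 >= 0:
        tau = np.array([0.0])
        return {
            "status": "turned",
            "tau": tau,
            "sigma": np.array([sigma0]),
            "sigma_dot": np.array([0.0]),
            "floor": floor,
            "t_stop": 0.0,
        }

    def ev_turn(_t, y):
        return y[1] - eps

    ev_turn.terminal = True
    ev_turn.direction = 1

    def ev_floor(_t, y):
        return y[0] - (floor - eps)

    ev_floor.terminal = True
    ev_floor.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, p.tau_max),
        [sigma0, 0.0],
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=[ev_turn, ev_floor],
    )
    t_stop = sol.t[-1]
    if sol.t_events[0].size:
        status = "turned"
    elif sol.t_events[1].size:
        status = "overshot"
    else:
        status = "ok"
    tau = np.linspace(0.0, t_stop, n_grid)
    y = sol.sol(tau)
    return {
        "status": status,
        "tau": tau,
        "sigma": y[0],
        "sigma_dot": y[1],
        "floor": floor,
        "t_stop": t_stop,
    }


def _classify(sigma0: float, p: DMFTParams) -> tuple[str, tuple]:
    u, q, m, clamped = solve_uq(sigma0, p)
    if clamped:
        return "too_small", (u, q, m, None)
    ev = evolve_sigma(u, q, sigma0, p)
    status = {"overshot": "too_small", "turned": "too_large", "ok": "ok"}[ev["status"]]
    return status, (u, q, m, ev)


def find_sigma0(
    p: DMFTParams,
    scan: tuple[float, float] | None = None,
    n_scan: int = 40,
    max_bisect: int = 60,
) -> DMFTSolution:
    """Self-consistent solution by bisection on the total variance sigma0.

    A coarse log-spaced scan brackets sigma0 between a "turned" (too small)
    and an "overshot" (too large) candidate; bisection then shrinks the
    bracket until its relative width is below 1e-8. Raises if no admissible
    bracket exists (parameters outside the chaotic regime).
    """
    s_scale = p.var_factor  # g^2 sqrt(K); order of the eta variance for phi <= 1
    lo, hi = scan if scan is not None else (1e-3 * s_scale, 3.0 * s_scale)
    grid = np.geomspace(lo, hi, n_scan)
    lo_ok = hi_ok = None
    for s0 in grid:
        cls, _ = _classify(float(s0), p)
        if cls == "too_small":
            lo_ok = float(s0)
        else:  # "too_large" or an already-admissible "ok": upper edge
            hi_ok = float(s0)
            break
    if lo_ok is None or hi_ok is None:
        raise RuntimeError(
            "no admissible sigma0 bracket found: parameters may lie outside "
            "the chaotic regime"
        )
    a, b = lo_ok, hi_ok
    for _ in range(max_bisect):
        mid = 0.5 * (a + b)
        cls, _ = _classify(mid, p)
        if cls == "too_small":
            a = mid
        else:  # too_large or ok: shrink from above
            b = mid
        if (b - a) < 1e-8 * b:
            break
    sigma0 = 0.5 * (a + b)
    u, q, m, _ = solve_uq(sigma0, p)
    ev = evolve_sigma(u, q, sigma0, p)

    # extend sigma to tau_max on a uniform grid, clamped to the quenched floor
    floor = p.var_factor * q
    tau = np.linspace(0.0, p.tau_max, 1001)
    sigma = np.interp(tau, ev["tau"], ev["sigma"], right=floor)
    sigma = np.maximum(sigma, floor)
    sigma_dot = np.interp(tau, ev["tau"], ev["sigma_dot"], right=0.0)

    corr = np.array([_correlator(s, u, sigma0, p) for s in sigma])
    R_raw = p.var_factor * (corr - q)  # decays to 0 at the quenched floor
    from .stats import correlation_time  # local import to avoid cycle at import time

    beta = 1.0 / correlation_time(tau, R_raw)
    R_eta = np.maximum(R_raw, 0.0)

    s_tot = np.sqrt(sigma0)
    f = float(ndtr(u / s_tot))
    res_u = abs(u - (p.bias - p.J0 * np.sqrt(p.K) * _mean_rate(u, s_tot, p)))
    q_rhs, _ = _q_rhs(q, u, sigma0, p)
    res_q = abs(q - q_rhs)
    return DMFTSolution(
        params=p,
        u=u,
        m=m,
        q=q,
        sigma0=sigma0,
        quenched_var=floor,
        f=f,
        beta=beta,
        tau=tau,
        sigma=sigma,
        sigma_dot=sigma_dot,
        R_eta=R_eta,
        residual_u=res_u,
        residual_q=res_q,
        admissible=ev["status"] in ("ok", "turned", "overshot"),
        bracket=(a, b),
    )


def energy_drift(sol: DMFTSolution) -> float:
    """Relative drift of the conserved energy along the sigma trajectory.

    The sigma ODE derives from a potential: with F(sigma) the right-hand
    side, E = sigma_dot^2 / 2 - V(sigma) (V the path antiderivative of F)
    is constant. Returns max |E - E(0)| normalized by the potential scale,
    evaluated on the stored grid restricted to the strictly decaying part.
    """
    p = sol.params
    keep = sol.sigma > sol.quenched_var * (1 + 1e-9)
    keep[0] = True
    s = sol.sigma[keep]
    sd = sol.sigma_dot[keep]
    F = s - p.var_factor * np.array([_correlator(v, sol.u, sol.sigma0, p) for v in s])
    # cumulative trapezoid of F d sigma along the path
    V = np.concatenate([[0.0], np.cumsum(0.5 * (F[1:] + F[:-1]) * np.diff(s))])
    E = 0.5 * sd**2 - V
    scale = max(np.max(np.abs(V)), 0.5 * float(np.max(sd**2)), 1e-12)
    return float(np.max(np.abs(E - E[0])) / scale)


def compare_to_simulation(sol: DMFTSolution, stats, spec=None) -> dict:
    """Relative errors of DMFT (m, f, beta) against measured SummaryStats.

    ``spec`` (a WeightSpec) is checked for parameter agreement when given.
    Also reports an L2 distance between the normalized R_eta curves when
    the stats carry one.
    """
    p = sol.params
    if spec is not None:
        if (spec.family != "gaussian" or spec.K != p.K
                or not np.isclose(spec.J0, p.J0) or not np.isclose(spec.g, p.g)):
            raise ValueError("simulation parameters do not match the DMFT problem")
    out = {
        "rel_err_m": abs(sol.m - stats.phi_bar) / abs(stats.phi_bar),
        "rel_err_f": abs(sol.f - stats.f) / abs(stats.f),
    }
    if stats.beta is not None:
        out["rel_err_beta"] = abs(sol.beta - stats.beta) / abs(stats.beta)
    if stats.R_eta is not None and stats.R_lags is not None:
        Rn_sim = stats.R_eta / stats.R_eta[0]
        Rn_th = np.interp(stats.R_lags, sol.tau, sol.R_eta / sol.R_eta[0])
        out["R_eta_l2"] = float(
            np.sqrt(np.trapezoid((Rn_sim - Rn_th) ** 2, stats.R_lags))
        )
    return out
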