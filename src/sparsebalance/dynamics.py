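"""Forward-Euler integration of rectified rate networks.

Single inhibitory population (currents ``x_i``, rates ``phi(x_i)``):

    tau_x dx_i/dt = -x_i - sum_j J_ij phi(x_j) + I0 ,   J_ij >= 0,

and the two-population E-I variant where excitatory input enters with ``+``
sign and inhibitory with ``-``. The recurrent synaptic input is

    eta_i(t) = sum_j J_ij phi(x_j),

so the single-population dynamics is a low-pass filter of ``eta``:
``tau_x dx/dt = -x - eta + I0``. Time is measured in units of ``tau_x``
(fixed to 1). All supplied nonlinearities are rectified (``phi(x) = 0`` for
``x <= 0``), which the integrator exploits: only units above threshold
contribute to the recurrent term, so in sparse regimes the matrix-vector
product touches a small set of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import WeightMatrix

__all__ = [
    "Nonlinearity",
    "SimulationConfig",
    "Trajectory",
    "apply_nonlinearity",
    "simulate",
    "simulate_ei",
]


@dataclass(frozen=True)
class Nonlinearity:
    """Rectified F-I function phi.

    kind = "heaviside":  phi(x) = 1 for x > 0, else 0
    kind = "rect_tanh":  phi(x) = tanh(x) for x > 0, else 0
    kind = "rect_power": phi(x) = x**lam for x > 0, else 0
                         (lam = 1 rectified linear, lam = 2 rectified
                         quadratic; lam = 0 reproduces the Heaviside)

    phi(0) = 0 in every case (the "x <= 0" branch applies at threshold).
    """

    kind: str = "rect_tanh"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "rect_tanh", "rect_power"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.kind == "rect_power" and self.lam < 0:
            raise ValueError("rect_power exponent lambda must be >= 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return apply_nonlinearity(x, self)


def apply_nonlinearity(x: np.ndarray, nl: Nonlinearity) -> np.ndarray:
    """Elementwise rate phi(x); zero on x <= 0."""
    x = np.asarray(x)
    pos = x > 0
    if nl.kind == "heaviside" or (nl.kind == "rect_power" and nl.lam == 0):
        return pos.astype(x.dtype if x.dtype.kind == "f" else np.float64)
    out = np.zeros_like(x, dtype=x.dtype if x.dtype.kind == "f" else np.float64)
    if nl.kind == "rect_tanh":
        np.tanh(x, where=pos, out=out)
    else:
        np.power(x, nl.lam, where=pos, out=out)
    out[~pos] = 0.0
    return out


def _phi_positive(xpos: np.ndarray, nl: Nonlinearity) -> np.ndarray:
    """phi evaluated on values already known to be > 0."""
    if nl.kind == "heaviside" or (nl.kind == "rect_power" and nl.lam == 0):
        return np.ones_like(xpos)
    if nl.kind == "rect_tanh":
        return np.tanh(xpos)
    return xpos**nl.lam


@dataclass(frozen=True)
class SimulationConfig:
    """Euler-integration settings. Time unit is tau_x = 1."""

    I0: float = 1.0
    tau_x: float = 1.0
    dt: float = 0.02
    T: float = 1000.0
    burn_in: float = 100.0
    record_stride: int = 5  # steps between stored samples (default 0.1 tau_x)
    seed: int = 0
    record_eta: bool = True
    dtype: type = np.float64

    def __post_init__(self) -> None:
        if not (0 < self.dt <= 0.05):
            raise ValueError("dt must lie in (0, 0.05]")
        if self.burn_in >= self.T:
            raise ValueError("burn_in must be smaller than T")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded post-burn-in time series (units x recorded times)."""

    x: np.ndarray
    phi: np.ndarray
    times: np.ndarray
    eta: np.ndarray | None = None
    labels: np.ndarray | None = None
    config: SimulationConfig | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        return self.x.shape[1]

    def population(self, label: str) -> "Trajectory":
        """Sub-trajectory of the units with the given population label."""
        if self.labels is None:
            raise ValueError("trajectory carries no population labels")
        sel = self.labels == label
        return Trajectory(
            x=self.x[sel],
            phi=self.phi[sel],
            times=self.times,
            eta=None if self.eta is None else self.eta[sel],
            labels=self.labels[sel],
            config=self.config,
            meta=dict(self.meta),
        )


class SimulationDiverged(FloatingPointError):
    """Raised when the Euler state becomes nonfinite (e.g. rect_power blowup)."""


def _euler_core(
    Weff: np.ndarray,
    nl: Nonlinearity,
    I_ext: np.ndarray,
    x0: np.ndarray,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Integrate tau_x dx/dt = -x + Weff @ phi(x) + I_ext.

    ``Weff`` is the *effective* (signed) coupling: ``-J`` for the purely
    inhibitory network, the signed block matrix for E-I. Returns recorded
    (x, phi, recur, times) where ``recur = Weff @ phi`` at the recorded steps.
    """
    dtype = np.dtype(cfg.dtype)
    N = Weff.shape[0]
    # Fortran order makes the active-column gather contiguous
    WF = np.asfortranarray(Weff, dtype=dtype)
    x = np.ascontiguousarray(x0, dtype=dtype).copy()
    I_ext = np.asarray(I_ext, dtype=dtype)
    a = dtype.type(cfg.dt / cfg.tau_x)

    n_steps = int(round(cfg.T / cfg.dt))
    burn_steps = int(round(cfg.burn_in / cfg.dt))
    rec_idx = np.arange(burn_steps, n_steps, cfg.record_stride)
    n_rec = rec_idx.size
    xs = np.empty((N, n_rec), dtype=dtype)
    phis = np.empty((N, n_rec), dtype=dtype)
    recs = np.empty((N, n_rec), dtype=dtype) if cfg.record_eta else None
    times = (rec_idx * cfg.dt).astype(np.float64)

    dense_cutoff = max(1, N // 3)
    rec_ptr = 0
    next_rec = rec_idx[0] if n_rec else n_steps
    for step in range(n_steps):
        idx = np.flatnonzero(x > 0)
        if idx.size == 0:
            recur = np.zeros(N, dtype=dtype)
            phi_full = None
        elif idx.size <= dense_cutoff:
            phi_act = _phi_positive(x[idx], nl)
            recur = WF[:, idx] @ phi_act
            phi_full = None
        else:
            phi_full = apply_nonlinearity(x, nl)
            recur = WF @ phi_full
        if step == next_rec:
            xs[:, rec_ptr] = x
            if phi_full is None:
                col = np.zeros(N, dtype=dtype)
                if idx.size:
                    col[idx] = phi_act
                phis[:, rec_ptr] = col
            else:
                phis[:, rec_ptr] = phi_full
            if recs is not None:
                recs[:, rec_ptr] = recur
            rec_ptr += 1
            next_rec = rec_idx[rec_ptr] if rec_ptr < n_rec else n_steps
        x += a * (-x + recur + I_ext)
        if step % 200 == 0 and not np.isfinite(x).all():
            raise SimulationDiverged(
                f"nonfinite state at step {step} (t = {step * cfg.dt:.2f} tau_x); "
                "rect_power lambda > 1 dynamics can diverge"
            )
    if not np.isfinite(x).all():
        raise SimulationDiverged(f"nonfinite state at final step {n_steps}")
    return xs, phis, recs, times


def _initial_state(N: int, cfg: SimulationConfig, x0) -> np.ndarray:
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (N,):
            raise ValueError(f"x0 must have shape ({N},)")
        return x0
    rng = np.random.default_rng(cfg.seed)
    return 0.1 * rng.standard_normal(N)


def simulate(
    W: WeightMatrix | np.ndarray,
    nl: Nonlinearity,
    cfg: SimulationConfig,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Simulate the single-population inhibitory network (J >= 0 couples with
    a minus sign). Records currents x, rates phi(x) and, when
    ``cfg.record_eta``, the recurrent synaptic input ``eta = J @ phi >= 0``.
    """
    J = W.values if isinstance(W, WeightMatrix) else np.asarray(W)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("weight matrix must be square")
    N = J.shape[0]
    x0 = _initial_state(N, cfg, x0)
    I_ext = np.full(N, cfg.I0)
    xs, phis, recs, times = _euler_core(-J, nl, I_ext, x0, cfg)
    eta = -recs if recs is not None else None  # eta = +J @ phi
    meta = {"I0": cfg.I0}
    if isinstance(W, WeightMatrix):
        meta["weight_seed"] = W.seed
        if W.spec is not None:
            meta["spec"] = W.spec
    return Trajectory(x=xs, phi=phis, eta=eta, times=times, config=cfg, meta=meta)


def simulate_ei(
    W: WeightMatrix,
    nl: Nonlinearity,
    IE: float,
    II: float,
    cfg: SimulationConfig,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Simulate the signed two-population E-I network from ``build_ei_matrix``.

    Excitatory columns enter with + sign and inhibitory with - sign (already
    encoded in ``W.values``); population biases are ``IE`` (excitatory units)
    and ``II`` (inhibitory units). ``Trajectory.eta`` holds the signed net
    recurrent input.
    """
    if W.labels is None:
        raise ValueError("E-I simulation requires a labelled block matrix")
    N = W.N
    I_ext = np.where(W.labels == "E", IE, II).astype(float)
    x0 = _initial_state(N, cfg, x0)
    xs, phis, recs, times = _euler_core(W.values, nl, I_ext, x0, cfg)
    return Trajectory(
        x=xs,
        phi=phis,
        eta=recs,
        times=times,
        labels=W.labels.copy(),
        config=cfg,
        meta={"IE": IE, "II": II, "weight_seed": W.seed, **W.meta},
    )
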