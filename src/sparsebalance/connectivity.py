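"""Synaptic weight matrices with in-degree-dependent moment scalings.

Nonzero weights are drawn i.i.d. from a positive-support family (gamma,
lognormal, binary) or from an unconstrained Gaussian, with population mean

    E[J] = J0 / sqrt(K)

and population variance

    Var[J] = g^2 / K**nu ,

where ``K`` is the in-degree. ``nu = 1`` is the conventional ("low
variance") scaling; ``nu = 1/2`` is the high-variance scaling that produces
the sparse-balance regime. Each row of a sampled matrix carries exactly
``K`` structurally nonzero entries; when ``K == N`` the matrix is dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "WeightSpec",
    "WeightMatrix",
    "sample_weights",
    "dilute_mask",
    "build_ei_matrix",
    "family_params",
]

_FAMILIES = ("gamma", "lognormal", "gaussian", "binary")


@dataclass(frozen=True)
class WeightSpec:
    """Distribution family and moment scalings of the nonzero weights.

    Parameters
    ----------
    family : {"gamma", "lognormal", "gaussian", "binary"}
    J0 : float
        Order-1 mean-coupling scale; nonzero-weight mean is ``J0/sqrt(K)``.
    g : float
        Order-1 variance-coupling scale; nonzero-weight variance is
        ``g**2 / K**nu``.
    nu : float
        Variance-scaling exponent in (0, 1]. ``0.5`` = high variance,
        ``1.0`` = low variance.
    K : int
        In-degree (structurally nonzero entries per row).
    N : int
        Network size, ``K <= N``.
    """

    family: str
    J0: float
    g: float
    nu: float
    K: int
    N: int

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if not self.J0 > 0:
            raise ValueError("J0 must be positive")
        if self.g < 0:
            raise ValueError("g must be nonnegative")
        if not (0 < self.nu <= 1):
            raise ValueError("nu must lie in (0, 1]")
        if not (0 < self.K <= self.N):
            raise ValueError("need 0 < K <= N")

    @property
    def weight_mean(self) -> float:
        """Target mean of a nonzero weight, ``J0 / sqrt(K)``."""
        return self.J0 / np.sqrt(self.K)

    @property
    def weight_var(self) -> float:
        """Target variance of a nonzero weight, ``g**2 / K**nu``."""
        return self.g**2 / self.K**self.nu


@dataclass
class WeightMatrix:
    """A sampled connectivity matrix plus the metadata needed to re-sample it."""

    values: np.ndarray
    spec: WeightSpec | None
    seed: int
    labels: np.ndarray | None = None  # per-unit population labels for E-I nets
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def row_nonzero_counts(self) -> np.ndarray:
        return np.count_nonzero(self.values, axis=1)


def family_params(spec: WeightSpec) -> dict:
    """Distribution parameters matching the target first two moments.

    gamma:     shape ``kappa = (J0^2/g^2) K^(nu-1)``, scale
               ``theta = (g^2/J0) K^(1/2-nu)`` (so ``kappa*theta`` is the
               mean and ``kappa*theta^2`` the variance).
    lognormal: ``sigma_ln^2 = log(1 + var/mean^2)``,
               ``mu_ln = log(mean) - sigma_ln^2/2``.
    binary:    two-point law on {0, w} with ``w = mean + var/mean`` and
               ``P(w) = mean/w``.
    gaussian:  the two moments directly (no sign constraint).
    """
    m, v = spec.weight_mean, spec.weight_var
    if spec.family == "gamma":
        if v <= 0:
            raise ValueError("gamma family requires positive variance (g > 0)")
        kappa = spec.J0**2 / spec.g**2 * spec.K ** (spec.nu - 1.0)
        theta = spec.g**2 / spec.J0 * spec.K ** (0.5 - spec.nu)
        return {"kappa": kappa, "theta": theta}
    if spec.family == "lognormal":
        if v <= 0:
            raise ValueError("lognormal family requires positive variance (g > 0)")
        s2 = np.log1p(v / m**2)
        return {"mu_ln": np.log(m) - s2 / 2.0, "sigma_ln": np.sqrt(s2)}
    if spec.family == "binary":
        if m <= 0 or v <= 0:
            raise ValueError("binary family requires positive mean and variance")
        w = m + v / m
        p = m / w
        if not (0 < p < 1):
            raise ValueError(f"binary family infeasible: P(w) = {p} outside (0, 1)")
        return {"w": w, "p": p}
    return {"mean": m, "sd": np.sqrt(v)}


def _draw_values(spec: WeightSpec, n: int, rng: np.random.Generator,
                 dtype=np.float64) -> np.ndarray:
    """Draw ``n`` i.i.d. nonzero-weight values for ``spec``."""
    m = spec.weight_mean
    if spec.g == 0.0:  # degenerate zero-variance limit: all weights equal
        return np.full(n, m, dtype=dtype)
    p = family_params(spec)
    if spec.family == "gamma":
        vals = rng.gamma(shape=p["kappa"], scale=p["theta"], size=n)
    elif spec.family == "lognormal":
        vals = rng.lognormal(mean=p["mu_ln"], sigma=p["sigma_ln"], size=n)
    elif spec.family == "binary":
        vals = np.where(rng.random(n) < p["p"], p["w"], 0.0)
    else:
        vals = rng.normal(loc=p["mean"], scale=p["sd"], size=n)
    return vals.astype(dtype, copy=False)


def _row_subset_mask(n_rows: int, n_cols: int, K: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with a uniformly random K-subset of columns True per row."""
    if K > n_cols:
        raise ValueError(f"K={K} exceeds number of columns {n_cols}")
    if K == n_cols:
        return np.ones((n_rows, n_cols), dtype=bool)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for i in range(n_rows):
        mask[i, rng.choice(n_cols, size=K, replace=False)] = True
    return mask


def dilute_mask(N: int, K: int, seed: int | np.random.Generator) -> np.ndarray:
    """Boolean N x N mask with exactly ``K`` True entries per row.

    Columns are chosen uniformly at random without replacement, row by row
    (exact in-degree, not Bernoulli K/N). ``K == N`` gives the all-True mask.
    """
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _row_subset_mask(N, N, K, rng)


def sample_weights(spec: WeightSpec, seed: int, dtype=np.float64) -> WeightMatrix:
    """Sample a weight matrix with exactly ``K`` nonzero entries per row.

    Nonzero entries are i.i.d. from the family with mean ``J0/sqrt(K)`` and
    variance ``g^2/K^nu``. Self-couplings are sampled like any other entry.
    Note the binary family stores a structural mask in ``meta['structure']``
    since a drawn value can be exactly 0.
    """
    rng = np.random.default_rng(seed)
    N, K = spec.N, spec.K
    J = np.zeros((N, N), dtype=dtype)
    meta: dict = {}
    if K == N:
        J[:] = _draw_values(spec, N * N, rng, dtype).reshape(N, N)
    else:
        mask = dilute_mask(N, K, rng)
        J[mask] = _draw_values(spec, N * K, rng, dtype)
        if spec.family == "binary":
            meta["structure"] = mask
    return WeightMatrix(values=J, spec=spec, seed=seed, meta=meta)


def build_ei_matrix(
    J: Mapping[str, float],
    NE: int,
    NI: int,
    K: int,
    *,
    g: float,
    nu: float = 0.5,
    family: str = "gamma",
    seed: int = 0,
    dtype=np.float64,
    block_variance: str = "proportional",
) -> WeightMatrix:
    """Signed block connectivity for a two-population E-I network.

    ``J`` maps block names ``EE, EI, IE, II`` (postsynaptic-presynaptic) to
    nonnegative coupling scales ``J_ab``; block ``ab`` weights have mean
    ``J_ab/sqrt(K)``. Each unit receives exactly ``K`` nonzero weights from
    each population. In the returned matrix, excitatory (first ``NE``)
    columns carry ``+`` sign and inhibitory columns ``-`` sign, so the
    recurrent input is ``W @ phi``.

    ``block_variance`` fixes how the single shared ``g`` sets the per-block
    weight variance:

    * ``"proportional"`` (default): variance ``g^2 * J_ab / K**nu``. For the
      gamma family this makes the scale parameter ``theta = g^2 K**(1/2-nu)``
      identical across blocks (block shape proportional to ``J_ab``), i.e. a
      stronger coupling scale means proportionally more of the same unit
      synaptic weight, and the summed input from each presynaptic population
      retains a single gamma scale.
    * ``"shared"``: flat variance ``g^2 / K**nu`` in every block.

    A block scale of exactly 0 yields a zero block.
    """
    if block_variance not in ("proportional", "shared"):
        raise ValueError("block_variance must be 'proportional' or 'shared'")
    missing = {"EE", "EI", "IE", "II"} - set(J)
    if missing:
        raise ValueError(f"missing block scales: {sorted(missing)}")
    if any(J[b] < 0 for b in ("EE", "EI", "IE", "II")):
        raise ValueError("block coupling scales must be nonnegative")
    if K > NE or K > NI:
        raise ValueError("in-degree K must not exceed either population size")

    N = NE + NI
    rng = np.random.default_rng(seed)
    W = np.zeros((N, N), dtype=dtype)
    labels = np.array(["E"] * NE + ["I"] * NI)
    row_sl = {"E": slice(0, NE), "I": slice(NE, N)}
    col_sl = {"E": slice(0, NE), "I": slice(NE, N)}
    for block, sign in (("EE", 1.0), ("EI", -1.0), ("IE", 1.0), ("II", -1.0)):
        post, pre = block[0], block[1]
        n_post = NE if post == "E" else NI
        n_pre = NE if pre == "E" else NI
        sub = np.zeros((n_post, n_pre), dtype=dtype)
        if J[block] > 0:
            g_eff = g * np.sqrt(J[block]) if block_variance == "proportional" else g
            spec = WeightSpec(family=family, J0=J[block], g=g_eff, nu=nu, K=K, N=n_pre)
            if K == n_pre:
                sub[:] = _draw_values(spec, n_post * n_pre, rng, dtype).reshape(n_post, n_pre)
            else:
                mask = _row_subset_mask(n_post, n_pre, K, rng)
                sub[mask] = _draw_values(spec, n_post * K, rng, dtype)
        W[row_sl[post], col_sl[pre]] = sign * sub
    return WeightMatrix(
        values=W,
        spec=None,
        seed=seed,
        labels=labels,
        meta={"J": dict(J), "g": g, "nu": nu, "family": family, "K": K,
              "NE": NE, "NI": NI, "block_variance": block_variance},
    )
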