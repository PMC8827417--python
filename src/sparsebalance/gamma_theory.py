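"""Closed-form theory for gamma-weight networks with Heaviside units.

With nonzero weights J ~ gamma(kappa, theta), where

    kappa = (J0^2 / g^2) * K**(nu - 1),   theta = (g^2 / J0) * K**(1/2 - nu),

the recurrent input eta = sum of the f*K weights of the currently active
inputs is itself gamma distributed (sums of gammas with a shared scale are
gamma):

    eta ~ gamma(alpha, theta),  alpha = f * K * kappa,

with mean ``J0 * f * sqrt(K)`` and variance ``g^2 * f * K**(1 - nu)``.
Averaging the dynamics over units and time gives the balance relation

    x_bar = I0 - J0 * f * sqrt(K).

The shape parameter alpha controls Gaussianity of the input: a gamma with
shape >~ 20 is close to normal. In the high-variance regime (nu = 1/2,
f ~ 1/sqrt(K)) alpha is K-independent and order 1, so the input stays
non-Gaussian at any K; in the low-variance regime (nu = 1, f ~ K^0) alpha
grows like K and the input becomes Gaussian.

These relations are exact only for Heaviside rates (active inputs all fire
at 1); for other nonlinearities they are approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import WeightSpec, family_params

__all__ = [
    "GammaPrediction",
    "eta_distribution_params",
    "balance_relation",
    "predicted_f",
    "eta_shape_diagnostic",
    "predict",
]

GAUSSIAN_SHAPE_THRESHOLD = 20.0


@dataclass(frozen=True)
class GammaPrediction:
    """Analytic parameters of the recurrent-input distribution."""

    kappa: float
    theta: float
    alpha: float
    eta_mean: float
    eta_var: float
    x_bar_pred: float
    f: float


def eta_distribution_params(f: float, spec: WeightSpec) -> tuple[float, float]:
    """(alpha, theta) of the recurrent-input distribution eta ~ gamma(alpha, theta).

    Requires the gamma weight family and 0 < f <= 1. ``f = 0`` means a
    degenerate input identically 0 and is signaled as an error.
    """
    if spec.family != "gamma":
        raise ValueError("eta closure holds only for the gamma weight family")
    if f == 0:
        raise ValueError("f = 0: eta distribution degenerate at 0")
    if not (0 < f <= 1):
        raise ValueError("f must lie in (0, 1]")
    p = family_params(spec)
    alpha = f * spec.K * p["kappa"]
    return alpha, p["theta"]


def balance_relation(f: float, J0: float, K: int, I0: float) -> float:
    """Predicted mean total current x_bar = I0 - J0 * f * sqrt(K)."""
    return I0 - J0 * f * np.sqrt(K)


def predicted_f(x_bar: float, J0: float, K: int, I0: float) -> float:
    """Inverse of the balance relation: f = (I0 - x_bar) / (J0 * sqrt(K))."""
    return (I0 - x_bar) / (J0 * np.sqrt(K))


def eta_shape_diagnostic(f: float, spec: WeightSpec) -> tuple[float, bool]:
    """Shape parameter alpha = f*K*kappa and an approximately-Gaussian flag.

    The flag is set when alpha >= 20 (gamma close to normal).
    """
    alpha, _ = eta_distribution_params(f, spec)
    return alpha, bool(alpha >= GAUSSIAN_SHAPE_THRESHOLD)


def predict(f: float, spec: WeightSpec, I0: float) -> GammaPrediction:
    """Full analytic prediction bundle at a measured (or assumed) sparsity f."""
    alpha, theta = eta_distribution_params(f, spec)
    p = family_params(spec)
    eta_mean = alpha * theta
    eta_var = alpha * theta**2
    return GammaPrediction(
        kappa=p["kappa"],
        theta=theta,
        alpha=alpha,
        eta_mean=eta_mean,
        eta_var=eta_var,
        x_bar_pred=balance_relation(f, spec.J0, spec.K, I0),
        f=f,
    )
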