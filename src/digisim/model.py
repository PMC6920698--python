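"""Rate laws of the digitalizer reaction network.

Single source of truth for the equations used by the deterministic and
stochastic simulators:

    dmR/dt = beta_R + alpha_R * hill_activation(tf_a; K_TF, n_act)
             - (delta_mR + mu) * mR - k_pair * mR * mS
    dmS/dt = alpha_S * hill_repression(R; K_R, n_rep)
             - (delta_mS + mu) * mS - k_pair * mR * mS
    dR/dt  = lambda_R * mR - (delta_R + mu) * R
    dG/dt  = lambda_G * mR - (delta_G + mu) * G

The bimolecular pairing term removes one mR and one mS per event
(co-degradation), which is what makes the two RNA pools mutually
exclusive.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, SystemState

__all__ = [
    "hill_activation",
    "hill_repression",
    "derivatives",
    "rhs",
    "analytic_steady_state_unpaired",
]


def _check_hill_args(x, K, n) -> None:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("concentration must be finite and >= 0")
    if not np.isfinite(K) or K <= 0:
        raise ValueError("K must be finite and > 0")
    if not np.isfinite(n) or n < 1:
        raise ValueError("Hill coefficient must be finite and >= 1")


def hill_activation(x, K: float, n: float):
    """Activating Hill input x^n / (K^n + x^n), in [0, 1].

    Monotone non-decreasing in ``x``; equals 1/2 at ``x == K``.
    """
    _check_hill_args(x, K, n)
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        r = (x / K) ** n
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return float(out) if out.ndim == 0 else out


def hill_repression(r, K: float, n: float):
    """Repressive Hill input K^n / (K^n + r^n) = 1 - hill_activation(r, K, n)."""
    _check_hill_args(r, K, n)
    r = np.asarray(r, dtype=float)
    with np.errstate(over="ignore"):
        q = (r / K) ** n
        out = np.where(np.isinf(q), 0.0, 1.0 / (1.0 + q))
    return float(out) if out.ndim == 0 else out


def rhs(y: np.ndarray, tf_a: float, p: ModelParams) -> np.ndarray:
    """Raw right-hand side over the species vector ``y = (mR, mS, R, G)``.

    No validation; used inside ODE solvers where ``y`` may transiently dip
    a rounding error below zero.
    """
    mR, mS, R, G = y
    pair = p.k_pair * mR * mS
    act = hill_activation(max(tf_a, 0.0), p.K_TF, p.n_act)
    rep = hill_repression(max(R, 0.0), p.K_R, p.n_rep)
    return np.array(
        [
            p.beta_R + p.alpha_R * act - (p.delta_mR + p.mu) * mR - pair,
            p.alpha_S * rep - (p.delta_mS + p.mu) * mS - pair,
            p.lambda_R * mR - (p.delta_R + p.mu) * R,
            p.lambda_G * mR - (p.delta_G + p.mu) * G,
        ]
    )


def derivatives(state: SystemState, params: ModelParams) -> np.ndarray:
    """Rate vector (dmR, dmS, dR, dG)/dt at ``state``.

    Raises if any species is negative beyond numerical tolerance (the
    SystemState constructor already enforces this for constructed states).
    """
    out = rhs(state.vector(), state.tf_a, params)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite derivative; check parameters/state")
    return out


def analytic_steady_state_unpaired(
    params: ModelParams, tf_a: float
) -> SystemState:
    """Closed-form steady state of the cascade when pairing is off.

    With ``k_pair = 0`` the network is a feed-forward cascade and the fixed
    point factorises::

        mR* = (beta_R + alpha_R * hill_activation(tf_a)) / (delta_mR + mu)
        R*  = lambda_R * mR* / (delta_R + mu)
        G*  = lambda_G * mR* / (delta_G + mu)
        mS* = alpha_S * hill_repression(R*) / (delta_mS + mu)

    Used throughout the test-suite as the independent oracle for the
    numerical steady-state machinery.
    """
    if params.k_pair != 0:
        raise ValueError("closed form requires k_pair == 0")
    decays = (
        params.delta_mR + params.mu,
        params.delta_mS + params.mu,
        params.delta_R + params.mu,
        params.delta_G + params.mu,
    )
    if min(decays) <= 0:
        raise ValueError("every effective decay rate (delta + mu) must be > 0")
    mR = (params.beta_R + params.alpha_R * hill_activation(tf_a, params.K_TF, params.n_act)) / decays[0]
    R = params.lambda_R * mR / decays[2]
    G = params.lambda_G * mR / decays[3]
    mS = params.alpha_S * hill_repression(R, params.K_R, params.n_rep) / decays[1]
    return SystemState(tf_a=tf_a, mR=mR, mS=mS, R=R, G=G)
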