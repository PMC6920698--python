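"""Parameter estimation from summarised fluorescence time courses.

Fits selected kinetic parameters of the switch model to per-condition
median fluorescence by least squares on the log scale,

    loss(theta) = sum_(dose,time) [log m_model(t, d; theta) - log m_obs]^2,
    m_model = gain * omega * G_ode(t, d) + median(autofluorescence),

with a bounded local optimiser (L-BFGS-B) restarted from log-uniform
random points inside the box.  The search is log-parameterised because all
rates are positive and span decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cytometry import DEFAULT_OMEGA, NoiseModel
from .params import ModelParams

__all__ = ["FitResult", "fit_parameters", "IdentifiabilityError"]

_PARAM_NAMES = tuple(ModelParams().as_dict().keys())
#: gain and lambda_G enter the predicted median only through their product
#: gain * lambda_G (G_ode is proportional to lambda_G), so fitting both is
#: refused outright.
_CONFOUNDED = frozenset({"gain", "lambda_G"})


class IdentifiabilityError(ValueError):
    """Raised when the requested free-parameter set is not identifiable."""


@dataclass(frozen=True)
class FitResult:
    estimates: dict
    loss: float
    n_starts: int
    converged: tuple
    best_start: int
    start_losses: tuple = ()


#: solver tolerance used inside the fit objective; looser than the
#: simulation default because the log-median residuals are noise-limited.
_FIT_RTOL = 1e-6
_FIT_ATOL = 1e-8


def _predict_medians(
    fixed: ModelParams, free_values: dict, doses, times, gain, omega, autofluor_median
) -> np.ndarray:
    from ._fastode import integrate_constant_input
    from .ssa import _params_vector

    p = fixed.replace(**{k: v for k, v in free_values.items() if k != "gain"})
    g = free_values.get("gain", gain)
    pv = _params_vector(p)
    times = np.asarray(times, dtype=float)
    grid = np.unique(times[times > 0])
    out = np.empty((len(doses), times.size))
    # uninduced steady state (shared by all doses): settle well past the
    # slowest timescale, then hold
    relax = max(10.0 / min(p.delta_R + p.mu, p.delta_G + p.mu, 1.0), 500.0)
    st0, ok = integrate_constant_input(
        pv, 0.0, np.zeros(4), np.array([relax]), _FIT_RTOL, _FIT_ATOL
    )
    if not ok:
        raise RuntimeError("relaxation to the uninduced steady state failed")
    init = st0[-1]
    for i, d in enumerate(doses):
        states, ok = integrate_constant_input(
            pv, float(d), init.copy(), grid, _FIT_RTOL, _FIT_ATOL
        )
        if not ok:
            raise RuntimeError(f"integration failed at dose {d}")
        for j, t in enumerate(times):
            G = init[3] if t == 0 else states[np.argmin(np.abs(grid - t)), 3]
            out[i, j] = g * omega * G + autofluor_median
    return out


def fit_parameters(
    observed: pd.DataFrame,
    free,
    fixed: ModelParams,
    bounds: dict | None = None,
    noise: NoiseModel | None = None,
    omega: float = DEFAULT_OMEGA,
    n_starts: int = 10,
    seed: int = 0,
    construct: str = "digitalized",
) -> FitResult:
    """Recover model parameters from a summarised flow experiment.

    Parameters
    ----------
    observed : DataFrame
        Summary table (as produced by :func:`digisim.stats.summarize`)
        holding at least two distinct times and two distinct doses for the
        fitted construct.
    free : iterable of str
        Names of parameters to fit; ModelParams field names plus the
        special name ``"gain"``.  ``{"gain", "lambda_G"}`` together is
        refused (their product is the only identifiable combination).
    fixed : ModelParams
        Values of all non-free parameters (and starting scale of free
        ones).
    bounds : dict, optional
        ``name -> (lo, hi)``; defaults to a factor-30 box around the value
        in ``fixed`` (or around the noise-model gain).
    """
    noise = noise if noise is not None else NoiseModel()
    free = tuple(free)
    unknown = set(free) - set(_PARAM_NAMES) - {"gain"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if _CONFOUNDED <= set(free):
        raise IdentifiabilityError(
            "gain and lambda_G are perfectly confounded (only their product "
            "enters the predicted median); fit at most one of them"
        )
    sub = observed[observed["construct"] == construct]
    doses = np.asarray(sorted(sub["dose_nM"].unique()), dtype=float)
    times = np.asarray(sorted(sub["time_min"].unique()), dtype=float)
    if doses.size < 2 or times.size < 2:
        raise ValueError("observed data must cover >= 2 doses and >= 2 times")
    obs = (
        sub.pivot_table(index="dose_nM", columns="time_min", values="median_au")
        .loc[doses, times]
        .to_numpy()
    )
    if np.any(~np.isfinite(obs)) or np.any(obs <= 0):
        raise ValueError("observed medians must be finite and positive")
    log_obs = np.log(obs)
    autofluor_median = noise.autofluor_median()

    def loss_of(values: dict) -> float:
        pred = _predict_medians(
            fixed, values, doses, times, noise.gain, omega, autofluor_median
        )
        return float(np.sum((np.log(np.maximum(pred, 1e-300)) - log_obs) ** 2))

    if not free:
        return FitResult(
            estimates={}, loss=loss_of({}), n_starts=0, converged=(),
            best_start=-1,
        )

    def default_bound(name: str):
        centre = noise.gain if name == "gain" else getattr(fixed, name)
        if centre <= 0:
            raise ValueError(
                f"no default bounds for {name!r} (fixed value is 0); "
                "pass explicit bounds"
            )
        return (centre / 30.0, centre * 30.0)

    bounds = dict(bounds or {})
    box = np.array([bounds.get(name, default_bound(name)) for name in free])
    if np.any(box <= 0):
        raise ValueError("bounds must be positive")
    log_box = np.log(box)

    def objective(log_theta: np.ndarray) -> float:
        values = {name: float(np.exp(v)) for name, v in zip(free, log_theta)}
        try:
            return loss_of(values)
        except Exception:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [
        np.array([
            np.clip(np.log(noise.gain if n == "gain" else getattr(fixed, n)),
                    lo, hi) if getattr(fixed, n, noise.gain) > 0 else 0.5 * (lo + hi)
            for n, (lo, hi) in zip(free, log_box)
        ])
    ]
    while len(starts) < n_starts:
        starts.append(rng.uniform(log_box[:, 0], log_box[:, 1]))

    results = []
    for x0 in starts[:n_starts]:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(lo, hi) for lo, hi in log_box],
        )
        results.append(res)
    losses = [float(r.fun) for r in results]
    conv = [bool(r.success) for r in results]
    if not any(conv):
        diag = "; ".join(
            f"start {i}: {r.message} (loss={losses[i]:.3g})"
            for i, r in enumerate(results)
        )
        raise RuntimeError(f"all optimiser starts failed: {diag}")
    best = int(np.argmin([l if c else np.inf for l, c in zip(losses, conv)]))
    est = {
        name: float(np.exp(v)) for name, v in zip(free, results[best].x)
    }
    return FitResult(
        estimates=est,
        loss=losses[best],
        n_starts=n_starts,
        converged=tuple(conv),
        best_start=best,
        start_losses=tuple(losses),
    )
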