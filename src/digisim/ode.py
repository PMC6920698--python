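"""Deterministic simulation and dose-response analysis of the switch.

Steady states are found by long integration followed by Newton refinement,
with continuation seeding across a dose grid so that coexisting branches
(if any) are discoverable from the OFF and ON directions separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, root

from .model import analytic_steady_state_unpaired, rhs
from .params import InducerProtocol, ModelParams, SystemState

__all__ = [
    "TimeCourse",
    "DoseResponseCurve",
    "ResponseMetrics",
    "SweepResult",
    "simulate_ode",
    "steady_state",
    "dose_response",
    "response_metrics",
    "repression_sweep",
    "hysteresis_scan",
    "deinduction",
    "DegenerateCurveError",
    "SteadyStateError",
]

_RTOL = 1e-8
_ATOL = 1e-10


class SteadyStateError(RuntimeError):
    """Raised when steady-state iteration does not converge."""


class DegenerateCurveError(ValueError):
    """Raised for a flat dose-response curve where metrics are undefined."""


@dataclass(frozen=True)
class TimeCourse:
    """One deterministic trajectory: a time grid and the state at each time."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 4), columns (mR, mS, R, G)
    protocol: InducerProtocol

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if y.shape != (t.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    def species(self, name: str) -> np.ndarray:
        return self.states[:, ("mR", "mS", "R", "G").index(name)]

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_vector(
            self.states[i], tf_a=self.protocol.level_at(self.times[i])
        )


@dataclass(frozen=True)
class DoseResponseCurve:
    doses: np.ndarray
    steady: list  # SystemState per dose
    converged: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if len(self.steady) != d.size:
            raise ValueError("one steady state per dose required")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "converged", np.asarray(self.converged, bool))

    def readout(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.steady])


@dataclass(frozen=True)
class ResponseMetrics:
    """Scalar descriptors of one monotone dose-response curve.

    ``transition_width`` is the dose span between 10% and 90% of the
    dynamic range, measured on the linear dose axis; ``effective_hill`` is
    the exponent of a least-squares Hill fit.
    """

    off_level: float
    on_level: float
    fold_change: float
    ec50: float
    transition_width: float
    effective_hill: float


@dataclass(frozen=True)
class SweepResult:
    strength_grid: np.ndarray
    curves: list  # DoseResponseCurve per strength
    metrics: list  # ResponseMetrics per strength
    phase_pairs: np.ndarray  # shape (n_strengths, n_doses, 2): (mR*, mS*)


def simulate_ode(
    params: ModelParams,
    protocol: InducerProtocol,
    t_grid: np.ndarray,
    init: SystemState | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> TimeCourse:
    """Integrate the ODE model over ``t_grid`` under a piecewise protocol.

    Each constant-input segment is integrated separately so the solver
    never steps across an input discontinuity.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    init = init if init is not None else SystemState()
    y = init.vector()
    out = np.empty((t_grid.size, 4))
    written = 0
    if t_grid[0] == 0.0:
        out[0] = y
        written = 1
    t0 = 0.0
    for a, b, level in protocol.segments(t0, float(t_grid[-1])):
        t_eval = t_grid[(t_grid > a) & (t_grid <= b)]
        t_eval_full = np.unique(np.concatenate([t_eval, [b]]))
        sol = solve_ivp(
            lambda t, yy: rhs(yy, level, params),
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval_full,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SteadyStateError(
                f"ODE solver failed on segment [{a}, {b}] (tf_a={level}): {sol.message}"
            )
        if t_eval.size:
            keep = np.isin(sol.t, t_eval)
            out[written : written + t_eval.size] = sol.y.T[keep]
            written += t_eval.size
        y = np.clip(sol.y[:, -1], 0.0, None)
    states = np.clip(out, 0.0, None)
    return TimeCourse(times=t_grid, states=states, protocol=protocol)


def steady_state(
    params: ModelParams,
    tf_a: float,
    init: SystemState | None = None,
    t_block: float = 2000.0,
    max_blocks: int = 50,
) -> SystemState:
    """Steady state under constant input, from a given initial condition.

    Long LSODA integration in blocks until the derivative norm is small,
    then Newton (hybr) refinement on the right-hand side.  The initial
    condition is honoured deliberately so that coexisting stable branches
    can be reached by continuation.
    """
    decays = min(
        params.delta_mR + params.mu,
        params.delta_mS + params.mu,
        params.delta_R + params.mu,
        params.delta_G + params.mu,
    )
    if decays <= 0:
        raise SteadyStateError("all effective decay rates (delta + mu) must be > 0")
    y = (init.vector() if init is not None else np.zeros(4))
    f = lambda yy: rhs(yy, tf_a, params)  # noqa: E731
    scale = 1.0
    for _ in range(max_blocks):
        sol = solve_ivp(
            lambda t, yy: f(yy), (0.0, t_block), y, method="LSODA",
            rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        scale = 1.0 + float(np.max(np.abs(y)))
        if np.max(np.abs(f(y))) <= 1e-6 * scale:
            break
    else:
        raise SteadyStateError("no steady state after bounded integration work")
    res = root(f, y, method="hybr", tol=1e-13)
    if res.success and np.all(res.x > -1e-9):
        y = np.clip(res.x, 0.0, None)
    y = _polish_slaved(y, tf_a, params, f)
    if np.max(np.abs(f(y))) > 1e-9 * scale:
        raise SteadyStateError("derivative norm above tolerance after refinement")
    return SystemState.from_vector(y, tf_a=tf_a)


def _polish_slaved(y: np.ndarray, tf_a: float, p: ModelParams, f) -> np.ndarray:
    """Recompute the components slaved to mR from their exact balances.

    At a fixed point, R, G and mS follow algebraically from mR; the Newton
    step resolves them only to the norm of the largest component, which can
    leave tiny species (e.g. mS when P2 is fully repressed) with poor
    *relative* accuracy.  Substituting the exact relations restores
    per-component precision without moving mR."""
    from .model import hill_repression

    mR = y[0]
    R = p.lambda_R * mR / (p.delta_R + p.mu)
    G = p.lambda_G * mR / (p.delta_G + p.mu)
    mS = (
        p.alpha_S * hill_repression(R, p.K_R, p.n_rep)
        / (p.delta_mS + p.mu + p.k_pair * mR)
    )
    polished = np.array([mR, mS, R, G])
    # keep the polish only if it does not degrade the residual
    if np.max(np.abs(f(polished))) <= max(np.max(np.abs(f(y))), 1e-300) * 4.0 + 1e-12:
        return polished
    return y


def _on_seed(params: ModelParams, dose: float) -> SystemState:
    """High-expression initial condition used for down-continuation."""
    p0 = params.replace(k_pair=0.0, alpha_S=0.0)
    s = analytic_steady_state_unpaired(p0, dose)
    return SystemState(tf_a=dose, mR=s.mR, mS=0.0, R=s.R, G=s.G)


def dose_response(
    params: ModelParams,
    doses: np.ndarray,
    direction: str = "up",
    init: SystemState | None = None,
) -> DoseResponseCurve:
    """Steady-state curve over a dose grid with continuation seeding.

    ``direction='up'`` walks the grid from low to high dose seeding each
    solve with the previous steady state (OFF-branch continuation);
    ``'down'`` walks high to low seeded from a fully ON state.  On a
    monostable system the two agree.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    order = range(doses.size) if direction == "up" else range(doses.size - 1, -1, -1)
    if init is None:
        init = SystemState() if direction == "up" else _on_seed(params, doses[-1])
    steady: list[SystemState | None] = [None] * doses.size
    converged = np.zeros(doses.size, bool)
    seed = init
    for i in order:
        try:
            st = steady_state(params, doses[i], init=seed)
        except SteadyStateError as e:
            raise SteadyStateError(f"dose index {i} (dose={doses[i]}): {e}") from e
        steady[i] = st
        converged[i] = True
        seed = st
    return DoseResponseCurve(doses=doses, steady=steady, converged=converged)


def _hill_curve(d, off, on, ec50, h):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(d > 0, (d / ec50) ** h, 0.0)
    return off + (on - off) * a / (1.0 + a)


def response_metrics(curve: DoseResponseCurve, readout: str = "mR") -> ResponseMetrics:
    """EC50, 10-90% transition width, fold change and effective Hill slope.

    The curve must be monotone (non-decreasing) in the chosen readout;
    level crossings are located by linear interpolation on the dose axis.
    ``off_level`` is taken at the dose-0 point (the curve must include
    dose 0).
    """
    if not np.all(curve.converged):
        raise ValueError("curve contains unconverged points")
    if curve.doses[0] != 0.0:
        raise ValueError("curve must include dose 0 for the OFF level")
    y = curve.readout(readout)
    off, on = float(y[0]), float(y[-1])
    rng = on - off
    if abs(rng) < 1e-12:
        raise DegenerateCurveError("flat dose-response curve; metrics undefined")
    if np.any(np.diff(y) < -1e-9 * abs(rng)):
        raise ValueError("readout is not monotone non-decreasing in dose")
    y_mono = np.maximum.accumulate(y)

    def crossing(level: float) -> float:
        return float(np.interp(level, y_mono, curve.doses))

    ec50 = crossing(off + 0.5 * rng)
    width = crossing(off + 0.9 * rng) - crossing(off + 0.1 * rng)
    try:
        popt, _ = curve_fit(
            lambda d, ec, h: _hill_curve(d, off, on, ec, h),
            curve.doses,
            y,
            p0=(max(ec50, 1e-9), 2.0),
            bounds=([1e-12, 0.05], [np.inf, 100.0]),
            maxfev=10000,
        )
        eff_hill = float(popt[1])
    except RuntimeError:
        eff_hill = float("nan")
    fold = on / off if off > 0 else float("inf")
    return ResponseMetrics(
        off_level=off,
        on_level=on,
        fold_change=fold,
        ec50=ec50,
        transition_width=max(width, 0.0),
        effective_hill=eff_hill,
    )


def repression_sweep(
    params: ModelParams,
    strengths: np.ndarray,
    doses: np.ndarray,
    readout: str = "mR",
) -> SweepResult:
    """Dose-response curves over a grid of mutual-repression strengths.

    Each strength ``s`` multiplies ``k_pair`` and ``alpha_S`` and divides
    ``K_R`` (both inhibitory arms scaled jointly), then the full up-branch
    dose response and its metrics are computed; (mR*, mS*) pairs are
    collected for phase-plane views.
    """
    strengths = np.asarray(strengths, dtype=float)
    if np.any(strengths <= 0):
        raise ValueError("strengths must be > 0")
    curves, metrics = [], []
    phase = np.empty((strengths.size, np.asarray(doses).size, 2))
    for i, s in enumerate(strengths):
        ps = params.scaled_repression(float(s))
        curve = dose_response(ps, doses, direction="up")
        curves.append(curve)
        metrics.append(response_metrics(curve, readout=readout))
        phase[i, :, 0] = curve.readout("mR")
        phase[i, :, 1] = curve.readout("mS")
    return SweepResult(
        strength_grid=strengths, curves=curves, metrics=metrics, phase_pairs=phase
    )


def hysteresis_scan(
    params: ModelParams,
    doses: np.ndarray,
    readout: str = "mR",
    rel_threshold: float = 1e-3,
) -> dict:
    """Compare up- and down-continuation branches over a dose grid.

    The system is flagged bistable iff the largest branch gap exceeds
    ``rel_threshold`` times the dynamic range of the up branch.
    """
    up = dose_response(params, doses, direction="up")
    down = dose_response(params, doses, direction="down")
    yu, yd = up.readout(readout), down.readout(readout)
    gap = float(np.max(np.abs(yu - yd)))
    dyn = float(np.max(yu) - np.min(yu))
    bistable = dyn > 0 and gap > rel_threshold * dyn
    return {
        "bistable": bool(bistable),
        "max_branch_gap": gap,
        "dynamic_range": dyn,
        "up": up,
        "down": down,
    }


def deinduction(
    params: ModelParams,
    t_on: float,
    t_total: float,
    tf_high: float = 1000.0,
    mu: float | None = None,
    n_points: int = 400,
) -> dict[str, TimeCourse]:
    """Induce fully, then remove inducer; compare with the sRNA-free device.

    Returns time courses for the digitalized construct and its
    non-digitalized counterpart (``alpha_S = 0``) under the identical step
    protocol and solver settings.
    """
    if not t_on < t_total:
        raise ValueError("t_on must be < t_total")
    p = params if mu is None else params.replace(mu=mu)
    protocol = InducerProtocol.step_off(tf_high, t_on)
    grid = np.unique(np.concatenate([
        np.linspace(0.0, t_total, n_points), [t_on]
    ]))
    grid = grid[grid > 0]
    grid = np.concatenate([[0.0], grid]) if grid[0] != 0.0 else grid
    out = {}
    for label, pc in (("digitalized", p), ("non_digitalized", p.replace(alpha_S=0.0))):
        out[label] = simulate_ode(pc, protocol, grid)
    return out
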