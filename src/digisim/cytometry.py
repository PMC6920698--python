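"""Synthetic flow-cytometry and plate-reader data generation.

Turns simulated per-cell G (reporter) molecule counts into
fluorescence-like event tables with the statistical structure of benchmark
expression measurements: three constructs (digitalized, non-digitalized,
promoterless autofluorescence control), a dose x time design, lognormal
cell-to-cell (extrinsic) noise and a lognormal autofluorescence background.

Per-cell fluorescence (arbitrary units)::

    AU = gain * G * exp(eps) + A,   eps ~ Normal(0, sigma_ext),
                                    A   ~ Lognormal(autofluor_mu, autofluor_sigma)

clipped at the instrument floor.  The promoterless control produces G = 0
and therefore pure autofluorescence; its upper quantile defines the
"no-fluorescence" gate used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ode import simulate_ode
from .params import (
    CONSTRUCTS,
    InducerProtocol,
    ModelParams,
    SystemState,
    construct_params,
)
from .ssa import StochasticConfig, simulate_population

__all__ = [
    "NoiseModel",
    "EVENT_COLUMNS",
    "fluorescence_model",
    "generate_flow_experiment",
    "generate_platereader",
    "write_events_csv",
    "read_events_csv",
]

EVENT_COLUMNS = ("cell_id", "construct", "dose_nM", "time_min",
                 "fluorescence_au", "alive")

#: effective reporter molecules per nM for the cytometry pipeline (a
#: multi-copy plasmid reporter contributes a few molecules per nM-equivalent
#: of the single-circuit model).
DEFAULT_OMEGA = 3.0


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-layer noise parameters.

    gain: AU per reporter molecule; sigma_ext: SD of the lognormal
    extrinsic (cell-to-cell) factor in log-units; autofluor_mu /
    autofluor_sigma: log-mean and log-SD of the lognormal autofluorescence
    background (AU); floor: instrument baseline below which no event is
    recorded.
    """

    gain: float = 1.0
    sigma_ext: float = 0.3
    autofluor_mu: float = float(np.log(50.0))
    autofluor_sigma: float = 0.4
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.sigma_ext < 0 or self.autofluor_sigma < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    def autofluor_median(self) -> float:
        return float(np.exp(self.autofluor_mu))


def fluorescence_model(
    G: np.ndarray, noise: NoiseModel, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Map per-cell reporter counts to fluorescence AU (seeded)."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("molecule counts must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eps = rng.normal(0.0, noise.sigma_ext, size=G.shape) if noise.sigma_ext > 0 else 0.0
    if noise.autofluor_sigma > 0:
        A = rng.lognormal(noise.autofluor_mu, noise.autofluor_sigma, size=G.shape)
    else:
        A = np.full(G.shape, np.exp(noise.autofluor_mu))
    au = noise.gain * G * np.exp(eps) + A
    return np.maximum(au, noise.floor)


def generate_flow_experiment(
    doses,
    times,
    constructs=CONSTRUCTS,
    base_params: ModelParams | None = None,
    n_events: int = 25_000,
    omega: float = DEFAULT_OMEGA,
    noise: NoiseModel | None = None,
    seed: int = 0,
    mode: str = "ode",
    init_steady: bool = True,
) -> pd.DataFrame:
    """Generate a full synthetic flow-cytometry event table.

    For every (construct, dose, time) condition, ``n_events`` per-cell
    reporter counts are simulated — by the exact SSA (``mode='ssa'``) or by
    the ODE-mean shortcut with Poisson molecule noise (``mode='ode'``, the
    default for large event counts) — and passed through the fluorescence
    noise model.  With ``init_steady`` (default) cells start from the
    uninduced deterministic steady state, so the t=0 snapshot is the basal
    population, and induction to ``dose`` happens at t=0.

    Deterministic for a given ``seed``; condition order does not matter.
    """
    if noise is None:
        noise = NoiseModel()
    if mode not in ("ode", "ssa"):
        raise ValueError("mode must be 'ode' or 'ssa'")
    base = base_params
    times = np.asarray(sorted(set(float(t) for t in times)))
    doses = np.asarray(sorted(set(float(d) for d in doses)))
    frames = []
    for construct in constructs:
        p = construct_params(construct, base)
        for i_dose, dose in enumerate(doses):
            ss = np.random.SeedSequence(
                (int(seed), CONSTRUCTS.index(construct), i_dose)
            )
            rng = np.random.default_rng(ss)
            init = _uninduced_init(p) if init_steady else SystemState()
            if mode == "ode":
                counts = _ode_counts_with_init(p, dose, times, omega, n_events, rng, init)
                alive = np.ones(n_events, dtype=bool)
                for j, t in enumerate(times):
                    au = fluorescence_model(counts[j], noise, rng)
                    frames.append(_frame(construct, dose, t, au, alive))
            else:
                cfg = StochasticConfig(
                    omega=omega, n_cells=n_events,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                    t_max=float(times[-1]) if times[-1] > 0 else 1.0,
                    snapshot_times=tuple(times),
                )
                snaps = simulate_population(
                    p, cfg, InducerProtocol.constant(dose),
                    init=init, construct=construct, dose=dose,
                )
                for snap in snaps:
                    au = fluorescence_model(snap.species("G"), noise, rng)
                    frames.append(
                        _frame(construct, dose, snap.time, au, snap.alive)
                    )
    table = pd.concat(frames, ignore_index=True)
    return table


def _uninduced_init(p: ModelParams) -> SystemState:
    from .ode import steady_state  # local import to avoid cycle at import time

    return steady_state(p, 0.0)


def _ode_counts_with_init(params, dose, times, omega, n_events, rng, init):
    grid = np.unique(np.concatenate([[1e-9], times[times > 0]]))
    tc = simulate_ode(params, InducerProtocol.constant(dose), grid, init=init)
    g_on_grid = tc.species("G")
    gvals = np.empty(times.size)
    for j, t in enumerate(times):
        gvals[j] = init.G if t == 0 else g_on_grid[np.argmin(np.abs(tc.times - t))]
    return rng.poisson(np.maximum(gvals[:, None], 0.0) * omega,
                       size=(times.size, n_events))


def _frame(construct, dose, t, au, alive):
    return pd.DataFrame(
        {
            "cell_id": np.arange(au.size),
            "construct": construct,
            "dose_nM": dose,
            "time_min": float(t),
            "fluorescence_au": au,
            "alive": np.asarray(alive, dtype=bool),
        }
    )


def generate_platereader(
    doses,
    times,
    constructs=CONSTRUCTS,
    base_params: ModelParams | None = None,
    growth_rate: float = 0.02,
    K_od: float = 2.0,
    od0: float = 0.05,
    omega: float = DEFAULT_OMEGA,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk plate-reader style table with OD600-normalised fluorescence.

    OD follows logistic growth OD(t) = K/(1 + (K/od0 - 1) e^{-r t}); bulk
    fluorescence is proportional to cell number times the mean per-cell
    signal, so the ``fluorescence_per_od`` column isolates per-cell
    expression.
    """
    if growth_rate <= 0 or K_od <= 0 or od0 <= 0:
        raise ValueError("growth parameters must be > 0")
    if noise is None:
        noise = NoiseModel()
    times = np.asarray(sorted(set(float(t) for t in times)))
    doses = np.asarray(sorted(set(float(d) for d in doses)))
    rng = np.random.default_rng(seed)
    mean_autofluor = float(
        np.exp(noise.autofluor_mu + noise.autofluor_sigma**2 / 2)
    )
    rows = []
    for construct in constructs:
        p = construct_params(construct, base_params)
        for dose in doses:
            grid = np.unique(np.concatenate([[1e-9], times[times > 0]]))
            tc = simulate_ode(p, InducerProtocol.constant(dose), grid)
            for t in times:
                g = 0.0 if t == 0 else float(
                    tc.species("G")[np.argmin(np.abs(tc.times - t))]
                )
                od = K_od / (1.0 + (K_od / od0 - 1.0) * np.exp(-growth_rate * t))
                per_cell = (
                    noise.gain * g * omega * np.exp(noise.sigma_ext**2 / 2)
                    + mean_autofluor
                )
                bulk = od * per_cell
                rows.append(
                    dict(construct=construct, dose_nM=dose, time_min=float(t),
                         od600=float(od), fluorescence=float(bulk),
                         fluorescence_per_od=float(bulk / od))
                )
    return pd.DataFrame(rows)


def write_events_csv(table: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write an event table as CSV, with optional '#' provenance header."""
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, columns=list(EVENT_COLUMNS))


def read_events_csv(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events_csv` (lossless)."""
    table = pd.read_csv(path, comment="#")
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    table["construct"] = table["construct"].astype(str)
    table["alive"] = table["alive"].astype(bool)
    return table
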