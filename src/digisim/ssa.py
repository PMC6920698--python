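"""Exact stochastic simulation (Gillespie direct method) of the switch.

The ODE rate laws are converted to propensities with a system-size factor
``omega`` (molecules per nM): concentrations x become counts n = omega*x,
zeroth-order rates are multiplied by omega and the bimolecular pairing rate
divided by omega, so propensity/omega evaluated at n = omega*x equals the
ODE flux at x.  Hill terms are kept as-is at the count level (no
elementary operator-binding reactions) — an approximation that matches the
ODE reduction.

Each cell draws its random stream from ``numpy.random.SeedSequence((seed,
cell_index))``, so populations are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import InducerProtocol, ModelParams, SystemState

__all__ = [
    "StochasticConfig",
    "PopulationSnapshot",
    "Reaction",
    "build_reactions",
    "gillespie",
    "simulate_population",
    "one_hit_survival",
]

_N_SPECIES = 4  # (mR, mS, R, G)


@dataclass(frozen=True)
class StochasticConfig:
    """Population-simulation settings.

    omega: system-size conversion (molecules per nM); n_cells: number of
    independent cells; seed: root seed of the per-cell streams; t_max:
    simulated horizon (min); snapshot_times: recording times within
    [0, t_max].
    """

    omega: float = 1.0
    n_cells: int = 500
    seed: int = 0
    t_max: float = 160.0
    snapshot_times: tuple[float, ...] = (0.0, 5.0, 20.0, 60.0, 160.0)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        ts = tuple(float(t) for t in self.snapshot_times)
        object.__setattr__(self, "snapshot_times", ts)
        if any(t < 0 or t > self.t_max for t in ts):
            raise ValueError("snapshot_times must lie within [0, t_max]")
        if list(ts) != sorted(ts):
            raise ValueError("snapshot_times must be sorted")


@dataclass(frozen=True)
class PopulationSnapshot:
    """Per-cell molecule counts of one population at one time point."""

    time: float
    counts: np.ndarray  # shape (n_cells, 4) int64, columns (mR, mS, R, G)
    alive: np.ndarray  # shape (n_cells,) bool
    construct: str = "digitalized"
    dose: float = 0.0

    def species(self, name: str) -> np.ndarray:
        return self.counts[:, ("mR", "mS", "R", "G").index(name)]


@dataclass(frozen=True)
class Reaction:
    name: str
    stoichiometry: np.ndarray  # length-4 int vector


def _reaction_stoichiometry(mu_active: bool) -> np.ndarray:
    """Stoichiometry matrix, one row per reaction channel.

    Order: P1 transcription, P2 transcription, mR decay, mS decay,
    mR-mS pairing co-degradation, R translation, G translation, R decay,
    G decay (+4 dilution channels when mu > 0).
    """
    rows = [
        (+1, 0, 0, 0),  # P1 transcription -> mR
        (0, +1, 0, 0),  # P2 transcription -> mS
        (-1, 0, 0, 0),  # mR decay
        (0, -1, 0, 0),  # mS decay
        (-1, -1, 0, 0),  # pairing: one mR and one mS co-degraded
        (0, 0, +1, 0),  # R translation
        (0, 0, 0, +1),  # G translation
        (0, 0, -1, 0),  # R decay
        (0, 0, 0, -1),  # G decay
    ]
    if mu_active:
        rows += [(-1, 0, 0, 0), (0, -1, 0, 0), (0, 0, -1, 0), (0, 0, 0, -1)]
    return np.array(rows, dtype=np.int64)


def _params_vector(p: ModelParams) -> np.ndarray:
    return np.array(
        [
            p.alpha_R, p.beta_R, p.K_TF, p.n_act,
            p.alpha_S, p.K_R, p.n_rep, p.k_pair,
            p.delta_mR, p.delta_mS, p.delta_R, p.delta_G,
            p.lambda_R, p.lambda_G, p.mu,
        ]
    )


@njit(cache=True)
def _propensities(n, pv, tf_a, omega, out):
    """Propensity of each channel at count state ``n`` (in place)."""
    mR, mS, R, G = n[0], n[1], n[2], n[3]
    (alpha_R, beta_R, K_TF, n_act, alpha_S, K_R, n_rep, k_pair,
     d_mR, d_mS, d_R, d_G, l_R, l_G, mu) = (
        pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7],
        pv[8], pv[9], pv[10], pv[11], pv[12], pv[13], pv[14])
    act = 0.0
    if tf_a > 0.0:
        r = (tf_a / K_TF) ** n_act
        act = r / (1.0 + r)
    rep = 1.0 / (1.0 + (R / (omega * K_R)) ** n_rep)
    out[0] = omega * (beta_R + alpha_R * act)
    out[1] = omega * alpha_S * rep
    out[2] = d_mR * mR
    out[3] = d_mS * mS
    out[4] = k_pair / omega * mR * mS
    out[5] = l_R * mR
    out[6] = l_G * mR
    out[7] = d_R * R
    out[8] = d_G * G
    if out.shape[0] > 9:
        out[9] = mu * mR
        out[10] = mu * mS
        out[11] = mu * R
        out[12] = mu * G


@njit(cache=True)
def _ssa_core(pv, omega, breakpoints, levels, t_record, init, stoich,
              seed, g_threshold):
    """Direct-method SSA for one cell.

    Returns (recorded counts, died flag, death time).  Waiting times are
    re-drawn at protocol breakpoints (the memoryless property makes this
    exact).  If ``g_threshold`` >= 1, the cell dies the moment its G count
    reaches the threshold; its state is frozen from then on.
    """
    np.random.seed(seed)
    n_rec = t_record.shape[0]
    n_chan = stoich.shape[0]
    rec = np.zeros((n_rec, _N_SPECIES), dtype=np.int64)
    n = init.copy()
    a = np.zeros(n_chan)
    t = 0.0
    i_rec = 0
    died = False
    death_time = -1.0
    t_end = t_record[n_rec - 1]
    n_seg = breakpoints.shape[0]
    for i_seg in range(n_seg):
        seg_end = breakpoints[i_seg + 1] if i_seg + 1 < n_seg else t_end
        if seg_end > t_end:
            seg_end = t_end
        if died or t >= seg_end:
            continue
        tf_a = levels[i_seg]
        while t < seg_end:
            _propensities(n, pv, tf_a, omega, a)
            a_tot = 0.0
            for k in range(n_chan):
                a_tot += a[k]
            if a_tot <= 0.0:
                t = seg_end
                break
            tau = np.random.exponential(1.0 / a_tot)
            t_next = t + tau
            if t_next >= seg_end:
                t = seg_end
                break
            # the state is n on [t, t_next): flush records falling in it
            while i_rec < n_rec and t_record[i_rec] < t_next:
                rec[i_rec] = n
                i_rec += 1
            u = np.random.random() * a_tot
            acc = 0.0
            k_fire = n_chan - 1
            for k in range(n_chan):
                acc += a[k]
                if u < acc:
                    k_fire = k
                    break
            for sp in range(_N_SPECIES):
                n[sp] += stoich[k_fire, sp]
            t = t_next
            if g_threshold >= 1 and n[3] >= g_threshold:
                died = True
                death_time = t
                break
        # constant until seg_end (or frozen at death): flush records
        while i_rec < n_rec and t_record[i_rec] <= t:
            rec[i_rec] = n
            i_rec += 1
        if died:
            break
    while i_rec < n_rec:
        rec[i_rec] = n
        i_rec += 1
    return rec, died, death_time


def build_reactions(params: ModelParams, omega: float):
    """Reaction set of the count-level model.

    Returns ``(reactions, propensity_fn)`` where ``reactions`` is a list of
    named :class:`Reaction` stoichiometries and ``propensity_fn(counts,
    tf_a)`` evaluates all channel propensities.  Nine channels in the
    growth-free model; ``mu > 0`` adds four first-order dilution channels.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    mu_active = params.mu > 0
    stoich = _reaction_stoichiometry(mu_active)
    names = [
        "P1_transcription", "P2_transcription", "mR_decay", "mS_decay",
        "pairing_codegradation", "R_translation", "G_translation",
        "R_decay", "G_decay",
    ]
    if mu_active:
        names += ["mR_dilution", "mS_dilution", "R_dilution", "G_dilution"]
    reactions = [Reaction(nm, stoich[i]) for i, nm in enumerate(names)]
    pv = _params_vector(params)

    def propensity_fn(counts, tf_a: float) -> np.ndarray:
        n = np.asarray(counts, dtype=np.float64)
        if n.shape != (_N_SPECIES,) or np.any(n < 0):
            raise ValueError("counts must be 4 non-negative values")
        out = np.zeros(stoich.shape[0])
        _propensities(n, pv, float(tf_a), float(omega), out)
        return out

    return reactions, propensity_fn


def _cell_seed(seed: int, cell_index: int) -> int:
    # counter-based stream: one uint32 word per (root seed, cell) pair
    return int(np.random.SeedSequence((int(seed), int(cell_index))).generate_state(1)[0])


def _protocol_arrays(protocol: InducerProtocol):
    return (
        np.asarray(protocol.breakpoints, dtype=np.float64),
        np.asarray(protocol.levels, dtype=np.float64),
    )


def gillespie(
    params: ModelParams,
    config: StochasticConfig,
    protocol: InducerProtocol,
    cell_index: int = 0,
    init: SystemState | None = None,
    t_record: np.ndarray | None = None,
    g_threshold: int = 0,
):
    """Exact single-cell trajectory, recorded at ``t_record`` times.

    The per-cell random stream is derived from ``(config.seed,
    cell_index)``, so the same pair always reproduces the same trajectory,
    independent of simulation order.  Returns ``(counts, died,
    death_time)`` with ``counts`` of shape (len(t_record), 4).
    """
    if t_record is None:
        t_record = np.asarray(config.snapshot_times, dtype=np.float64)
    else:
        t_record = np.asarray(t_record, dtype=np.float64)
    if t_record.size == 0 or np.any(np.diff(t_record) < 0):
        raise ValueError("t_record must be non-empty and sorted")
    init_counts = (
        np.zeros(_N_SPECIES, dtype=np.int64)
        if init is None
        else np.round(init.vector() * config.omega).astype(np.int64)
    )
    bp, lv = _protocol_arrays(protocol)
    stoich = _reaction_stoichiometry(params.mu > 0)
    rec, died, death_time = _ssa_core(
        _params_vector(params), float(config.omega), bp, lv, t_record,
        init_counts, stoich, _cell_seed(config.seed, cell_index),
        int(g_threshold),
    )
    if np.any(rec < 0):  # pragma: no cover - guarded by construction
        raise RuntimeError("negative count encountered")
    return rec, bool(died), float(death_time)


def simulate_population(
    params: ModelParams,
    config: StochasticConfig,
    protocol: InducerProtocol,
    init: SystemState | None = None,
    construct: str = "digitalized",
    dose: float | None = None,
    g_threshold: int = 0,
) -> list[PopulationSnapshot]:
    """Independent-cell population, one snapshot per requested time."""
    t_rec = np.asarray(config.snapshot_times, dtype=np.float64)
    counts = np.zeros((config.n_cells, t_rec.size, _N_SPECIES), dtype=np.int64)
    alive = np.ones(config.n_cells, dtype=bool)
    for c in range(config.n_cells):
        rec, died, _ = gillespie(
            params, config, protocol, cell_index=c, init=init,
            t_record=t_rec, g_threshold=g_threshold,
        )
        counts[c] = rec
        alive[c] = not died
    d = dose if dose is not None else float(protocol.levels[-1])
    return [
        PopulationSnapshot(
            time=float(t_rec[j]), counts=counts[:, j, :], alive=alive,
            construct=construct, dose=d,
        )
        for j in range(t_rec.size)
    ]


def one_hit_survival(
    params: ModelParams,
    config: StochasticConfig,
    doses: np.ndarray,
    threshold: int = 1,
) -> np.ndarray:
    """Survival fraction per dose under one-hit toxin killing.

    A cell dies the moment its toxin (G) count reaches ``threshold``
    (default: a single molecule suffices).  Dead cells stay dead; no
    escaper mutations are modelled.  Survival = alive cells / n_cells at
    ``config.t_max``.
    """
    if threshold < 1:
        raise ValueError("toxin threshold must be >= 1 molecule")
    doses = np.asarray(doses, dtype=float)
    t_rec = np.array([config.t_max])
    surv = np.empty(doses.size)
    for i, d in enumerate(doses):
        protocol = InducerProtocol.constant(float(d))
        n_alive = 0
        for c in range(config.n_cells):
            _, died, _ = gillespie(
                params, config, protocol, cell_index=c, t_record=t_rec,
                g_threshold=threshold,
            )
            n_alive += 0 if died else 1
        surv[i] = n_alive / config.n_cells
    return surv
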