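"""Parameter, state and protocol types for the digitalizer switch model.

The circuit is a mutual-inhibition switch downstream of an inducible
promoter P1: an operon mRNA ``mR`` encodes a transcriptional repressor R
(translationally coupled to a gene of interest, readout G), and R shuts off
the strong promoter P2 that transcribes a small RNA ``mS``.  The sRNA pairs
with mR and drives co-degradation, so mR and mS are mutually exclusive.
The active transcription factor TF^a driving P1 is treated as an external
input, not a dynamical species.

Units: concentrations in nM, time in minutes.
"""

from __future__ import annotations

import dataclasses
import math
import sys
from dataclasses import dataclass
from typing import Sequence

import numpy as np

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "ModelParams",
    "SystemState",
    "InducerProtocol",
    "baseline_params",
    "alks_palkb_params",
    "bistable_example_params",
    "construct_params",
    "load_params_toml",
    "params_toml_text",
    "CONSTRUCTS",
]

CONSTRUCTS = ("digitalized", "non_digitalized", "promoterless")


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of the digitalizer ODE/SSA model.

    Parameters
    ----------
    alpha_R : float
        Maximal transcription rate of the inducible promoter P1 (nM/min).
    beta_R : float
        Basal (uninduced) P1 transcription rate, the leak the switch is
        built to suppress (nM/min).
    K_TF : float
        Half-activation constant of P1 by active TF (nM).
    n_act : float
        Activation Hill coefficient (>= 1).
    alpha_S : float
        Maximal transcription rate of the repressible promoter P2
        producing the sRNA (nM/min).
    K_R : float
        Half-repression constant of P2 by repressor R (nM).
    n_rep : float
        Repression Hill coefficient (>= 1).
    k_pair : float
        Bimolecular mR-mS pairing / co-degradation rate (1/(nM*min)).
    delta_mR, delta_mS, delta_R, delta_G : float
        First-order decay rates (1/min).
    lambda_R, lambda_G : float
        Translation rates of R and of the readout G per mR (1/min).
    mu : float
        Optional dilution rate applied to all species (1/min); the default
        0 is the growth-free model.
    """

    alpha_R: float = 10.0
    beta_R: float = 0.15
    K_TF: float = 50.0
    n_act: float = 2.0
    alpha_S: float = 5.0
    K_R: float = 2000.0
    n_rep: float = 2.0
    k_pair: float = 1.0
    delta_mR: float = 0.2
    delta_mS: float = 0.2
    delta_R: float = 0.02
    delta_G: float = 0.02
    lambda_R: float = 2.0
    lambda_G: float = 2.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")
        if self.n_act < 1 or self.n_rep < 1:
            raise ValueError("Hill coefficients n_act and n_rep must be >= 1")
        if self.K_TF <= 0 or self.K_R <= 0:
            raise ValueError("K_TF and K_R must be > 0")

    def replace(self, **changes: float) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def scaled_repression(self, s: float) -> "ModelParams":
        """Scale both arms of the mutual inhibition by a factor ``s``.

        ``s`` multiplies the pairing rate ``k_pair`` (sRNA repression
        strength) and divides ``K_R`` (so the R-repression strength
        ``1/K_R`` is multiplied).  The sRNA transcription rate ``alpha_S``
        is left fixed: it sets the position of the switching threshold,
        which is what the strength sweep is meant to pivot around.
        """
        if s <= 0:
            raise ValueError("repression scale must be > 0")
        return self.replace(k_pair=self.k_pair * s, K_R=self.K_R / s)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


SPECIES = ("mR", "mS", "R", "G")


@dataclass(frozen=True)
class SystemState:
    """Concentrations (nM) of the four species plus the external input.

    ``tf_a`` is the concentration of active (inducer-bound) transcription
    factor; it is a control input, not a state variable of the dynamics.
    """

    tf_a: float = 0.0
    mR: float = 0.0
    mS: float = 0.0
    R: float = 0.0
    G: float = 0.0

    _TOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("tf_a",) + SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < -self._TOL:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    def vector(self) -> np.ndarray:
        """Species vector (mR, mS, R, G) with tiny negatives clipped to 0."""
        return np.clip(np.array([self.mR, self.mS, self.R, self.G]), 0.0, None)

    @classmethod
    def from_vector(cls, y: Sequence[float], tf_a: float = 0.0) -> "SystemState":
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        return cls(tf_a=tf_a, mR=y[0], mS=y[1], R=y[2], G=y[3])

    def with_input(self, tf_a: float) -> "SystemState":
        return dataclasses.replace(self, tf_a=tf_a)


@dataclass(frozen=True)
class InducerProtocol:
    """Piecewise-constant active-TF input.

    ``levels[i]`` is the tf_a value on the half-open interval
    ``[breakpoints[i], breakpoints[i+1])``; the last level extends to
    infinity.  A constant protocol is a single breakpoint at 0.
    """

    breakpoints: tuple[float, ...] = (0.0,)
    levels: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        lv = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if len(bp) != len(lv) or not bp:
            raise ValueError("breakpoints and levels must be equal-length, non-empty")
        if list(bp) != sorted(set(bp)):
            raise ValueError("breakpoints must be strictly increasing")
        if any(x < 0 for x in lv):
            raise ValueError("levels must be >= 0")

    @classmethod
    def constant(cls, tf_a: float) -> "InducerProtocol":
        return cls((0.0,), (float(tf_a),))

    @classmethod
    def step_off(cls, tf_on: float, t_off: float) -> "InducerProtocol":
        """Induce at level ``tf_on`` from t=0, remove inducer at ``t_off``."""
        return cls((0.0, float(t_off)), (float(tf_on), 0.0))

    def level_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right") - 1)
        return self.levels[max(idx, 0)]

    def segments(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Decompose [t0, t1] into (start, end, level) constant pieces."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        cuts = [t0] + [b for b in self.breakpoints if t0 < b < t1] + [t1]
        return [(a, b, self.level_at(a)) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


def baseline_params() -> ModelParams:
    """The repository's published baseline parameter set (nM, min)."""
    return ModelParams()


def construct_params(construct: str, base: ModelParams | None = None) -> ModelParams:
    """Parameter preset for one of the three benchmark constructs.

    ``digitalized`` is the full model; ``non_digitalized`` removes the sRNA
    (alpha_S = 0); ``promoterless`` removes P1 entirely (alpha_R = beta_R = 0),
    the autofluorescence control.
    """
    base = base if base is not None else baseline_params()
    if construct == "digitalized":
        return base
    if construct == "non_digitalized":
        return base.replace(alpha_S=0.0)
    if construct == "promoterless":
        return base.replace(alpha_R=0.0, beta_R=0.0)
    raise ValueError(f"unknown construct {construct!r}; expected one of {CONSTRUCTS}")


_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ModelParams))


def load_params_toml(path) -> dict[str, ModelParams]:
    """Load per-construct parameter sections from a TOML file.

    Each top-level table is a construct preset; keys must be ModelParams
    field names (unknown keys are errors, not warnings).
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    out: dict[str, ModelParams] = {}
    for section, table in doc.items():
        if not isinstance(table, dict):
            raise ValueError(f"top-level key {section!r} must be a table")
        unknown = set(table) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter keys in [{section}]: {sorted(unknown)}"
            )
        out[section] = ModelParams(**{k: float(v) for k, v in table.items()})
    return out


def params_toml_text(presets: dict[str, ModelParams] | None = None) -> str:
    """Render construct presets as TOML text (flat key-value per section)."""
    if presets is None:
        base = baseline_params()
        presets = {c: construct_params(c, base) for c in CONSTRUCTS}
    lines: list[str] = []
    for section, p in presets.items():
        lines.append(f"[{section}]")
        for name in _PARAM_NAMES:
            lines.append(f"{name} = {getattr(p, name)!r}")
        lines.append("")
    return "\n".join(lines)


def alks_palkb_params(base: ModelParams | None = None) -> ModelParams:
    """Scenario preset for a leakier expression system (AlkS/PalkB-like).

    Identical to the baseline except for a five-fold higher basal
    transcription rate of P1 — the regime where suppressing basal leak
    matters most.  Used for scenario realism only.
    """
    base = base if base is not None else baseline_params()
    return base.replace(beta_R=5.0 * base.beta_R)


def bistable_example_params() -> ModelParams:
    """A strongly mutually-repressing parameter set with genuine bistability.

    Found by grid search over the repression parameters (large sRNA supply
    alpha_S > maximal mRNA production, tight R repression of P2,
    cooperative n_rep = 2): the OFF branch then remains self-sustaining at
    every dose while an ON branch coexists at high dose, so up- and
    down-continuation separate.  Serves as the positive control for
    hysteresis detection.
    """
    return ModelParams(alpha_S=50.0, K_R=20.0, beta_R=0.5)
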