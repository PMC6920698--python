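"""TOML run configuration, output serialisation and the demo pipeline.

One configuration file drives every subcommand.  Top-level tables:
construct presets (``[digitalized]``, ``[non_digitalized]``,
``[promoterless]``) holding ModelParams keys, plus ``[design]``,
``[noise]``, ``[stochastic]`` and ``[run]``.  Unknown tables or keys are
errors, not warnings — silent typos in kinetic constants are worse than a
crash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from . import __version__
from .cytometry import DEFAULT_OMEGA, NoiseModel
from .params import CONSTRUCTS, ModelParams, construct_params

__all__ = ["RunConfig", "load_config", "default_config_text", "run_pipeline",
           "ConfigError", "write_table"]


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


@dataclass(frozen=True)
class DesignConfig:
    doses: tuple = (0.0, 10.0, 30.0, 60.0, 150.0, 500.0)
    times: tuple = (0.0, 20.0, 60.0, 160.0, 1440.0)
    n_events: int = 25_000
    constructs: tuple = CONSTRUCTS


@dataclass(frozen=True)
class StochasticDefaults:
    omega: float = DEFAULT_OMEGA
    n_cells: int = 500
    t_max: float = 160.0


@dataclass(frozen=True)
class RunConfig:
    presets: dict
    design: DesignConfig = DesignConfig()
    noise: NoiseModel = NoiseModel()
    stochastic: StochasticDefaults = StochasticDefaults()
    seed: int = 0

    def preset(self, construct: str) -> ModelParams:
        if construct not in self.presets:
            raise ConfigError(f"no preset for construct {construct!r}")
        return self.presets[construct]

    def params_hash(self) -> str:
        blob = json.dumps(
            {c: p.as_dict() for c, p in sorted(self.presets.items())},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(section: str, table: dict, cls, defaults):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - names
    if unknown:
        raise ConfigError(f"[{section}]: unknown keys {sorted(unknown)}")
    merged = {**{f.name: getattr(defaults, f.name) for f in dataclasses.fields(cls)}}
    for k, v in table.items():
        if isinstance(merged[k], tuple):
            v = tuple(v)
        merged[k] = v
    try:
        return cls(**merged)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"[{section}]: {e}") from e


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _config_from_doc(doc)


def config_from_text(text: str) -> RunConfig:
    """Parse and validate a TOML run configuration from a string."""
    return _config_from_doc(tomllib.loads(text))


def _config_from_doc(doc: dict) -> RunConfig:
    known = set(CONSTRUCTS) | {"design", "noise", "stochastic", "run"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level tables: {sorted(unknown)}")
    presets = {}
    base = ModelParams()
    pnames = set(base.as_dict())
    for c in CONSTRUCTS:
        table = doc.get(c, {})
        bad = set(table) - pnames
        if bad:
            raise ConfigError(f"[{c}]: unknown parameter keys {sorted(bad)}")
        try:
            presets[c] = construct_params(c).replace(
                **{k: float(v) for k, v in table.items()}
            )
        except ValueError as e:
            raise ConfigError(f"[{c}]: {e}") from e
    design = _build("design", doc.get("design", {}), DesignConfig, DesignConfig())
    noise = _build("noise", doc.get("noise", {}), NoiseModel, NoiseModel())
    sto = _build("stochastic", doc.get("stochastic", {}), StochasticDefaults,
                 StochasticDefaults())
    run = doc.get("run", {})
    if set(run) - {"seed"}:
        raise ConfigError(f"[run]: unknown keys {sorted(set(run) - {'seed'})}")
    return RunConfig(presets=presets, design=design, noise=noise,
                     stochastic=sto, seed=int(run.get("seed", 0)))


def default_config_text(seed: int = 0) -> str:
    """Render the baseline configuration as TOML text."""
    lines = []
    for c in CONSTRUCTS:
        lines.append(f"[{c}]")
        for k, v in construct_params(c).as_dict().items():
            lines.append(f"{k} = {float(v)!r}")
        lines.append("")
    d = DesignConfig()
    lines += [
        "[design]",
        f"doses = {list(d.doses)}",
        f"times = {list(d.times)}",
        f"n_events = {d.n_events}",
        f'constructs = {list(d.constructs)!r}'.replace("'", '"'),
        "",
        "[noise]",
    ]
    n = NoiseModel()
    for k in ("gain", "sigma_ext", "autofluor_mu", "autofluor_sigma", "floor"):
        lines.append(f"{k} = {float(getattr(n, k))!r}")
    s = StochasticDefaults()
    lines += [
        "",
        "[stochastic]",
        f"omega = {float(s.omega)!r}",
        f"n_cells = {s.n_cells}",
        f"t_max = {float(s.t_max)!r}",
        "",
        "[run]",
        f"seed = {int(seed)}",
        "",
    ]
    return "\n".join(lines)


def provenance_lines(config: RunConfig, extra: dict | None = None) -> list[str]:
    lines = [
        f"digisim {__version__}",
        f"seed = {config.seed}",
        f"params_hash = {config.params_hash()}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {v}")
    return lines


def write_table(
    table: pd.DataFrame, path, config: RunConfig | None = None,
    sep: str = "\t", overwrite: bool = False, extra: dict | None = None,
) -> None:
    """Write a tidy table with a '#'-prefixed provenance header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite to replace it")
    with open(path, "w") as fh:
        if config is not None:
            for line in provenance_lines(config, extra):
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep=sep, index=False)


def run_pipeline(config: RunConfig, outdir, overwrite: bool = False) -> dict:
    """Seeded end-to-end demo: sweep -> synthetic events -> summaries -> fit.

    Produces ``sweep.tsv`` (+ ``sweep_metrics.json``), ``events.csv``,
    ``summary.tsv`` and ``fit.json`` under ``outdir`` and returns the paths.
    Stage order is fixed; every file carries a provenance header with the
    seed and a hash of the parameter presets.
    """
    from .cytometry import generate_flow_experiment, write_events_csv
    from .ode import repression_sweep
    from .stats import summarize
    from .calibrate import fit_parameters

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / n for k, n in [
        ("sweep", "sweep.tsv"), ("sweep_metrics", "sweep_metrics.json"),
        ("events", "events.csv"), ("summary", "summary.tsv"),
        ("fit", "fit.json"),
    ]}
    for pth in paths.values():
        if pth.exists() and not overwrite:
            raise FileExistsError(f"{pth} exists; pass overwrite to replace it")

    p = config.preset("digitalized")
    strengths = np.array([0.3, 1.0, 3.0, 10.0, 30.0])
    doses = np.concatenate([[0.0], np.logspace(-1, 3, 41)])
    sweep = repression_sweep(p, strengths, doses)
    write_table(sweep_to_frame(sweep), paths["sweep"], config, overwrite=overwrite)
    with open(paths["sweep_metrics"], "w") as fh:
        json.dump(
            {
                "strengths": list(map(float, strengths)),
                "metrics": [dataclasses.asdict(m) for m in sweep.metrics],
                "seed": config.seed,
                "params_hash": config.params_hash(),
            },
            fh, indent=2,
        )

    events = generate_flow_experiment(
        doses=config.design.doses, times=config.design.times,
        constructs=config.design.constructs,
        base_params=None if _is_baseline(config) else config.preset("digitalized"),
        n_events=config.design.n_events, omega=config.stochastic.omega,
        noise=config.noise, seed=config.seed,
    )
    write_events_csv(events, paths["events"],
                     header_lines=provenance_lines(config))
    summary = summarize(events)
    write_table(summary, paths["summary"], config, overwrite=overwrite)

    fit = fit_parameters(
        summary, free=("k_pair", "alpha_S"),
        fixed=p.replace(k_pair=p.k_pair * 0.3, alpha_S=max(p.alpha_S * 0.5, 0.1)),
        noise=config.noise, omega=config.stochastic.omega,
        n_starts=5, seed=config.seed,
    )
    with open(paths["fit"], "w") as fh:
        json.dump(
            {
                "estimates": fit.estimates, "loss": fit.loss,
                "n_starts": fit.n_starts, "best_start": fit.best_start,
                "converged": list(fit.converged),
                "seed": config.seed, "params_hash": config.params_hash(),
            },
            fh, indent=2,
        )
    return paths


def _is_baseline(config: RunConfig) -> bool:
    return config.preset("digitalized") == ModelParams()


def sweep_to_frame(sweep) -> pd.DataFrame:
    """Tidy (strength, dose, mR, mS, R, G, converged) view of a sweep."""
    rows = []
    for s, curve in zip(sweep.strength_grid, sweep.curves):
        for i, d in enumerate(curve.doses):
            st = curve.steady[i]
            rows.append(dict(strength=float(s), dose=float(d), mR=st.mR,
                             mS=st.mS, R=st.R, G=st.G,
                             converged=bool(curve.converged[i])))
    return pd.DataFrame(rows)
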