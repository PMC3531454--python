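"""Configuration, result I/O and the end-to-end analysis pipeline.

The pipeline ties together the stages: DYK parameter-map fitting ->
cluster-chain construction -> analytic ISI/occupancy statistics ->
stochastic simulation -> generic-model comparison, with all randomness
flowing from a single configured seed.  Times are seconds, rates 1/s,
concentrations uM throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ChainModel, build_conditioned_waiting_times, fpt_moments, \
    splitting_probability, stationary_occupancy
from .distributions import ExponentialDist
from .dyk import CellParams, ParamMap, fit_parameter_maps, make_closing_density
from .generic import GenericParams, approximation_error, generic_moments
from .simulate import extract_spikes, isi_statistics, simulate_trajectory

__all__ = [
    "RunConfig", "ConfigError", "load_config", "write_results",
    "build_cell_chain", "run_pipeline", "PUFF_RATE_REF_S",
]

log = logging.getLogger("puffspike")

#: Calibrated cell-level puff rate (1/s) at the standard parameter set,
#: i.e. a mean interpuff interval of 20 s as measured in SH-SY5Y cells.
#: The DYK parameter maps provide the relative [IP3]/n_ch dependence
#: around this calibration point.
PUFF_RATE_REF_S = 0.05


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass(frozen=True)
class ChainConfig:
    n_clusters: int = 4
    target_state: int | None = None
    puff_rate_ref: float = PUFF_RATE_REF_S
    calibrate_puff_rate: bool = True

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ConfigError("chain.n_clusters must be >= 2")
        if self.puff_rate_ref <= 0:
            raise ConfigError("chain.puff_rate_ref must be positive")


@dataclass(frozen=True)
class GenericConfig:
    rho: float = float("inf")
    xi_override: float | None = None

    def __post_init__(self):
        if not self.rho > 0:
            raise ConfigError("generic.rho must be positive (inf allowed)")
        if self.xi_override is not None and not 0 < self.xi_override <= 1:
            raise ConfigError("generic.xi_override must lie in (0, 1]")


@dataclass(frozen=True)
class SweepConfig:
    name: str | None = None
    values: tuple = ()

    def __post_init__(self):
        if self.name is not None and self.name not in ("ip3", "n_ch", "lambda_cl"):
            raise ConfigError(f"unknown sweep parameter {self.name!r}")
        if self.name is not None and len(self.values) < 2:
            raise ConfigError("sweep.values needs at least 2 entries")


@dataclass(frozen=True)
class FitConfig:
    enabled: bool = True
    n_samples: int = 4000
    method: str = "spectral"

    def __post_init__(self):
        if self.method not in ("spectral", "ctmc"):
            raise ConfigError("fit.method must be 'spectral' or 'ctmc'")
        if self.n_samples < 100:
            raise ConfigError("fit.n_samples must be >= 100")


@dataclass(frozen=True)
class RunSettings:
    seed: int = 0
    t_max: float = 4000.0
    n_samples: int = 4000
    outdir: str = "results"

    def __post_init__(self):
        if self.t_max <= 0:
            raise ConfigError("run.t_max must be positive")


@dataclass(frozen=True)
class RunConfig:
    cell: CellParams = field(default_factory=CellParams)
    chain: ChainConfig = field(default_factory=ChainConfig)
    generic: GenericConfig = field(default_factory=GenericConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        d = {
            "cell": asdict(self.cell),
            "chain": asdict(self.chain),
            "generic": asdict(self.generic),
            "sweep": {"name": self.sweep.name, "values": list(self.sweep.values)},
            "fit": asdict(self.fit),
            "run": asdict(self.run),
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {
    "cell": CellParams,
    "chain": ChainConfig,
    "generic": GenericConfig,
    "sweep": SweepConfig,
    "fit": FitConfig,
    "run": RunSettings,
}


def _build_section(cls, raw: dict, section: str):
    import dataclasses

    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    if section == "sweep" and "values" in raw:
        raw = dict(raw, values=tuple(raw["values"]))
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; missing keys get defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# chain construction from the DYK maps
# ---------------------------------------------------------------------------

def build_cell_chain(
    cell: CellParams,
    pmap: ParamMap,
    chain_cfg: ChainConfig = ChainConfig(),
) -> ChainModel:
    """Cluster chain for a cell, with waiting times taken from the DYK maps.

    The 0 -> 1 transition is a pure cell-level exponential; by default its
    rate is the measured reference puff rate rescaled by the DYK map's
    relative [IP3]/n_ch dependence (set ``calibrate_puff_rate=False`` to
    use the raw DYK rate).  Subsequent openings use the fitted GE density
    in the CICR regime; the closing density is the maximum of n_ch
    exponential channel closings.
    """
    anchor = replace(cell, ip3=pmap.anchor_ip3, n_ch=pmap.anchor_nch)
    rel = pmap.puff_rate(cell) / pmap.puff_rate(anchor)
    lam_puff = chain_cfg.puff_rate_ref * rel if chain_cfg.calibrate_puff_rate \
        else pmap.puff_rate(cell)
    ge_open = pmap.opening_density(cell)
    N = chain_cfg.n_clusters
    return ChainModel(
        n_clusters=N,
        psi_open=tuple([ExponentialDist(lam_puff)] + [ge_open] * (N - 1)),
        psi_close=make_closing_density(cell),
        target_state=chain_cfg.target_state,
        puff_is_total=True,
    )


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

def write_results(
    tables: dict[str, pd.DataFrame],
    directory: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    timings: dict | None = None,
) -> dict:
    """Write CSV tables plus a JSON manifest; returns the manifest."""
    outdir = Path(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        fname = f"{name}.csv"
        df.to_csv(outdir / fname, index=False)
        files[name] = fname
    manifest = {
        "package": "puffspike",
        "version": __version__,
        "seed": seed,
        "config_hash": config.config_hash() if config is not None else None,
        "files": files,
        "timings_s": timings or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with open(outdir / "run.log", "w") as fh:
        for stage, dt in (timings or {}).items():
            fh.write(f"{stage}: {dt:.3f} s\n")
    return manifest


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _swept_cells(config: RunConfig):
    base = config.cell
    if config.sweep.name is None:
        return []
    out = []
    for v in config.sweep.values:
        if config.sweep.name == "n_ch":
            out.append(replace(base, n_ch=int(v)))
        else:
            out.append(replace(base, **{config.sweep.name: float(v)}))
    return out


def run_pipeline(
    config: RunConfig,
    stages: tuple = ("fit", "analyze", "simulate", "generic", "sweep"),
    write: bool = True,
    param_map: ParamMap | None = None,
) -> dict:
    """Execute the configured stages; returns {stage tables, objects}.

    Any stage error aborts with a stage-tagged exception.  Re-running with
    the same configuration and seed reproduces the outputs bit for bit.
    """
    rng_root = np.random.SeedSequence(config.run.seed)
    seeds = {name: np.random.default_rng(s)
             for name, s in zip(("fit", "simulate"), rng_root.spawn(2))}
    tables: dict[str, pd.DataFrame] = {}
    objects: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        return name in stages

    try:
        t0 = time.perf_counter()
        if param_map is None:
            if not stage("fit") or not config.fit.enabled:
                raise ConfigError("pipeline needs a parameter map: enable the fit stage "
                                  "or pass param_map")
            pmap = fit_parameter_maps(
                anchor=config.cell,
                n_samples=config.fit.n_samples,
                seed=seeds["fit"],
                method=config.fit.method,
            )
        else:
            pmap = param_map
        objects["param_map"] = pmap
        timings["fit"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        t0 = time.perf_counter()
        chain = build_cell_chain(config.cell, pmap, config.chain)
        cwt = build_conditioned_waiting_times(chain)
        objects["chain"] = chain
        objects["cwt"] = cwt
        timings["chain"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"stage 'chain' failed: {exc}") from exc

    xi = None
    fpt = None
    if stage("analyze"):
        try:
            t0 = time.perf_counter()
            pi = stationary_occupancy(cwt)
            fpt = fpt_moments(cwt, 0, chain.target_state)
            xi = splitting_probability(cwt, 1, chain.target_state, 0)
            tables["occupancy"] = pd.DataFrame(
                {"open_clusters": np.arange(len(pi)), "probability": pi}
            )
            tables["isi_analytic"] = pd.DataFrame([{
                "T_av_s": fpt.mean, "sd_s": fpt.sd, "cv": fpt.cv,
                "skewness": fpt.skewness, "excess_kurtosis": fpt.excess_kurtosis,
                "xi": xi,
            }])
            timings["analyze"] = time.perf_counter() - t0
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc

    if stage("simulate"):
        try:
            t0 = time.perf_counter()
            traj = simulate_trajectory(chain, config.run.t_max, seeds["simulate"])
            train = extract_spikes(traj, chain.target_state)
            tables["trajectory"] = pd.DataFrame(
                {"time_s": traj.event_times, "open_clusters": traj.states}
            )
            tables["spikes"] = pd.DataFrame({"spike_epoch_s": train.spike_epochs})
            if len(train.isis) >= 2:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    stats = isi_statistics(train, seed=config.run.seed)
                row = stats.summary()
                row.update({f"se_{k}": v for k, v in (stats.se or {}).items()})
                row["n_isis"] = len(train.isis)
                tables["isi_simulated"] = pd.DataFrame([row])
            objects["trajectory"] = traj
            objects["spike_train"] = train
            timings["simulate"] = time.perf_counter() - t0
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if stage("generic"):
        try:
            t0 = time.perf_counter()
            if xi is None:
                xi = splitting_probability(cwt, 1, chain.target_state, 0)
            lam_puff = chain.psi_open[0].lam
            use_xi = config.generic.xi_override if config.generic.xi_override else xi
            gp = GenericParams(
                puff_rates=lam_puff / config.chain.n_clusters,
                couplings=use_xi,
                rho=config.generic.rho,
                n_clusters=config.chain.n_clusters,
            )
            gm = generic_moments(gp)
            row = {
                "lambda_inf_per_s": gp.lambda_inf,
                "rho_per_s": gp.rho,
                "xi": use_xi,
                "T_av_generic_s": gm.mean,
                "sd_generic_s": gm.sd,
                "cv_generic": gm.cv,
            }
            if fpt is not None:
                row["T_av_exact_s"] = fpt.mean
                row["rel_error"] = abs(fpt.mean - gm.mean) / fpt.mean
            tables["generic_comparison"] = pd.DataFrame([row])
            objects["generic_params"] = gp
            timings["generic"] = time.perf_counter() - t0
        except Exception as exc:
            raise RuntimeError(f"stage 'generic' failed: {exc}") from exc

    if stage("sweep") and config.sweep.name is not None:
        try:
            t0 = time.perf_counter()
            rows = []
            chains = []
            for cell in _swept_cells(config):
                c = build_cell_chain(cell, pmap, config.chain)
                chains.append(c)
                cw = build_conditioned_waiting_times(c)
                f = fpt_moments(cw, 0, c.target_state)
                rows.append({
                    f"{config.sweep.name}": getattr(cell, config.sweep.name),
                    "T_av_s": f.mean, "sd_s": f.sd, "cv": f.cv,
                    "xi": splitting_probability(cw, 1, c.target_state, 0),
                })
            sweep_df = pd.DataFrame(rows)
            err = approximation_error(chains)
            tables["sweep"] = sweep_df
            tables["approximation_error"] = err
            timings["sweep"] = time.perf_counter() - t0
        except Exception as exc:
            raise RuntimeError(f"stage 'sweep' failed: {exc}") from exc

    if write:
        manifest = write_results(
            tables, Path(config.run.outdir), config=config,
            seed=config.run.seed, timings=timings,
        )
        objects["manifest"] = manifest
    objects["tables"] = tables
    return objects
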