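"""Run configuration, serialization and reproducible end-to-end runs.

A run is described by a single YAML file (sections: ``model``, ``reference``,
``thresholds``, ``sampler``, plus top-level ``seed`` and ``out_dir``); unknown
keys are rejected before any computation.  ``run_from_config`` executes the
configured sampler and writes a samples CSV, a JSON manifest (config echo,
seeds, acceptance rates, wall time) and, where applicable, a diagnostics
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .objectives import DesignProblem, wtc_problem, toy_problem
from .samplers import (PTConfig, adaptive_mh_individual, naive_population_mcmc,
                       slmcmc, pt_slmcmc)
from .diagnostics import efficiency_report, posterior_viability_check

logger = logging.getLogger("popdesign")

_MODEL_KEYS = {"name", "cov_mode", "n_Tup", "toy_mode"}
_REFERENCE_KEYS = {"slope", "max_idr", "dose_step"}
_THRESHOLD_KEYS = {"epsilon", "delta"}
_SAMPLER_KEYS = {"name", "n_samples", "kappa", "N", "n_check", "burn_in_frac"}
_TOP_KEYS = {"model", "reference", "thresholds", "sampler", "seed", "out_dir"}


@dataclass
class RunConfig:
    """Validated run configuration with the printed defaults."""

    model: str = "wtc"
    cov_mode: str = "scalar"
    n_Tup: float | None = None
    slope: float = 0.4
    max_idr: float = 150.0
    dose_step: float = 25.0
    epsilon: float = 6.0
    delta: float = 0.2
    sampler: str = "slmcmc"
    n_samples: int = 20_000
    kappa: tuple = (3,)
    N: int = 300
    n_check: int = 600
    burn_in_frac: float = 0.5
    seed: int = 0
    out_dir: str = "popdesign_run"

    def __post_init__(self):
        if self.model not in ("wtc", "toy"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.sampler not in ("individual", "naive", "slmcmc", "pt-slmcmc"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        self.kappa = tuple(int(k) for k in np.atleast_1d(self.kappa))
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for section, keys, rename in (
                ("model", _MODEL_KEYS, {"name": "model"}),
                ("reference", _REFERENCE_KEYS, {}),
                ("thresholds", _THRESHOLD_KEYS, {}),
                ("sampler", _SAMPLER_KEYS, {"name": "sampler"})):
            sub = raw.get(section, {}) or {}
            bad = set(sub) - keys
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            for k, v in sub.items():
                kw[rename.get(k, k)] = v
        if "toy_mode" in kw:
            kw.pop("toy_mode")  # accepted for forward compatibility
        for k in ("seed", "out_dir"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kappa"] = list(self.kappa)
        return d

    def problem(self) -> DesignProblem:
        if self.model == "wtc":
            return wtc_problem(epsilon=self.epsilon, delta=self.delta,
                               cov_mode=self.cov_mode, max_idr=self.max_idr,
                               slope=self.slope, dose_step=self.dose_step,
                               n_Tup=self.n_Tup)
        return toy_problem(epsilon=self.epsilon, delta=self.delta)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_from_config(config, out_dir=None) -> dict:
    """Execute a fully seeded run; returns the manifest dict.

    ``config`` is a path to a YAML file or a :class:`RunConfig`.  Artifacts:
    ``samples.csv`` (one row per retained sample), ``manifest.json`` and, for
    the stochastic-likelihood samplers, ``report.json`` with the a-posteriori
    viability check and efficiency metrics.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    problem = cfg.problem()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if cfg.sampler == "individual":
        chain = adaptive_mh_individual(problem, cfg.n_samples, cfg.seed)
    elif cfg.sampler == "naive":
        chain = naive_population_mcmc(problem, cfg.n_samples, cfg.seed, N=cfg.N)
    elif cfg.sampler == "slmcmc":
        chain = slmcmc(problem, cfg.kappa[0], cfg.n_samples, cfg.seed)
    else:
        chain = pt_slmcmc(problem, PTConfig(cfg.kappa), cfg.n_samples, cfg.seed)
    wall = time.perf_counter() - t0

    chain.to_csv(out / "samples.csv")
    manifest = {
        "schema_version": 1,
        "popdesign_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_samples": len(chain),
        "acceptance_rate": chain.acceptance_rate,
        "wall_time_s": wall,
        "sampler_meta": {k: v for k, v in chain.meta.items()
                         if isinstance(v, (int, float, str, list))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if cfg.sampler in ("slmcmc", "pt-slmcmc"):
        rep = efficiency_report(chain, problem, n_check=cfg.n_check, N=cfg.N,
                                seed=cfg.seed, burn_in_frac=cfg.burn_in_frac)
        (out / "report.json").write_text(json.dumps(rep.to_dict(), indent=2))
    logger.info("run complete: %d samples, acceptance %.3f, %.1fs",
                len(chain), chain.acceptance_rate, wall)
    return manifest
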