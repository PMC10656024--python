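"""Synthetic calibration and validation data generators.

Real longitudinal fetal IgG data come from cordocentesis cohorts and are
not redistributable; these generators emulate their shape from a known
ground-truth parameter set so that calibration and refitting routines
can be exercised and verified by parameter recovery.  All noise flows
through an explicit integer seed.
"""

from __future__ import annotations

import json
import hashlib
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationTarget
from .parameters import ParameterSet, default_parameters
from .placenta import simulate
from .vaccine import VaccineParameters, maternal_igg_pt

__all__ = [
    "FixtureSpec",
    "generate_cordocentesis_fixture",
    "generate_vaccine_response_fixture",
    "run_manifest",
    "write_manifest",
    "read_manifest",
]

#: Sampling weeks emulating a cordocentesis cohort spanning mid-gestation
#: to delivery (17-41 weeks).
DEFAULT_WEEKS = np.arange(17.0, 42.0, 4.0)  # 17, 21, ..., 41


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic cordocentesis-style calibration target set."""

    truth: ParameterSet = field(default_factory=default_parameters)
    weeks: np.ndarray = field(default_factory=lambda: DEFAULT_WEEKS.copy())
    cv: float = 0.25          # per-subclass coefficient of variation for SDs
    noise_cv: float = 0.0     # lognormal noise applied to the means
    seed: int = 0
    n_subjects: int = 107     # emulated cohort size (metadata only)

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=float)
        if np.any(w < 0) or np.any(w > 45):
            raise ValueError("weeks must lie within gestation")
        if self.cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


def generate_cordocentesis_fixture(spec: FixtureSpec | None = None) -> CalibrationTarget:
    """Simulate the truth parameters and sample noisy subclass targets.

    Means are the simulated fetal subclass concentrations at the sampling
    weeks, optionally perturbed by lognormal noise with coefficient of
    variation ``noise_cv``; SDs are ``cv * mean``, emulating the spread of
    a cohort of ``n_subjects``.  Deterministic given the seed.
    """
    spec = FixtureSpec() if spec is None else spec
    weeks = np.asarray(spec.weeks, dtype=float)
    try:
        sim = simulate(spec.truth, t_end=float(weeks.max()),
                       t_eval=np.unique(np.concatenate([[0.0], weeks])))
    except Exception as exc:  # pragma: no cover - fixture truth must simulate
        raise RuntimeError(f"truth simulation failed: {exc}") from exc
    fet = sim.fetal[:, np.searchsorted(sim.t, weeks)]  # (4, k)
    mean = fet.T.copy()
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=mean.shape)
        mean = mean * noise
    sd = spec.cv * mean
    return CalibrationTarget(weeks=weeks, mean=mean, sd=sd)


def generate_vaccine_response_fixture(
    p_vax: VaccineParameters | None = None,
    sample_days: np.ndarray | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy samples of the maternal alpha-PT IgG response curve.

    Returns a DataFrame with columns ``day`` and ``igg_pt`` (titer units),
    supporting the optional refitting utility and its round-trip tests.
    """
    p_vax = VaccineParameters() if p_vax is None else p_vax
    if sample_days is None:
        sample_days = np.array([0.0, 7, 14, 21, 28, 42, 60, 90, 120, 180, 270])
    sample_days = np.asarray(sample_days, dtype=float)
    curve = maternal_igg_pt(sample_days, p_vax)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        curve = curve * rng.lognormal(-0.5 * sigma**2, sigma, size=curve.shape)
    return pd.DataFrame({"day": sample_days, "igg_pt": curve})


def run_manifest(config: dict, seeds: dict | None = None,
                 solver_options: dict | None = None) -> dict:
    """JSON-serializable record of a run: config hash, seeds, versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "package": "placigg",
        "version": __version__,
        "python": platform.python_version(),
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds or {},
        "solver_options": solver_options or {},
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
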