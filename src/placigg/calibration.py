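"""Iterative LHS calibration of the free placental parameters.

The calibrator follows a sample-prune scheme: Latin-hypercube sample the
current plausible box, run the forward model per draw, classify each run
against data-band pass criteria, and shrink every parameter's range to
the envelope of the passing draws; iterate until a target fraction of
runs passes.  The pass rule mirrors the longitudinal fetal-IgG fitting
bands: at the first target week the simulated concentration must not
exceed mean + 1 SD (one-sided, because early-gestation fetal IgG
approaches zero), and at the final target week it must lie within
mean +/- 1.5 SD.  Intermediate target weeks do not gate pass/fail but
are reported as RMSE diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ParameterRange,
    ParameterSet,
    SUBCLASSES,
    default_parameters,
)
from .placenta import SimulationResult, simulate
from .sensitivity import lhs_design

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "CalibrationFailure",
    "passes",
    "calibrate",
    "load_targets_csv",
    "save_targets_csv",
]


class CalibrationFailure(RuntimeError):
    """No passing parameter sets; carries per-parameter pass marginals."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CalibrationTarget:
    """Gestational-week-indexed fetal subclass means and SDs (molar)."""

    weeks: np.ndarray       # (k,) strictly increasing
    mean: np.ndarray        # (k, 4) molar
    sd: np.ndarray          # (k, 4) molar

    def __post_init__(self) -> None:
        if self.weeks.ndim != 1 or self.weeks.size < 2:
            raise ValueError("need at least a first and a final target week")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("target weeks must be strictly increasing")
        if self.mean.shape != (self.weeks.size, 4) or self.sd.shape != self.mean.shape:
            raise ValueError("mean and sd must be (n_weeks, 4)")
        if np.any(self.sd < 0):
            raise ValueError("SDs must be non-negative")

    @property
    def first_week(self) -> float:
        return float(self.weeks[0])

    @property
    def final_week(self) -> float:
        return float(self.weeks[-1])


def _fetal_at_weeks(sim: SimulationResult, weeks: np.ndarray) -> np.ndarray:
    """(k, 4) simulated fetal subclass concentrations at the target weeks."""
    if weeks.min() < sim.t.min() - 1e-9 or weeks.max() > sim.t.max() + 1e-9:
        raise ValueError("targets fall outside the simulated span")
    idx = sim._name_index([s.value for s in SUBCLASSES])
    fet = sim.fetal[idx]
    return np.column_stack([
        np.interp(weeks, sim.t, fet[i]) for i in range(4)
    ])


def passes(sim: SimulationResult, targets: CalibrationTarget,
           per_subclass: bool = True) -> bool:
    """Data-band pass rule for one simulation.

    Per subclass (or on total IgG with ``per_subclass=False``): simulated
    concentration at the first target week <= mean + 1 SD, and at the
    final target week within mean +/- 1.5 SD.
    """
    vals = _fetal_at_weeks(sim, np.array([targets.first_week, targets.final_week]))
    mean = targets.mean[[0, -1]]
    sd = targets.sd[[0, -1]]
    if not per_subclass:
        # Total-IgG variant: SDs add in quadrature.
        vals = vals.sum(axis=1, keepdims=True)
        mean = mean.sum(axis=1, keepdims=True)
        sd = np.sqrt((sd**2).sum(axis=1, keepdims=True))
    first_ok = np.all(vals[0] <= mean[0] + sd[0])
    final_ok = np.all(np.abs(vals[1] - mean[1]) <= 1.5 * sd[1])
    return bool(first_ok and final_ok)


def rmse(sim: SimulationResult, targets: CalibrationTarget) -> float:
    """Root-mean-square deviation from all target means (diagnostic only)."""
    vals = _fetal_at_weeks(sim, targets.weeks)
    return float(np.sqrt(np.mean((vals - targets.mean) ** 2)))


@dataclass
class CalibrationResult:
    """Accepted ranges and per-iteration pass fractions."""

    accepted_ranges: ParameterRange
    pass_fraction: list[float]
    accepted_sets: np.ndarray          # (n_pass, p) from the final iteration
    names: tuple[str, ...]
    iterations: int
    converged: bool
    seed: int


def calibrate(
    initial_ranges: ParameterRange,
    targets: CalibrationTarget,
    n_samples: int = 1000,
    seed: int = 0,
    max_iter: int = 10,
    pass_threshold: float = 0.95,
    envelope: tuple[float, float] = (2.5, 97.5),
    base: ParameterSet | None = None,
    t_end: float | None = None,
    per_subclass: bool = True,
    rtol: float = 1e-8,
) -> CalibrationResult:
    """Iterative sample-prune calibration over ``initial_ranges``.

    Each iteration LHS-samples ``n_samples`` parameter sets, simulates to
    the final target week, classifies runs with :func:`passes`, and
    narrows every free parameter's range to the ``envelope`` percentile
    band of the passing draws.  Terminates when the pass fraction reaches
    ``pass_threshold``.  Deterministic given ``seed``.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be at least 50")
    base = default_parameters() if base is None else base
    t_end = targets.final_week if t_end is None else t_end
    ranges = initial_ranges
    history: list[float] = []
    accepted = np.empty((0, len(ranges.names)))

    for it in range(1, max_iter + 1):
        design = lhs_design(ranges, n_samples, seed=seed + it - 1)
        ok = np.zeros(n_samples, dtype=bool)
        for i, row in enumerate(design.X):
            p = base.with_free_values(dict(zip(design.names, row)))
            try:
                sim = simulate(p, t_end=t_end, rtol=rtol)
                ok[i] = passes(sim, targets, per_subclass=per_subclass)
            except Exception:
                ok[i] = False
        frac = float(ok.mean())
        history.append(frac)
        accepted = design.X[ok]
        if not ok.any():
            marginals = {
                name: float(np.corrcoef(design.X[:, j], ok)[0, 1]) if ok.any() else 0.0
                for j, name in enumerate(design.names)
            }
            raise CalibrationFailure(
                f"no passing parameter sets at iteration {it}",
                diagnostics={"pass_fraction": history, "marginals": marginals},
            )
        if frac >= pass_threshold:
            return CalibrationResult(
                accepted_ranges=ranges, pass_fraction=history,
                accepted_sets=accepted, names=design.names,
                iterations=it, converged=True, seed=seed,
            )
        lo_q, hi_q = np.percentile(accepted, envelope, axis=0)
        # Degenerate (fixed) dimensions stay fixed.
        bounds = {}
        for j, name in enumerate(design.names):
            cur_lo, cur_hi = ranges.bounds[name]
            if cur_lo == cur_hi:
                bounds[name] = (cur_lo, cur_hi)
            else:
                bounds[name] = (float(lo_q[j]), float(hi_q[j]))
        ranges = ParameterRange(bounds)

    return CalibrationResult(
        accepted_ranges=ranges, pass_fraction=history,
        accepted_sets=accepted, names=tuple(ranges.names),
        iterations=max_iter, converged=False, seed=seed,
    )


def load_targets_csv(path: str | Path) -> CalibrationTarget:
    """Read a long-format target table (week, subclass, mean_M, sd_M)."""
    df = pd.read_csv(path, float_precision="round_trip")
    wide_m = df.pivot(index="week", columns="subclass", values="mean_M")
    wide_s = df.pivot(index="week", columns="subclass", values="sd_M")
    cols = [s.value for s in SUBCLASSES]
    return CalibrationTarget(
        weeks=wide_m.index.to_numpy(dtype=float),
        mean=wide_m[cols].to_numpy(dtype=float),
        sd=wide_s[cols].to_numpy(dtype=float),
    )


def save_targets_csv(targets: CalibrationTarget, path: str | Path) -> None:
    rows = []
    for k, week in enumerate(targets.weeks):
        for i, s in enumerate(SUBCLASSES):
            rows.append({
                "week": week, "subclass": s.value,
                "mean_M": targets.mean[k, i], "sd_M": targets.sd[k, i],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
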