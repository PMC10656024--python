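"""Transwell HUVEC transcytosis model of IgG1/IgG4 competition for FcRn.

A seven-state kinetic model of FcRn-mediated transcytosis across a HUVEC
monolayer: apical IgG1 and IgG4 bind free FcRn; complexes either
dissociate or are transcytosed, accumulating basolateral IgG.  Units are
nM and minutes; the assay horizon is 120 minutes, matching the
experimental protocol.  The default equations contain no degradation
term; ``with_degradation=True`` adds first-order loss ``-k_deg * [IgG]``
to the free apical species, exposing the optimized lysosomal rate.

A quasi-steady-state reduction yields the closed-form competitive
Langmuir expression for complex formation,

    C4 = FcRn0 * ([IgG4]/K_D4) / (1 + [IgG4]/K_D4 + [IgG1]/K_D1),

which quantifies how an abundant competitor suppresses transcytosis of a
less abundant subclass once total IgG exceeds the receptor's capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import igg_mass_to_molar

__all__ = [
    "HuvecParameters",
    "huvec_rhs",
    "simulate_huvec",
    "closed_form_complex",
    "find_saturation_point",
    "competition_curve",
    "mg_ml_to_nM",
    "AnalysisError",
]

_MIN_PER_S = 60.0


class AnalysisError(RuntimeError):
    """Raised when a sweep does not admit the requested analysis."""


def mg_ml_to_nM(c_mg_per_ml: float | np.ndarray) -> float | np.ndarray:
    """mg/ml -> nM via the 150 kDa IgG convention."""
    return igg_mass_to_molar(c_mg_per_ml) * 1e9


@dataclass(frozen=True)
class HuvecParameters:
    """Optimized Transwell model parameters (nM / minutes)."""

    FcRn0: float = 2200.0            # nM, HUVEC FcRn expression
    k_deg: float = 0.01              # 1/min, lysosomal degradation
    k_trans: float = 2.5e-5          # 1/min, transcytosis
    KD1: float = 1.25e-8 * 1e9       # nM, FcRn-IgG1
    KD4: float = 5e-8 * 1e9          # nM, FcRn-IgG4
    k_off: float = 0.15 * _MIN_PER_S  # 1/min, shared off-rate

    def __post_init__(self) -> None:
        for name in ("FcRn0", "k_deg", "KD1", "KD4", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_trans < 0:
            raise ValueError("k_trans must be non-negative")

    @property
    def kon1(self) -> float:
        return self.k_off / self.KD1  # 1/(nM min)

    @property
    def kon4(self) -> float:
        return self.k_off / self.KD4


# State layout: [IgG1, IgG4, FcRn, C1, C4, IgG1_T, IgG4_T]
def huvec_rhs(t: float, y: np.ndarray, p: HuvecParameters,
              with_degradation: bool = False) -> np.ndarray:
    """Transwell model derivatives (printed-equation form by default)."""
    igg1, igg4, fcrn, c1, c4, _, _ = y
    b1 = p.kon1 * igg1 * fcrn - p.k_off * c1
    b4 = p.kon4 * igg4 * fcrn - p.k_off * c4
    deg1 = p.k_deg * igg1 if with_degradation else 0.0
    deg4 = p.k_deg * igg4 if with_degradation else 0.0
    return np.array([
        -b1 - deg1,
        -b4 - deg4,
        -b1 - b4 + p.k_trans * (c1 + c4),
        b1 - p.k_trans * c1,
        b4 - p.k_trans * c4,
        p.k_trans * c1,
        p.k_trans * c4,
    ])


def simulate_huvec(
    p: HuvecParameters,
    igg1_nM: float,
    igg4_nM: float,
    duration_min: float = 120.0,
    with_degradation: bool = False,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-9,
):
    """Integrate the Transwell model from a fresh apical dose."""
    y0 = np.array([igg1_nM, igg4_nM, p.FcRn0, 0.0, 0.0, 0.0, 0.0])
    sol = solve_ivp(
        huvec_rhs, (0.0, duration_min), y0, args=(p, with_degradation),
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"HUVEC integration failed: {sol.message}")
    return sol


def closed_form_complex(igg_self: float, igg_other: float, FcRn0: float,
                        KD_self: float, KD_other: float) -> float:
    """Quasi-steady-state complex of one subclass competing with another.

    All arguments in consistent concentration units; returns the bound
    complex of the ``self`` subclass.
    """
    if KD_self <= 0 or KD_other <= 0:
        raise ValueError("dissociation constants must be positive")
    if igg_self < 0 or igg_other < 0 or FcRn0 < 0:
        raise ValueError("concentrations must be non-negative")
    x = igg_self / KD_self
    return FcRn0 * x / (1.0 + x + igg_other / KD_other)


def read_transcytosis_csv(path):
    """Read replicate-level basolateral ELISA measurements.

    Expected columns: ``t_min``, ``apical_igg1_mg_ml``,
    ``apical_igg4_mg_ml``, ``replicate``, ``basolateral_igg4_nM`` (and
    optionally ``basolateral_igg1_nM``) — the time courses used for
    optional parameter refitting.
    """
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t_min", "apical_igg1_mg_ml", "apical_igg4_mg_ml",
                "replicate", "basolateral_igg4_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcytosis CSV missing columns: {sorted(missing)}")
    return df


def refit_transcytosis(df, start: HuvecParameters | None = None,
                       free: tuple[str, ...] = ("FcRn0", "k_trans"),
                       with_degradation: bool = False) -> HuvecParameters:
    """Optional least-squares refit of Transwell parameters to time-course
    data from :func:`read_transcytosis_csv`.  Not run by default."""
    from dataclasses import replace as _replace
    from scipy.optimize import least_squares

    start = HuvecParameters() if start is None else start
    conditions = df.groupby(["apical_igg1_mg_ml", "apical_igg4_mg_ml"])

    def resid(x):
        p = _replace(start, **dict(zip(free, x)))
        out = []
        for (c1, c4), grp in conditions:
            t_eval = np.unique(grp["t_min"].to_numpy(dtype=float))
            sol = simulate_huvec(p, mg_ml_to_nM(c1), mg_ml_to_nM(c4),
                                 duration_min=float(t_eval.max()),
                                 with_degradation=with_degradation,
                                 t_eval=t_eval)
            pred = dict(zip(t_eval, sol.y[6]))
            out.extend(
                pred[t] - v
                for t, v in zip(grp["t_min"], grp["basolateral_igg4_nM"])
            )
        return np.asarray(out)

    x0 = np.array([getattr(start, name) for name in free])
    fit = least_squares(resid, x0, bounds=(1e-12, np.inf))
    return _replace(start, **dict(zip(free, fit.x)))


def _transcytosed_igg4(p, igg1_mg_ml, igg4_mg_ml, duration_min, with_degradation):
    sol = simulate_huvec(
        p, mg_ml_to_nM(igg1_mg_ml), mg_ml_to_nM(igg4_mg_ml),
        duration_min, with_degradation,
    )
    return sol.y[6, -1], sol.y[5, -1]  # (IgG4_T, IgG1_T) nM


def find_saturation_point(
    p: HuvecParameters | None = None,
    duration_min: float = 120.0,
    sweep_mg_ml: np.ndarray | None = None,
    edge_points: int = 3,
    with_degradation: bool = False,
) -> dict:
    """Apical IgG4 concentration at which transcytosis saturates.

    Sweeps apical IgG4 over ``sweep_mg_ml`` (default 0.05-1.0 mg/ml) and
    records basolateral IgG4 at the end of the assay.  The dose-response
    rises linearly while free receptor is abundant and plateaus once the
    apical dose exhausts the receptor pool; the saturation point is the
    breakpoint where the low-dose tangent meets the plateau tangent
    (each fit to ``edge_points`` grid points at the sweep edges).
    """
    p = HuvecParameters() if p is None else p
    if sweep_mg_ml is None:
        sweep_mg_ml = np.arange(0.05, 1.0001, 0.02)
    sweep_mg_ml = np.asarray(sweep_mg_ml, dtype=float)
    if np.any(np.diff(sweep_mg_ml) <= 0):
        raise ValueError("sweep must be strictly increasing")
    if sweep_mg_ml.size < 2 * edge_points:
        raise ValueError("sweep too short for the tangent fits")

    trans = np.array([
        _transcytosed_igg4(p, 0.0, c, duration_min, with_degradation)[0]
        for c in sweep_mg_ml
    ])
    if np.any(np.diff(trans) < -1e-9 * max(trans.max(), 1e-30)):
        raise AnalysisError("transcytosed IgG4 is not a monotone response")
    lo = np.polyfit(sweep_mg_ml[:edge_points], trans[:edge_points], 1)
    hi = np.polyfit(sweep_mg_ml[-edge_points:], trans[-edge_points:], 1)
    if lo[0] <= 0:
        raise AnalysisError("no transcytosis response; saturation undefined")
    if hi[0] >= 0.5 * lo[0]:
        raise AnalysisError("response does not saturate on the sweep")
    saturation = (hi[1] - lo[1]) / (lo[0] - hi[0])
    return {
        "saturation_mg_ml": float(saturation),
        "grid_mg_ml": sweep_mg_ml,
        "transcytosed_nM": trans,
        "low_dose_slope": float(lo[0]),
        "plateau_slope": float(hi[0]),
    }


def competition_curve(
    p: HuvecParameters | None = None,
    igg4_fixed_mg_ml: float = 0.2,
    igg1_sweep_mg_ml: np.ndarray | None = None,
    duration_min: float = 120.0,
    drop_fraction: float = 0.05,
    with_degradation: bool = False,
) -> dict:
    """Effect of increasing apical IgG1 on IgG4 transcytosis.

    With IgG4 held just below the saturation point, increasing IgG1 should
    leave IgG4 transcytosis untouched until the *total* IgG exceeds the
    receptor saturation point.  Flags the first IgG1 level at which IgG4
    transcytosis drops more than ``drop_fraction`` below its IgG1-free
    value.
    """
    p = HuvecParameters() if p is None else p
    if igg1_sweep_mg_ml is None:
        igg1_sweep_mg_ml = np.arange(0.0, 0.8001, 0.01)
    igg1_sweep_mg_ml = np.asarray(igg1_sweep_mg_ml, dtype=float)

    out4 = np.empty(igg1_sweep_mg_ml.size)
    out1 = np.empty(igg1_sweep_mg_ml.size)
    for i, c1 in enumerate(igg1_sweep_mg_ml):
        out4[i], out1[i] = _transcytosed_igg4(
            p, c1, igg4_fixed_mg_ml, duration_min, with_degradation
        )
    if igg1_sweep_mg_ml[0] != 0.0:
        ref = _transcytosed_igg4(p, 0.0, igg4_fixed_mg_ml, duration_min,
                                 with_degradation)[0]
    else:
        ref = out4[0]
    dropped = out4 < (1.0 - drop_fraction) * ref
    onset = None
    if dropped.any():
        onset = float(igg1_sweep_mg_ml[np.where(dropped)[0][0]])
    return {
        "igg1_grid_mg_ml": igg1_sweep_mg_ml,
        "igg4_transcytosed_nM": out4,
        "igg1_transcytosed_nM": out1,
        "igg4_reference_nM": float(ref),
        "onset_igg1_mg_ml": onset,
        "onset_total_mg_ml": None if onset is None else onset + igg4_fixed_mg_ml,
    }
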