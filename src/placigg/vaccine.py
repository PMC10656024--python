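"""Tdap immunization model and its coupling into the placental simulator.

A linear plasma-cell cascade drives the maternal anti-pertussis-toxin
(alpha-PT) IgG response: an antigen bolus ``Ag0`` decays exponentially
while stimulating generation of short-lived (proportion ``rho``) and
long-lived antibody-secreting cells (ASCs); both secrete IgG, which
decays with rate ``delta_IgG``.  Time is in days post-vaccination and
IgG in mg/ml; ASC densities (per 1e6 PBMC) are an opaque scaling
absorbed by ``k_IgG``.

The cascade is linear, so it admits an exact sum-of-exponentials
solution, used as the prescribed maternal alpha-PT concentration when
coupling into the placental model.  Per the equal-subclass assumption,
the vaccine-induced IgG is carried as four parallel sub-species — one
per subclass, each a quarter of the alpha-PT concentration with that
subclass's receptor affinities — competing with the constant endogenous
subclass pool for the shared placental receptor pools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import ParameterSet, SUBCLASSES, default_parameters, igg_mass_to_molar
from .placenta import Species, SimulationResult, baseline_species, simulate
from .receptors import schedules_from_parameters

__all__ = [
    "VaccineParameters",
    "vaccine_rhs",
    "maternal_igg_pt",
    "alpha_pt_species",
    "simulate_vaccinated_pregnancy",
    "optimize_tvax",
    "fcr_deficiency_scenario",
    "dose_compensation",
    "affinity_scenario",
]

_DAYS_PER_WEEK = 7.0
_PT_PREFIX = "aPT_"

#: The plasma-cell cascade was fit to cohort titer data, so its IgG output
#: is a relative titer.  Antigen-specific IgG is a trace fraction of total
#: serum IgG (~10 mg/ml); one titer unit is taken as 1 ug/ml so the peak
#: maternal alpha-PT response (~70 titer units) lands at ~0.07 mg/ml,
#: three orders of magnitude below the endogenous subclass pool.
TITER_TO_MG_ML = 1e-3


@dataclass(frozen=True)
class VaccineParameters:
    """Pertussis immunization model parameters (days / mg/ml units)."""

    k_ASC: float = 0.6        # plasma-cell generation, 1/(1e6 PBMC day Ag)
    k_IgG: float = 0.0475     # antibody production, mg/ml * 1e6 PBMC / day
    Ag0: float = 100.0        # initial antigen dose (arbitrary dose units)
    rho: float = 96.0         # % short-lived ASC
    delta_Ag: float = 0.15    # 1/day
    delta_IgG: float = 0.033  # 1/day
    delta_S_ASC: float = 0.173   # 1/day
    delta_L_ASC: float = 6.6e-4  # 1/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 100.0:
            raise ValueError("rho is a percentage in [0, 100]")
        for name in ("k_ASC", "k_IgG", "delta_Ag", "delta_IgG",
                     "delta_S_ASC", "delta_L_ASC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Ag0 < 0:
            raise ValueError("Ag0 must be non-negative")


# State layout: [Ag, S_ASC, L_ASC, IgG_PT]
def vaccine_rhs(t: float, y: np.ndarray, p: VaccineParameters) -> np.ndarray:
    """Mass-action plasma-cell cascade derivatives (t in days)."""
    ag, s_asc, l_asc, igg = y
    r = p.rho / 100.0
    return np.array([
        -p.delta_Ag * ag,
        r * p.k_ASC * ag - p.delta_S_ASC * s_asc,
        (1.0 - r) * p.k_ASC * ag - p.delta_L_ASC * l_asc,
        p.k_IgG * (s_asc + l_asc) - p.delta_IgG * igg,
    ])


def _relax(rate_in: float, rate_out: float, t: np.ndarray) -> np.ndarray:
    """(exp(-rate_in t) - exp(-rate_out t)) / (rate_out - rate_in), safely."""
    if abs(rate_out - rate_in) < 1e-12 * max(rate_in, rate_out, 1.0):
        return t * np.exp(-rate_in * t)
    return (np.exp(-rate_in * t) - np.exp(-rate_out * t)) / (rate_out - rate_in)


def maternal_igg_pt(t_days: float | np.ndarray, p: VaccineParameters) -> float | np.ndarray:
    """Exact maternal alpha-PT IgG concentration (mg/ml) at days post-dose.

    Closed-form solution of the linear cascade with all state zero at
    t = 0 except the antigen bolus; zero for t < 0.
    """
    t = np.atleast_1d(np.asarray(t_days, dtype=float))
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        tp = t[pos]
        r = p.rho / 100.0
        a, dS, dL, dI = p.delta_Ag, p.delta_S_ASC, p.delta_L_ASC, p.delta_IgG
        # S(t) and L(t) are differences of exponentials; IgG convolves each
        # exponential term c*exp(-lam t) into c*_relax(lam, dI, t).
        total = np.zeros_like(tp)
        for amp, d_cell in ((r, dS), (1.0 - r, dL)):
            c = amp * p.k_ASC * p.Ag0 / (d_cell - a)
            total += c * (_relax(a, dI, tp) - _relax(d_cell, dI, tp))
        out[pos] = p.k_IgG * total
    return float(out[0]) if np.isscalar(t_days) else out


def alpha_pt_species(
    p_placenta: ParameterSet,
    p_vax: VaccineParameters,
    t_vax_weeks: float,
    affinity_fold: tuple[float, float] = (1.0, 1.0),
    titer_to_mg_ml: float = TITER_TO_MG_ML,
) -> list[Species]:
    """Four alpha-PT sub-species (one per subclass) for the placental model.

    ``affinity_fold`` scales the alpha-PT species' (FcRn, FcgRIIb)
    association rates; a 10-fold K_D decrease is ``(10, 1)`` etc.  The
    endogenous subclass pool is untouched.  ``titer_to_mg_ml`` converts
    the cascade's titer units to mg/ml before the molar conversion.
    """
    fold_n, fold_b = affinity_fold
    aff = p_placenta.affinities
    species = []
    for i, s in enumerate(SUBCLASSES):
        def conc(t_weeks: float, _i=i) -> float:
            days = (t_weeks - t_vax_weeks) * _DAYS_PER_WEEK
            if days <= 0:
                return 0.0
            mg_ml = titer_to_mg_ml * maternal_igg_pt(days, p_vax)
            return igg_mass_to_molar(mg_ml) / 4.0

        species.append(Species(
            name=_PT_PREFIX + s.value,
            kon_fcrn=float(aff.k_on_fcrn[i]) * fold_n,
            kon_fcgr2b=float(aff.k_on_fcgr2b[i]) * fold_b,
            k_off=aff.k_off,
            maternal=conc,
        ))
    return species


def simulate_vaccinated_pregnancy(
    p_placenta: ParameterSet | None = None,
    p_vax: VaccineParameters | None = None,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    affinity_fold: tuple[float, float] = (1.0, 1.0),
    titer_to_mg_ml: float = TITER_TO_MG_ML,
    schedules=None,
    rtol: float = 1e-8,
) -> tuple[SimulationResult, float]:
    """Simulate a pregnancy with maternal immunization at ``t_vax`` weeks.

    Returns the full trajectory (endogenous subclasses plus the four
    alpha-PT sub-species) and the fetal alpha-PT IgG concentration (M,
    summed over sub-species) at delivery.  Receptor schedules always
    anchor term expression at week 40, so preterm deliveries simply stop
    earlier on the same expression trajectory.
    """
    p_placenta = default_parameters() if p_placenta is None else p_placenta
    p_vax = VaccineParameters() if p_vax is None else p_vax
    if not 0.0 < t_vax < gestational_length:
        raise ValueError("t_vax must fall strictly inside gestation")
    if schedules is None:
        schedules = schedules_from_parameters(p_placenta, t_end=40.0)
    if gestational_length > 40.0:
        schedules = {r: s.extended(gestational_length) for r, s in schedules.items()}

    species = baseline_species(p_placenta) + alpha_pt_species(
        p_placenta, p_vax, t_vax, affinity_fold, titer_to_mg_ml
    )
    # The alpha-PT source switches on at t_vax; integrate up to the kink,
    # then restart so the stiff integrator never steps across it.
    pre = simulate(
        p_placenta, schedules, t_end=t_vax, species=species, rtol=rtol,
        t_eval=np.unique(np.concatenate([np.arange(0.0, t_vax, 1.0), [t_vax]])),
        validate=False,
    )
    t_eval = np.unique(np.concatenate([
        np.arange(np.ceil(t_vax), gestational_length, 1.0),
        [t_vax, gestational_length],
    ]))
    post = simulate(
        p_placenta, schedules, t_end=gestational_length, species=species,
        t_start=t_vax, y0=pre.y[:, -1], t_eval=t_eval, rtol=rtol,
        validate=False,
    )
    res = SimulationResult(
        t=np.concatenate([pre.t[:-1], post.t]),
        y=np.concatenate([pre.y[:, :-1], post.y], axis=1),
        p=p_placenta, schedules=schedules, species=species,
    )
    res.validate()
    pt_names = [_PT_PREFIX + s.value for s in SUBCLASSES]
    fetal_pt = float(res.fetal_at_end(pt_names).sum())
    return res, fetal_pt


def optimize_tvax(
    p_placenta: ParameterSet | None = None,
    p_vax: VaccineParameters | None = None,
    gestational_length: float = 40.0,
    sweep: tuple[float, float] = (10.0, 38.0),
    step: float = 1.0,
    refine_step: float | None = 0.25,
    rtol: float = 1e-8,
) -> dict:
    """Vaccination week maximizing fetal alpha-PT IgG at delivery.

    Sweeps ``t_vax`` on a coarse grid, then refines around the coarse
    argmax at ``refine_step`` resolution.  The sweep is clipped below the
    gestational length.
    """
    lo, hi = sweep
    hi = min(hi, gestational_length - step)
    grid = np.arange(lo, hi + 1e-9, step)
    grid = grid[grid < gestational_length]
    if grid.size == 0:
        raise ValueError("empty feasible t_vax grid")
    vals = np.array([
        simulate_vaccinated_pregnancy(
            p_placenta, p_vax, t, gestational_length, rtol=rtol
        )[1]
        for t in grid
    ])
    k = int(np.argmax(vals))
    if refine_step is None:
        fine = np.empty(0)
    else:
        fine = np.arange(
            max(lo, grid[k] - step), min(hi, grid[k] + step) + 1e-9, refine_step
        )
        fine = np.setdiff1d(np.round(fine, 6), np.round(grid, 6))
    fine_vals = np.array([
        simulate_vaccinated_pregnancy(
            p_placenta, p_vax, t, gestational_length, rtol=rtol
        )[1]
        for t in fine
    ])
    all_t = np.concatenate([grid, fine])
    all_v = np.concatenate([vals, fine_vals])
    order = np.argsort(all_t)
    all_t, all_v = all_t[order], all_v[order]
    best = int(np.argmax(all_v))
    return {
        "optimal_tvax": float(all_t[best]),
        "optimal_fetal_pt_M": float(all_v[best]),
        "tvax_grid": all_t,
        "fetal_pt_M": all_v,
    }


def refit_vaccine_response(
    days: np.ndarray,
    igg_pt: np.ndarray,
    start: VaccineParameters | None = None,
    free: tuple[str, ...] = ("k_ASC", "k_IgG", "Ag0"),
) -> VaccineParameters:
    """Least-squares refit of the cascade's optimized parameters to a
    maternal alpha-PT time course.

    The cascade is linear, so the response scales with the product
    ``k_ASC * k_IgG * Ag0``; when all three are freed only that product
    (with the fixed decay rates setting the shape) is identifiable, and
    callers should compare products rather than individual values.
    """
    from scipy.optimize import least_squares

    start = VaccineParameters() if start is None else start
    days = np.asarray(days, dtype=float)
    igg_pt = np.asarray(igg_pt, dtype=float)
    x0 = np.array([getattr(start, name) for name in free])

    def resid(x):
        p = replace(start, **dict(zip(free, x)))
        return maternal_igg_pt(days, p) - igg_pt

    fit = least_squares(resid, x0, bounds=(1e-12, np.inf))
    return replace(start, **dict(zip(free, fit.x)))


def _fetal_pt(p_placenta, p_vax, schedules=None, affinity_fold=(1.0, 1.0),
              t_vax=25.0, gestational_length=40.0, rtol=1e-8) -> float:
    return simulate_vaccinated_pregnancy(
        p_placenta, p_vax, t_vax, gestational_length,
        affinity_fold=affinity_fold, schedules=schedules, rtol=rtol,
    )[1]


_RECEPTOR_FIELDS = ("FcRnSTBtotal_end", "FcgRIIbECtotal_end", "FcRnECtotal_end")


def fcr_deficiency_scenario(
    p_placenta: ParameterSet | None = None,
    p_vax: VaccineParameters | None = None,
    receptor: str = "FcRnSTBtotal_end",
    fold_change_grid: np.ndarray | None = None,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    rtol: float = 1e-8,
) -> dict:
    """Percent change in fetal alpha-PT IgG as one receptor's term
    expression varies multiplicatively around its default."""
    if receptor not in _RECEPTOR_FIELDS:
        raise ValueError(f"receptor must be one of {_RECEPTOR_FIELDS}")
    p_placenta = default_parameters() if p_placenta is None else p_placenta
    p_vax = VaccineParameters() if p_vax is None else p_vax
    if fold_change_grid is None:
        fold_change_grid = np.logspace(-1, 1, 9)
    fold_change_grid = np.asarray(fold_change_grid, dtype=float)

    baseline = _fetal_pt(p_placenta, p_vax, t_vax=t_vax,
                         gestational_length=gestational_length, rtol=rtol)
    pct = np.empty(fold_change_grid.size)
    for i, fold in enumerate(fold_change_grid):
        if np.isclose(fold, 1.0):
            pct[i] = 0.0
            continue
        p_mod = replace(p_placenta, **{receptor: getattr(p_placenta, receptor) * fold})
        val = _fetal_pt(p_mod, p_vax, t_vax=t_vax,
                        gestational_length=gestational_length, rtol=rtol)
        pct[i] = 100.0 * (val - baseline) / baseline
    return {
        "receptor": receptor,
        "fold_change": fold_change_grid,
        "percent_change": pct,
        "baseline_fetal_pt_M": baseline,
    }


def dose_compensation(
    p_placenta: ParameterSet | None = None,
    p_vax: VaccineParameters | None = None,
    receptor: str = "FcRnSTBtotal_end",
    deficiency_fold: float = 10.0,
    dose_fold_grid: np.ndarray | None = None,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    rtol: float = 1e-8,
) -> dict:
    """Smallest vaccine dose multiplier restoring baseline alpha-PT transfer
    under a receptor deficiency.

    The antigen bolus scales the maternal IgG response linearly, but
    placental transfer is sublinear under receptor limitation, so the
    compensating dose need not equal the deficiency fold.
    """
    if receptor not in _RECEPTOR_FIELDS:
        raise ValueError(f"receptor must be one of {_RECEPTOR_FIELDS}")
    p_placenta = default_parameters() if p_placenta is None else p_placenta
    p_vax = VaccineParameters() if p_vax is None else p_vax
    if dose_fold_grid is None:
        dose_fold_grid = np.arange(1.0, 10.0 + 1e-9, 1.0)
    dose_fold_grid = np.asarray(dose_fold_grid, dtype=float)

    baseline = _fetal_pt(p_placenta, p_vax, t_vax=t_vax,
                         gestational_length=gestational_length, rtol=rtol)
    p_def = replace(
        p_placenta, **{receptor: getattr(p_placenta, receptor) / deficiency_fold}
    )
    vals = np.empty(dose_fold_grid.size)
    restoring = None
    for i, fold in enumerate(dose_fold_grid):
        vax = replace(p_vax, Ag0=p_vax.Ag0 * fold)
        vals[i] = _fetal_pt(p_def, vax, t_vax=t_vax,
                            gestational_length=gestational_length, rtol=rtol)
        if restoring is None and vals[i] >= baseline:
            restoring = float(fold)
    return {
        "receptor": receptor,
        "deficiency_fold": deficiency_fold,
        "dose_fold": dose_fold_grid,
        "fetal_pt_M": vals,
        "baseline_fetal_pt_M": baseline,
        "restoring_dose_fold": restoring,  # None => unbounded on this grid
    }


def affinity_scenario(
    p_placenta: ParameterSet | None = None,
    p_vax: VaccineParameters | None = None,
    target: str = "FcRn",
    KD_fold_decrease: float = 10.0,
    t_vax: float = 25.0,
    gestational_length: float = 40.0,
    rtol: float = 1e-8,
) -> dict:
    """Percent change in fetal alpha-PT IgG when the vaccine-induced IgG's
    receptor affinity is increased (K_D decreased), baseline pool unchanged."""
    if target not in ("FcRn", "FcgRIIb", "both"):
        raise ValueError("target must be FcRn, FcgRIIb, or both")
    p_placenta = default_parameters() if p_placenta is None else p_placenta
    p_vax = VaccineParameters() if p_vax is None else p_vax
    fold_n = KD_fold_decrease if target in ("FcRn", "both") else 1.0
    fold_b = KD_fold_decrease if target in ("FcgRIIb", "both") else 1.0

    baseline = _fetal_pt(p_placenta, p_vax, t_vax=t_vax,
                         gestational_length=gestational_length, rtol=rtol)
    val = _fetal_pt(p_placenta, p_vax, affinity_fold=(fold_n, fold_b),
                    t_vax=t_vax, gestational_length=gestational_length, rtol=rtol)
    return {
        "target": target,
        "KD_fold_decrease": KD_fold_decrease,
        "percent_change": 100.0 * (val - baseline) / baseline,
        "baseline_fetal_pt_M": baseline,
        "fetal_pt_M": val,
    }
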