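"""Five-compartment mass-action model of transplacental IgG transport.

IgG travels from maternal blood (M) into syncytiotrophoblast endosomes
(STB), where it binds FcRn at acidified pH; bound complexes are
transcytosed into the villous stroma (STR).  From the stroma IgG either
binds FcgRIIb at the fetal endothelial cell surface or is taken up into
EC endosomes where it binds EC FcRn; complexes of either receptor are
transcytosed into fetal blood (F).  Unbound endosomal IgG is degraded in
lysosomes, and fetal IgG decays with clearance ``delta_Ab``.  All four
subclasses (plus any vaccine-induced species) share the three receptor
pools, so transfer is competitive whenever receptor expression is
limiting.

State per species: [IgG_STB, C_STB, IgG_STR, IgG_EC, C_EC_FcRn,
C_EC_FcgRIIb, IgG_F].  Maternal concentrations are held constant by
default (a prescribed boundary condition); ``deplete_maternal=True``
integrates the maternal compartment too, which together with zero
degradation makes total IgG moles exactly conserved — the basis of the
mass-balance tests.

Binding fluxes are written in mol/week and divided by the receiving
compartment's volume, so every exchange between compartments conserves
moles; the stroma <-> EC-surface binding therefore carries a V_EC/V_STR
factor on the stromal side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ParameterSet, SUBCLASSES, default_parameters
from .receptors import FcRSchedule, Receptor, schedules_from_parameters

__all__ = [
    "Species",
    "SimulationResult",
    "SimulationError",
    "baseline_species",
    "placental_rhs",
    "simulate",
    "subclass_entropy",
    "fm_hierarchy_holds",
    "ec_receptor_variant",
    "competition_experiment",
    "HIERARCHY",
]

#: The subclass transfer hierarchy most frequently reported for humans.
HIERARCHY: tuple[str, ...] = ("IgG1", "IgG3", "IgG4", "IgG2")

_N_STATES = 7  # per-species compartments excluding maternal
_IDX = {name: i for i, name in enumerate(
    ["IgG_STB", "C_STB", "IgG_STR", "IgG_EC", "C_EC_FcRn", "C_EC_FcgRIIb", "IgG_F"]
)}


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries solver diagnostics."""


@dataclass(frozen=True)
class Species:
    """One transported IgG species (a subclass or a vaccine-induced pool).

    ``maternal`` is either a constant molar concentration or a function of
    gestational week giving the prescribed maternal concentration.
    """

    name: str
    kon_fcrn: float   # 1/(M week)
    kon_fcgr2b: float
    k_off: float      # 1/week
    maternal: float | Callable[[float], float]

    def maternal_at(self, t: float) -> float:
        return self.maternal(t) if callable(self.maternal) else self.maternal


def baseline_species(p: ParameterSet) -> list[Species]:
    """The four endogenous subclass species of a parameter set."""
    aff = p.affinities
    return [
        Species(
            name=s.value,
            kon_fcrn=float(aff.k_on_fcrn[i]),
            kon_fcgr2b=float(aff.k_on_fcgr2b[i]),
            k_off=aff.k_off,
            maternal=float(p.igg0[i]),
        )
        for i, s in enumerate(SUBCLASSES)
    ]


def _maternal_vector(species: Sequence[Species], t: float) -> np.ndarray:
    return np.array([sp.maternal_at(t) for sp in species])


def placental_rhs(
    t: float,
    y: np.ndarray,
    p: ParameterSet,
    schedules: dict[Receptor, FcRSchedule],
    species: Sequence[Species],
    deplete_maternal: bool = False,
    source: Callable[[float], np.ndarray] | None = None,
) -> np.ndarray:
    """Derivative of the placental state vector at gestational week ``t``.

    ``y`` holds 7 states per species (see module docstring), followed by
    one maternal concentration per species when ``deplete_maternal``.
    ``source`` adds an external mol/(L week) input to the maternal
    compartment (only meaningful with ``deplete_maternal``).
    """
    n_sp = len(species)
    Y = y[: _N_STATES * n_sp].reshape(n_sp, _N_STATES)
    stb, c_stb, strm, ec, c_ecn, c_r2b, fet = (Y[:, i] for i in range(_N_STATES))

    if deplete_maternal:
        m = y[_N_STATES * n_sp:]
    else:
        m = _maternal_vector(species, t)

    kon_n = np.array([sp.kon_fcrn for sp in species])
    kon_b = np.array([sp.kon_fcgr2b for sp in species])
    koff = np.array([sp.k_off for sp in species])

    rn_stb_free = schedules[Receptor.FcRn_STB].total_at(t) - c_stb.sum()
    rn_ec_free = schedules[Receptor.FcRn_EC].total_at(t) - c_ecn.sum()
    r2b_free = schedules[Receptor.FcgRIIb_EC].total_at(t) - c_r2b.sum()

    ku, kt, kd, dab = p.k_up, p.k_trans, p.k_deg, p.delta_Ab
    v_m, v_stb, v_str, v_ec, v_f = p.V_M, p.V_STB, p.V_STR, p.V_EC, p.V_F

    bind_stb = kon_n * stb * rn_stb_free - koff * c_stb      # M/week in V_STB
    bind_ecn = kon_n * ec * rn_ec_free - koff * c_ecn        # M/week in V_EC
    bind_r2b = kon_b * strm * r2b_free - koff * c_r2b        # M/week in V_EC

    d = np.empty_like(Y)
    d[:, _IDX["IgG_STB"]] = ku / v_stb * m - bind_stb - kd / v_stb * stb
    d[:, _IDX["C_STB"]] = bind_stb - kt / v_stb * c_stb
    d[:, _IDX["IgG_STR"]] = (
        kt / v_str * c_stb - ku / v_str * strm - (v_ec / v_str) * bind_r2b
    )
    d[:, _IDX["IgG_EC"]] = ku / v_ec * strm - bind_ecn - kd / v_ec * ec
    d[:, _IDX["C_EC_FcRn"]] = bind_ecn - kt / v_ec * c_ecn
    d[:, _IDX["C_EC_FcgRIIb"]] = bind_r2b - kt / v_ec * c_r2b
    d[:, _IDX["IgG_F"]] = kt / v_f * (c_ecn + c_r2b) - dab / v_f * fet

    out = d.reshape(-1)
    if deplete_maternal:
        dm = -ku / v_m * m
        if source is not None:
            dm = dm + source(t)
        out = np.concatenate([out, dm])
    return out


@dataclass
class SimulationResult:
    """Trajectory of a placental simulation on a weekly (or finer) grid."""

    t: np.ndarray                 # (n_t,) gestational weeks
    y: np.ndarray                 # (n_states, n_t)
    p: ParameterSet
    schedules: dict[Receptor, FcRSchedule]
    species: list[Species] = field(repr=False)
    deplete_maternal: bool = False

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def _block(self, compartment: str) -> np.ndarray:
        n_sp = len(self.species)
        return self.y[: _N_STATES * n_sp].reshape(n_sp, _N_STATES, -1)[
            :, _IDX[compartment], :
        ]

    def compartment(self, name: str) -> np.ndarray:
        """(n_species, n_t) concentrations of one compartment."""
        return self._block(name)

    @property
    def fetal(self) -> np.ndarray:
        return self._block("IgG_F")

    @property
    def maternal(self) -> np.ndarray:
        n_sp = len(self.species)
        if self.deplete_maternal:
            return self.y[_N_STATES * n_sp:]
        return np.array([
            [sp.maternal_at(t) for t in self.t] for sp in self.species
        ])

    @property
    def fm_ratio(self) -> np.ndarray:
        """Fetal:maternal concentration ratio per species over time."""
        m = self.maternal
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(m > 0, self.fetal / m, np.nan)

    def total_fetal(self, names: Sequence[str] | None = None) -> np.ndarray:
        idx = self._name_index(names)
        return self.fetal[idx].sum(axis=0)

    def fetal_at_end(self, names: Sequence[str] | None = None) -> np.ndarray:
        idx = self._name_index(names)
        return self.fetal[idx, -1]

    def fm_at_end(self, names: Sequence[str] | None = None) -> np.ndarray:
        idx = self._name_index(names)
        return self.fm_ratio[idx, -1]

    def entropy_series(self) -> np.ndarray:
        """Subclass entropy of the four endogenous subclasses over time."""
        idx = self._name_index([s.value for s in SUBCLASSES])
        fet = self.fetal[idx]
        out = np.full(fet.shape[1], np.nan)
        ok = fet.sum(axis=0) > 0
        if ok.any():
            out[ok] = np.array([subclass_entropy(fet[:, j]) for j in np.where(ok)[0]])
        return out

    def _name_index(self, names: Sequence[str] | None) -> np.ndarray:
        if names is None:
            return np.arange(len(self.species))
        lookup = {sp.name: i for i, sp in enumerate(self.species)}
        return np.array([lookup[n] for n in names])

    def total_moles(self) -> np.ndarray:
        """Total IgG moles across all compartments at each saved time."""
        p = self.p
        blocks = {k: self._block(k) for k in _IDX}
        moles = (
            p.V_STB * (blocks["IgG_STB"] + blocks["C_STB"])
            + p.V_STR * blocks["IgG_STR"]
            + p.V_EC * (blocks["IgG_EC"] + blocks["C_EC_FcRn"] + blocks["C_EC_FcgRIIb"])
            + p.V_F * blocks["IgG_F"]
        ).sum(axis=0)
        if self.deplete_maternal:
            moles = moles + p.V_M * self.maternal.sum(axis=0)
        return moles

    def validate(self, slack: float = 1e-9) -> None:
        """Check non-negativity and bound-receptor <= scheduled totals."""
        if self.y.min() < -slack:
            raise SimulationError(
                f"negative concentration in trajectory: {self.y.min():.3e}"
            )
        for comp, receptor in [
            ("C_STB", Receptor.FcRn_STB),
            ("C_EC_FcRn", Receptor.FcRn_EC),
            ("C_EC_FcgRIIb", Receptor.FcgRIIb_EC),
        ]:
            bound = self._block(comp).sum(axis=0)
            total = self.schedules[receptor].total_at(self.t)
            if np.any(bound > total + slack):
                raise SimulationError(f"bound {comp} exceeds scheduled total")


def simulate(
    p: ParameterSet | None = None,
    schedules: dict[Receptor, FcRSchedule] | None = None,
    t_end: float = 40.0,
    *,
    species: Sequence[Species] | None = None,
    t_start: float = 0.0,
    y0: np.ndarray | None = None,
    deplete_maternal: bool = False,
    source: Callable[[float], np.ndarray] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
    validate: bool = True,
) -> SimulationResult:
    """Integrate the placental model from conception (or ``t_start``) to term.

    Dense output is saved at weekly resolution (plus ``t_end``) unless a
    custom ``t_eval`` is given.  The system couples per-second binding
    kinetics with per-week transport, so a stiff (LSODA) integrator with
    tight tolerances is used throughout.
    """
    p = default_parameters() if p is None else p
    if schedules is None:
        schedules = schedules_from_parameters(p, t_end=min(t_end, 40.0))
    if t_end > 40.0:
        schedules = {r: s.extended(t_end) for r, s in schedules.items()}
    sp = list(baseline_species(p) if species is None else species)

    n = _N_STATES * len(sp) + (len(sp) if deplete_maternal else 0)
    if y0 is None:
        y0 = np.zeros(n)
        if deplete_maternal:
            y0[_N_STATES * len(sp):] = _maternal_vector(sp, t_start)
    if t_eval is None:
        t_eval = np.unique(np.concatenate([
            np.arange(np.ceil(t_start), t_end, 1.0), [t_start, t_end]
        ]))
    sol = solve_ivp(
        placental_rhs,
        (t_start, t_end),
        y0,
        args=(p, schedules, sp, deplete_maternal, source),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    res = SimulationResult(
        t=sol.t, y=sol.y, p=p, schedules=schedules, species=sp,
        deplete_maternal=deplete_maternal,
    )
    if validate:
        res.validate()
    return res


def subclass_entropy(fetal: np.ndarray) -> float:
    """Shannon entropy (natural log) of the fetal subclass distribution.

    ``E = -sum_i P_i ln P_i`` with ``P_i`` the proportion of each subclass;
    ``0 ln 0 := 0``.  Low entropy indicates selective transfer.
    """
    c = np.asarray(fetal, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one subclass concentration must be positive")
    P = c / total
    nz = P > 0
    return float(-(P[nz] * np.log(P[nz])).sum())


def fm_hierarchy_holds(fm: np.ndarray, names: Sequence[str],
                       order: Sequence[str] = HIERARCHY) -> bool:
    """True iff the F:M values strictly follow ``order`` (ties fail)."""
    vals = dict(zip(names, fm))
    ranked = [vals[n] for n in order]
    return all(a > b for a, b in zip(ranked, ranked[1:]))


def _variant_schedules(p, variant, fcrn_ec_end, r2b_ec_end, t_end=40.0):
    sched = schedules_from_parameters(p, t_end=t_end)
    from .receptors import make_schedule
    if variant == "FcRn_only":
        r2b_ec_end = 0.0
    elif variant == "R2b_only":
        fcrn_ec_end = 0.0
    elif variant != "co_expressed":
        raise ValueError(f"unknown variant {variant!r}")
    for receptor, r_end in [
        (Receptor.FcRn_EC, fcrn_ec_end),
        (Receptor.FcgRIIb_EC, r2b_ec_end),
    ]:
        if r_end > 0:
            sched[receptor] = make_schedule(receptor, r_end, t_end)
        else:
            sched[receptor] = sched[receptor].scaled(0.0)
    return sched


def ec_receptor_variant(
    p: ParameterSet | None = None,
    variant: str = "co_expressed",
    expression_sweep: np.ndarray | None = None,
    t_end: float = 40.0,
    rtol: float = 1e-8,
) -> dict:
    """Sweep EC receptor expression under three EC receptor-variant models.

    ``co_expressed`` sweeps the EC FcRn term expression as a *fraction* of
    the (default) EC FcgRIIb term expression; ``FcRn_only`` and
    ``R2b_only`` remove the other receptor's pathway and sweep the
    remaining receptor's term expression (M).  Returns the grid, per-grid
    F:M ratios per subclass, and for the co-expressed variant the largest
    FcRn:FcgRIIb percentage at which the IgG1 > IgG3 > IgG4 > IgG2
    hierarchy holds (midpoint between the last passing and first failing
    grid ratio).
    """
    p = default_parameters() if p is None else p
    if expression_sweep is None:
        if variant == "co_expressed":
            # 50 log-spaced points per decade over 1%..100% of FcgRIIb.
            expression_sweep = np.logspace(-2, 0, 101)
        else:
            base = p.FcRnECtotal_end if variant == "FcRn_only" else p.FcgRIIbECtotal_end
            expression_sweep = base * np.logspace(-2, 2, 41)
    expression_sweep = np.asarray(expression_sweep, dtype=float)
    if expression_sweep.size == 0:
        raise ValueError("empty expression sweep")

    names = [s.value for s in SUBCLASSES]
    fm = np.empty((expression_sweep.size, len(names)))
    holds = np.zeros(expression_sweep.size, dtype=bool)
    for i, x in enumerate(expression_sweep):
        if variant == "co_expressed":
            sched = _variant_schedules(
                p, variant, x * p.FcgRIIbECtotal_end, p.FcgRIIbECtotal_end, t_end
            )
        elif variant == "FcRn_only":
            sched = _variant_schedules(p, variant, x, 0.0, t_end)
        else:
            sched = _variant_schedules(p, variant, 0.0, x, t_end)
        res = simulate(p, sched, t_end, rtol=rtol)
        fm[i] = res.fm_at_end(names)
        holds[i] = fm_hierarchy_holds(fm[i], names)

    out = {"grid": expression_sweep, "fm": fm, "subclasses": names,
           "hierarchy_holds": holds}
    if variant == "co_expressed":
        out["hierarchy_threshold_pct"] = _threshold_pct(expression_sweep, holds)
    return out


def _threshold_pct(grid: np.ndarray, holds: np.ndarray) -> float | None:
    """Largest passing ratio (%), as the midpoint to the first failing one."""
    if not holds.any():
        return None
    last_pass = np.where(holds)[0].max()
    if last_pass + 1 < grid.size:
        return 100.0 * 0.5 * (grid[last_pass] + grid[last_pass + 1])
    return 100.0 * grid[last_pass]


def competition_experiment(
    p: ParameterSet | None = None,
    R2b_sweep: np.ndarray | None = None,
    t_end: float = 40.0,
    rtol: float = 1e-8,
) -> dict:
    """Isolated vs. mixed subclass transfer over an EC FcgRIIb sweep.

    For each FcgRIIb term-expression level, F:M at term is computed with
    all four subclasses present (``mixed``) and with each subclass alone
    in the maternal pool (``isolated``); the returned ``delta`` is
    isolated minus mixed, quantifying competition for limited receptor.
    """
    p = default_parameters() if p is None else p
    if R2b_sweep is None:
        R2b_sweep = p.FcgRIIbECtotal_end * np.logspace(-1, 1, 9)
    R2b_sweep = np.asarray(R2b_sweep, dtype=float)
    if R2b_sweep.size == 0:
        raise ValueError("empty FcgRIIb sweep")

    names = [s.value for s in SUBCLASSES]
    mixed = np.empty((R2b_sweep.size, 4))
    isolated = np.empty((R2b_sweep.size, 4))
    from .receptors import make_schedule
    for i, r_end in enumerate(R2b_sweep):
        sched = schedules_from_parameters(p, t_end=t_end)
        sched[Receptor.FcgRIIb_EC] = make_schedule(Receptor.FcgRIIb_EC, r_end, t_end)
        mixed[i] = simulate(p, sched, t_end, rtol=rtol).fm_at_end(names)
        for j in range(4):
            solo = list(baseline_species(p))
            solo = [
                Species(sp.name, sp.kon_fcrn, sp.kon_fcgr2b, sp.k_off,
                        sp.maternal if k == j else 0.0)
                for k, sp in enumerate(solo)
            ]
            res = simulate(p, sched, t_end, species=solo, rtol=rtol)
            fm = res.fm_ratio[j, -1]
            isolated[i, j] = fm
    return {
        "grid": R2b_sweep, "subclasses": names,
        "mixed": mixed, "isolated": isolated, "delta": isolated - mixed,
    }
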