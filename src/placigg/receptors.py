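"""Time-varying placental Fc receptor expression schedules.

Total FcRn in syncytiotrophoblasts (STB), FcRn in endothelial cells (EC),
and FcgRIIb in ECs increase across gestation.  Each schedule is a convex,
monotone non-decreasing quadratic in gestational week, fixed to a term
expression level ``R_end`` at ``t_end``.  The default shape is
``R(t) = R_end * (t / t_end)**2`` — zero at conception, convex, and the
simplest curve meeting every constraint; custom quadratic coefficients are
accepted when they satisfy the same constraints.

Receptor conservation is enforced algebraically downstream
(free = total - bound), which is equivalent to integrating a separate
free-receptor equation with an explicit synthesis source when synthesis
adds only free receptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Receptor", "FcRSchedule", "make_schedule", "schedules_from_parameters"]


class Receptor(str, Enum):
    FcRn_STB = "FcRn_STB"
    FcRn_EC = "FcRn_EC"
    FcgRIIb_EC = "FcgRIIb_EC"


@dataclass(frozen=True)
class FcRSchedule:
    """Quadratic total-expression curve R(t) = a t^2 + b t + c on [0, t_end]."""

    receptor: Receptor
    a: float
    b: float
    c: float
    t_end: float
    #: End of the evaluation domain; defaults to t_end.  A simulation run a
    #: little past term (e.g. a 41-week delivery) extends the same quadratic.
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.t_max is not None and self.t_max < self.t_end:
            raise ValueError("t_max must be >= t_end")
        if self.a < 0:
            raise ValueError("schedule must be convex (a >= 0)")
        # Monotone non-decreasing and non-negative on [0, t_end]: with a >= 0
        # it suffices that R'(0) >= 0 and R(0) >= 0.
        if self.b < 0:
            raise ValueError("schedule must be non-decreasing on [0, t_end]")
        if self.c < 0:
            raise ValueError("schedule must be non-negative at t = 0")

    @property
    def R_end(self) -> float:
        return self.total_at(self.t_end)

    def _check_domain(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t_hi = self.t_end if self.t_max is None else self.t_max
        if np.any(t < 0) or np.any(t > t_hi + 1e-9):
            raise ValueError(f"t outside [0, {t_hi}]")
        return t

    def total_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Total receptor expression (M) at gestational week t."""
        tt = self._check_domain(t)
        out = self.a * tt**2 + self.b * tt + self.c
        return float(out) if np.isscalar(t) else out

    def synthesis_rate_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """dR/dt (M/week), the synthesis of new receptor as the placenta grows."""
        tt = self._check_domain(t)
        out = 2 * self.a * tt + self.b
        return float(out) if np.isscalar(t) else out

    def scaled(self, factor: float) -> "FcRSchedule":
        """Schedule with expression multiplied by a non-negative factor."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        return FcRSchedule(self.receptor, self.a * factor, self.b * factor,
                           self.c * factor, self.t_end, self.t_max)

    def extended(self, t_max: float) -> "FcRSchedule":
        """Same curve with the evaluation domain extended to ``t_max``."""
        return FcRSchedule(self.receptor, self.a, self.b, self.c,
                           self.t_end, max(t_max, self.t_end))


def make_schedule(
    receptor: Receptor | str,
    R_end: float,
    t_end: float = 40.0,
    shape: tuple[float, float, float] | None = None,
) -> FcRSchedule:
    """Construct a receptor schedule reaching ``R_end`` at ``t_end``.

    With ``shape=None`` the default pure quadratic through the origin is
    used.  A custom ``(a, b, c)`` must satisfy convexity, monotonicity,
    non-negativity, and R(t_end) = R_end (to 1e-9 relative).
    """
    if R_end <= 0 or t_end <= 0:
        raise ValueError("R_end and t_end must be positive")
    receptor = Receptor(receptor)
    if shape is None:
        return FcRSchedule(receptor, R_end / t_end**2, 0.0, 0.0, t_end)
    a, b, c = shape
    sched = FcRSchedule(receptor, a, b, c, t_end)
    if abs(sched.R_end - R_end) > 1e-9 * R_end:
        raise ValueError("custom shape does not reach R_end at t_end")
    return sched


def schedules_from_parameters(p, t_end: float = 40.0) -> dict[Receptor, FcRSchedule]:
    """Default schedules for the three receptor pools of a parameter set."""
    return {
        Receptor.FcRn_STB: make_schedule(Receptor.FcRn_STB, p.FcRnSTBtotal_end, t_end),
        Receptor.FcRn_EC: make_schedule(Receptor.FcRn_EC, p.FcRnECtotal_end, t_end),
        Receptor.FcgRIIb_EC: make_schedule(Receptor.FcgRIIb_EC, p.FcgRIIbECtotal_end, t_end),
    }
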