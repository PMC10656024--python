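"""Model parameters, units, and configuration I/O.

The internal unit system is fixed: time in gestational **weeks**,
concentrations in **molar (M)**, compartment volumes in **liters**.
Transport rate constants (``k_up``, ``k_trans``, ``k_deg``, ``delta_Ab``)
carry units of L/week and act as clearances: the molar flux out of a
compartment at concentration C is ``k * C`` mol/week, and the receiving
compartment's concentration derivative divides by its own volume.
Binding kinetics are tabulated per second in the literature and are
converted to per-week on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "IgGSubclass",
    "SUBCLASSES",
    "AffinityTable",
    "ParameterSet",
    "ParameterRange",
    "SECONDS_PER_WEEK",
    "IGG_MOLAR_MASS_G_PER_MOL",
    "FETAL_IGG_CLEARANCE_L_PER_WEEK",
    "FETAL_IGG_HALF_LIFE_DAYS",
    "derive_kinetic_rates",
    "igg_mass_to_molar",
    "igg_molar_to_mass",
    "clearance_from_half_life",
    "default_parameters",
    "default_ranges",
    "load_parameters",
    "save_parameters",
]

SECONDS_PER_WEEK = 7 * 24 * 3600  # 604800

#: Molecular weight used for every IgG subclass in mg/ml <-> M conversion.
IGG_MOLAR_MASS_G_PER_MOL = 150_000.0

#: Fetal IgG clearance as tabulated from infant half-life data (L/week).
FETAL_IGG_CLEARANCE_L_PER_WEEK = 0.02

#: Alternative basis: IgG half-life of 31 days in the fetus.  With the
#: clearance convention the equivalent L/week value is
#: ``clearance_from_half_life(31, V_F)``; the packaged default uses the
#: tabulated 0.02 L/week.
FETAL_IGG_HALF_LIFE_DAYS = 31.0


class IgGSubclass(str, Enum):
    """The four human IgG subclasses carried by every per-subclass container."""

    IgG1 = "IgG1"
    IgG2 = "IgG2"
    IgG3 = "IgG3"
    IgG4 = "IgG4"

    @property
    def index(self) -> int:
        return list(IgGSubclass).index(self)


SUBCLASSES: tuple[IgGSubclass, ...] = tuple(IgGSubclass)

# Equilibrium dissociation constants (M), receptor x subclass, from surface
# plasmon resonance literature.  k_off = 0.15 /s for every pair; k_on follows
# from k_on = k_off / K_D.
_KD_FCRN = {"IgG1": 1.25e-8, "IgG2": 2e-8, "IgG3": 3.3e-8, "IgG4": 5e-8}
_KD_FCGR2B = {"IgG1": 1e-5, "IgG2": 5e-5, "IgG3": 5e-6, "IgG4": 5e-6}
_KOFF_PER_S = 0.15

# Maternal serum concentration per subclass (M), cordocentesis cohort.
_IGG0 = {"IgG1": 3.78e-5, "IgG2": 1.81e-5, "IgG3": 2.35e-6, "IgG4": 2.27e-6}

# Calibrated ranges for the 11 free parameters (lower, upper).
_FREE_RANGES = {
    "k_up": (0.0872, 0.0982),          # L/week, uptake into cells
    "k_trans": (0.0569, 0.0743),       # L/week, transcytosis
    "k_deg": (8.4733, 9.0809),         # L/week, lysosomal degradation
    "FcRnSTBtotal_end": (3.33e-5, 4.94e-5),    # M, STB FcRn at term
    "FcgRIIbECtotal_end": (2.73e-5, 3.33e-5),  # M, EC FcgRIIb at term
    "FcRnECtotal_end": (2.36e-6, 2.86e-6),     # M, EC FcRn at term
    "V_M": (5.552, 5.619),             # L, maternal blood
    "V_STB": (0.224, 0.258),           # L, STB endosomal
    "V_STR": (0.165, 0.179),           # L, stromal
    "V_EC": (0.247, 0.275),            # L, EC endosomal
    "V_F": (0.254, 0.271),             # L, fetal blood
}

FREE_PARAMETER_NAMES: tuple[str, ...] = tuple(_FREE_RANGES)


def derive_kinetic_rates(K_D: float, k_off_per_s: float) -> tuple[float, float]:
    """Convert a dissociation constant and per-second off-rate to per-week rates.

    Returns ``(k_on, k_off)`` with k_on in 1/(M*week) and k_off in 1/week,
    satisfying ``k_on * K_D == k_off`` after conversion.
    """
    if K_D <= 0 or k_off_per_s <= 0:
        raise ValueError("K_D and k_off must be strictly positive")
    k_on_per_s = k_off_per_s / K_D
    return k_on_per_s * SECONDS_PER_WEEK, k_off_per_s * SECONDS_PER_WEEK


def igg_mass_to_molar(c_mg_per_ml: float | np.ndarray) -> float | np.ndarray:
    """Convert an IgG concentration in mg/ml to molar (150 kDa convention)."""
    c = np.asarray(c_mg_per_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * 1000.0 / IGG_MOLAR_MASS_G_PER_MOL / 1000.0  # mg/ml == g/L
    return float(out) if np.isscalar(c_mg_per_ml) else out


def igg_molar_to_mass(c_molar: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`igg_mass_to_molar`."""
    c = np.asarray(c_molar, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * IGG_MOLAR_MASS_G_PER_MOL
    return float(out) if np.isscalar(c_molar) else out


def clearance_from_half_life(t_half_days: float, volume_l: float) -> float:
    """Clearance (L/week) equivalent to a first-order half-life in a volume."""
    return math.log(2) / (t_half_days / 7.0) * volume_l


@dataclass(frozen=True)
class AffinityTable:
    """Receptor-IgG binding kinetics per (receptor, subclass) pair.

    ``kd[r][i]`` is molar; ``k_on``/``k_off`` are in the internal per-week
    unit system and satisfy ``k_on * K_D == k_off``.
    """

    kd_fcrn: np.ndarray    # (4,) M
    kd_fcgr2b: np.ndarray  # (4,) M
    k_off: float           # 1/week, shared across pairs

    def __post_init__(self) -> None:
        for arr in (self.kd_fcrn, self.kd_fcgr2b):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("dissociation constants must be positive")
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if np.any(self.kd_fcrn >= self.kd_fcgr2b):
            raise ValueError("FcRn must bind every subclass tighter than FcgRIIb")

    @property
    def k_on_fcrn(self) -> np.ndarray:
        return self.k_off / self.kd_fcrn

    @property
    def k_on_fcgr2b(self) -> np.ndarray:
        return self.k_off / self.kd_fcgr2b

    @classmethod
    def default(cls) -> "AffinityTable":
        return cls(
            kd_fcrn=np.array([_KD_FCRN[s.value] for s in SUBCLASSES]),
            kd_fcgr2b=np.array([_KD_FCGR2B[s.value] for s in SUBCLASSES]),
            k_off=_KOFF_PER_S * SECONDS_PER_WEEK,
        )


@dataclass(frozen=True)
class ParameterSet:
    """Full placental-model parameterization in internal units."""

    k_up: float
    k_trans: float
    k_deg: float
    FcRnSTBtotal_end: float
    FcgRIIbECtotal_end: float
    FcRnECtotal_end: float
    V_M: float
    V_STB: float
    V_STR: float
    V_EC: float
    V_F: float
    delta_Ab: float = FETAL_IGG_CLEARANCE_L_PER_WEEK
    igg0: np.ndarray = field(
        default_factory=lambda: np.array([_IGG0[s.value] for s in SUBCLASSES])
    )
    affinities: AffinityTable = field(default_factory=AffinityTable.default)

    def __post_init__(self) -> None:
        for name in (
            "k_up", "k_trans", "k_deg", "FcRnSTBtotal_end",
            "FcgRIIbECtotal_end", "FcRnECtotal_end",
            "V_M", "V_STB", "V_STR", "V_EC", "V_F", "delta_Ab",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if np.any(np.asarray(self.igg0) < 0):
            raise ValueError("maternal subclass concentrations must be >= 0")
        total_volume = self.V_M + self.V_STB + self.V_STR + self.V_EC + self.V_F
        if total_volume >= 10.0:
            raise ValueError("compartment volumes sum to an unphysiologic total")

    @property
    def volumes(self) -> dict[str, float]:
        return {
            "V_M": self.V_M, "V_STB": self.V_STB, "V_STR": self.V_STR,
            "V_EC": self.V_EC, "V_F": self.V_F,
        }

    def with_free_values(self, values: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the named free parameters replaced."""
        unknown = set(values) - set(FREE_PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"not free parameters: {sorted(unknown)}")
        return replace(self, **dict(values))

    def free_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FREE_PARAMETER_NAMES}

    def to_config(self) -> dict[str, float]:
        """Flat key-value document using the tabulated symbol names."""
        cfg: dict[str, float] = {name: getattr(self, name) for name in FREE_PARAMETER_NAMES}
        cfg["delta_Ab"] = self.delta_Ab
        for i, s in enumerate(SUBCLASSES):
            cfg[f"{s.value}_0"] = float(self.igg0[i])
            cfg[f"KD_FcRn_{s.value}"] = float(self.affinities.kd_fcrn[i])
            cfg[f"KD_FcgRIIb_{s.value}"] = float(self.affinities.kd_fcgr2b[i])
        cfg["k_off_per_s"] = self.affinities.k_off / SECONDS_PER_WEEK
        return cfg


@dataclass(frozen=True)
class ParameterRange:
    """Lower/upper bounds per free parameter (degenerate bounds = fixed)."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"range for {name} has lower > upper")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return lo, hi

    def contains(self, values: Mapping[str, float]) -> bool:
        return all(
            self.bounds[n][0] <= values[n] <= self.bounds[n][1] for n in self.names
        )


def default_ranges() -> ParameterRange:
    """Calibrated plausible range per free parameter."""
    return ParameterRange({k: v for k, v in _FREE_RANGES.items()})


def default_parameters() -> ParameterSet:
    """Packaged defaults: the midpoint of every calibrated range."""
    mids = {k: 0.5 * (lo + hi) for k, (lo, hi) in _FREE_RANGES.items()}
    return ParameterSet(**mids)


def load_parameters(config: str | Path | Mapping) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a flat config document.

    ``config`` may be a mapping, a YAML file path, or the literal string
    ``"defaults"``.  Missing free parameters fall back to the packaged
    defaults (range midpoints); affinity and maternal-concentration keys
    are optional and default to the tabulated values.
    """
    if isinstance(config, str) and config == "defaults":
        return default_parameters()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise ValueError(f"config file {config} does not hold a mapping")
    else:
        doc = config
    doc = dict(doc)

    defaults = default_parameters().to_config()
    known = set(defaults)
    unknown = set(doc) - known
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    merged = {**defaults, **{k: float(v) for k, v in doc.items()}}

    kd_fcrn = np.array([merged[f"KD_FcRn_{s.value}"] for s in SUBCLASSES])
    kd_r2b = np.array([merged[f"KD_FcgRIIb_{s.value}"] for s in SUBCLASSES])
    affinities = AffinityTable(
        kd_fcrn=kd_fcrn, kd_fcgr2b=kd_r2b,
        k_off=merged["k_off_per_s"] * SECONDS_PER_WEEK,
    )
    igg0 = np.array([merged[f"{s.value}_0"] for s in SUBCLASSES])
    return ParameterSet(
        **{name: merged[name] for name in FREE_PARAMETER_NAMES},
        delta_Ab=merged["delta_Ab"],
        igg0=igg0,
        affinities=affinities,
    )


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    """Serialize a parameter set to a flat YAML config (round-trip exact)."""
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_config(), fh, sort_keys=True)


def export_parameters_csv(p: ParameterSet, path: str | Path) -> None:
    """Write the full parameter table as a two-column CSV."""
    import pandas as pd

    cfg = p.to_config()
    pd.DataFrame(
        {"parameter": list(cfg), "value": list(cfg.values())}
    ).to_csv(path, index=False)
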