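"""Two-term Arrhenius model of fork opening/closing and binding energetics.

The net fork velocity (bp/s, opening positive) is the difference of two
force-dependent Arrhenius terms::

    v_net(F) = k_on * conc * exp[(c(F)*F - c(F_unz)*F_unz) * dz_on / kBT]
             - k_off * exp[-c(F)*F * dz_off / kBT]

``k_on`` is the per-nM association pre-factor at the unzipping force,
``k_off`` the dissociation pre-factor at zero force, and ``dz_on``/
``dz_off`` the transition-state distances in bp (the few base pairs that
must transiently open, or rezip, for a full protein to bind or be
displaced).  ``c(F)`` is the geometry-dependent conversion factor from
:mod:`forkdyn.elasticity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .elasticity import (
    ElasticityModel,
    PN_NM_TO_KJ_PER_MOL,
    basepair_energy_from_unzipping,
    conversion_factor,
)

__all__ = [
    "KineticParameters",
    "EnergeticsResult",
    "NoEquilibriumError",
    "DegenerateEquilibriumError",
    "opening_rate",
    "closing_rate",
    "net_rate",
    "equilibrium_force",
    "binding_free_energy",
    "free_energy_from_K",
    "passive_unwinding_rate",
    "mg_extrapolation",
    "compute_energetics",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ / (mol K)


class NoEquilibriumError(RuntimeError):
    """The net rate does not change sign inside the search bracket."""


class DegenerateEquilibriumError(RuntimeError):
    """Every force is an equilibrium (force-independent, balanced rates)."""


@dataclass
class KineticParameters:
    """Parameter set of the two-term Arrhenius fork model.

    Rates are in bp/s, transition-state distances in bp, forces in pN and
    the concentration in nM.  ``footprint`` is the number of base pairs
    opened per bound protein (the observed step size).
    """

    k_on_per_nM: float  # bp s^-1 nM^-1, association pre-factor at F_unz
    k_off: float  # bp s^-1, dissociation pre-factor at zero force
    dz_on: float  # bp
    dz_off: float  # bp
    F_unz: float  # pN
    concentration: float  # nM
    footprint: float = 23.0  # bp per bound protein
    geometry: str = "hairpin"

    def __post_init__(self) -> None:
        if self.k_on_per_nM < 0 or self.k_off < 0:
            raise ValueError("rate pre-factors must be non-negative")
        if self.dz_on < 0 or self.dz_off < 0:
            raise ValueError("transition-state distances must be non-negative")
        if self.F_unz <= 0:
            raise ValueError("F_unz must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1 bp")
        if self.geometry not in ("hairpin", "duplex"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown kinetic keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def with_(self, **kw) -> "KineticParameters":
        return replace(self, **kw)


@dataclass
class EnergeticsResult:
    """Derived binding energetics of the fork model."""

    dG_bp_per_bp: float  # pN nm per bp, base-pairing energy
    dG_bind: float  # kJ/mol per bound protein
    F_equi: float  # pN


def _work(F, geometry, m):
    """c(F)*F, the opening work per bp (pN nm) at force F."""
    return conversion_factor(F, geometry, m, warn_nonpositive=False) * np.asarray(F, dtype=float)


def opening_rate(F, p: KineticParameters, m: ElasticityModel | None = None):
    """Association (fork-opening) branch of the model, bp/s, always >= 0."""
    m = m or ElasticityModel()
    w = _work(F, p.geometry, m)
    w_unz = _work(p.F_unz, p.geometry, m)
    return p.k_on_per_nM * p.concentration * np.exp((w - w_unz) * p.dz_on / m.kBT)


def closing_rate(F, p: KineticParameters, m: ElasticityModel | None = None):
    """Dissociation (fork-closing) branch of the model, bp/s, always >= 0."""
    m = m or ElasticityModel()
    return p.k_off * np.exp(-_work(F, p.geometry, m) * p.dz_off / m.kBT)


def net_rate(F, p: KineticParameters, m: ElasticityModel | None = None):
    """Signed net fork velocity in bp/s (positive = opening)."""
    m = m or ElasticityModel()
    return opening_rate(F, p, m) - closing_rate(F, p, m)


def equilibrium_force(
    p: KineticParameters,
    m: ElasticityModel | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = 0.01,
) -> float:
    """Force at which opening and closing balance (net rate zero), in pN.

    Bracketed bisection to ``tol`` pN.  The root is unique because both
    Arrhenius exponents are monotone in the opening work c(F)*F.
    """
    m = m or ElasticityModel()
    if p.dz_on == 0 and p.dz_off == 0:
        if np.isclose(p.k_on_per_nM * p.concentration, p.k_off):
            raise DegenerateEquilibriumError(
                "force-independent balanced rates: every force is an equilibrium"
            )
        raise NoEquilibriumError("force-independent rates never cross zero")
    lo, hi = bracket if bracket is not None else (1.0, p.F_unz + 5.0)
    f_lo = net_rate(lo, p, m)
    f_hi = net_rate(hi, p, m)
    if f_lo == 0:
        return float(lo)
    if f_hi == 0:
        return float(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoEquilibriumError(
            f"net rate does not change sign on ({lo:g}, {hi:g}) pN"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = net_rate(mid, p, m)
        if f_mid == 0:
            return float(mid)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def binding_free_energy(
    F_unz: float,
    F_equi: float,
    footprint: float = 23.0,
    m: ElasticityModel | None = None,
) -> float:
    """Binding free energy per protein (kJ/mol) from the force balance.

    At equilibrium the base-pairing energy over one footprint equals the
    mechanical opening work plus the binding energy of one protein on each
    of the two fork strands::

        dG_bind = (c_unz*F_unz - c_equi*F_equi) * footprint / 2
    """
    m = m or ElasticityModel()
    per_bp = _work(F_unz, "hairpin", m) - _work(F_equi, "hairpin", m)
    value = float(per_bp * footprint / 2.0 * PN_NM_TO_KJ_PER_MOL)
    if value < 0:
        warnings.warn("F_equi exceeds F_unz: negative binding free energy", stacklevel=2)
    return value


def free_energy_from_K(K: float, T: float = 298.0) -> float:
    """Free energy RT*ln(K / 1 M) in kJ/mol for association constant K (1/M)."""
    if K <= 0:
        raise ValueError("association constant must be positive")
    return float(GAS_CONSTANT_KJ * T * np.log(K))


def passive_unwinding_rate(
    F,
    v_max: float,
    n: float,
    F_unz: float,
    m: ElasticityModel | None = None,
):
    """Opening velocity of a passive unwinder with step size ``n`` bp.

    ``v = v_max * exp[(dG_F - dG_bp)/kBT]`` with ``dG_F = c(F)*F*n`` and
    ``dG_bp = c(F_unz)*F_unz*n`` (entropic ssDNA stretching neglected).
    Reaches ``v_max`` exactly at the unzipping force.
    """
    if n < 1:
        raise ValueError("step size n must be >= 1 bp")
    m = m or ElasticityModel()
    dG_F = _work(F, "hairpin", m) * n
    dG_bp = basepair_energy_from_unzipping(F_unz, m) * n
    return v_max * np.exp((dG_F - dG_bp) / m.kBT)


def mg_extrapolation(koff_values) -> float:
    """Zero-dissociation Mg2+ concentration from a linear extrapolation.

    ``koff_values`` is a sequence of (Mg2+ mM, closing rate bp/s) pairs;
    an ordinary least-squares line is fit and its x-intercept returned.
    """
    pts = np.asarray(koff_values, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (Mg, k_off) points")
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    if slope <= 0:
        raise ValueError("non-positive slope: closing rate does not vanish at low Mg2+")
    return float(-intercept / slope)


def compute_energetics(
    p: KineticParameters,
    m: ElasticityModel | None = None,
    F_equi: float | None = None,
) -> EnergeticsResult:
    """Bundle F_equi, per-bp pairing energy and per-protein binding energy."""
    m = m or ElasticityModel()
    if F_equi is None:
        F_equi = equilibrium_force(p, m)
    return EnergeticsResult(
        dG_bp_per_bp=float(basepair_energy_from_unzipping(p.F_unz, m)),
        dG_bind=binding_free_energy(p.F_unz, F_equi, p.footprint, m),
        F_equi=float(F_equi),
    )
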