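"""Rate extraction from traces and nonlinear fitting of the Arrhenius model.

Rates are slopes of opened-bp vs time over constant-force windows.  The
fit inverts the signed net-rate model over (k_on_per_nM, k_off, dz_on,
dz_off) with the unzipping force held fixed at its independently measured
value; uncertainties come from a seeded bootstrap over measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .elasticity import ElasticityModel, extension_to_bp
from .kinetics import KineticParameters, NoEquilibriumError, equilibrium_force, net_rate

__all__ = [
    "RateMeasurement",
    "FitResult",
    "FitConvergenceError",
    "estimate_trace_rate",
    "fit_eq1",
    "standardize_kon",
    "unstandardize_kon",
]


class FitConvergenceError(RuntimeError):
    """All optimizer starts failed to converge."""


@dataclass
class RateMeasurement:
    """One (force, signed net rate) observation.

    Sign convention: positive = fork opening (association-dominated),
    negative = fork closing (dissociation-dominated).
    """

    F: float  # pN
    v: float  # bp/s, signed
    v_err: float = 0.0  # bp/s, standard error (0 = unknown)
    branch: str = ""  # "association" | "dissociation" (advisory)
    condition: str = ""  # free-form label (protein, nM, Mg2+)

    def __post_init__(self) -> None:
        if self.v_err < 0:
            raise ValueError("v_err must be non-negative")


@dataclass
class FitResult:
    """Fitted model parameters with bootstrap uncertainties."""

    params: KineticParameters
    errors: dict = field(default_factory=dict)  # bootstrap standard errors
    ci: dict = field(default_factory=dict)  # 95% percentile intervals
    F_equi_derived: float | None = None
    residual_rms: float = float("nan")
    n_points: int = 0
    n_bootstrap: int = 0
    seed: int | None = None
    at_bounds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "k_on_per_nM": self.params.k_on_per_nM,
            "k_off": self.params.k_off,
            "dz_on": self.params.dz_on,
            "dz_off": self.params.dz_off,
            "F_unz": self.params.F_unz,
            "concentration": self.params.concentration,
            "F_equi": self.F_equi_derived,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "n_bootstrap": self.n_bootstrap,
            "bootstrap_seed": self.seed,
        }
        for k, v in self.errors.items():
            d[f"{k}_err"] = v
        return d


def estimate_trace_rate(
    trace,
    window: tuple[float, float] | None = None,
    m: ElasticityModel | None = None,
    geometry: str = "hairpin",
    condition: str = "",
) -> RateMeasurement:
    """OLS slope of opened-bp vs time over a constant-force window.

    The window is given in seconds; the force must be constant over it.
    Standard error comes from the fit residuals.
    """
    m = m or ElasticityModel()
    t0, t1 = window if window is not None else (trace.t[0], trace.t[-1])
    sel = (trace.t >= t0) & (trace.t <= t1)
    if sel.sum() < 3:
        raise ValueError("window contains fewer than 3 samples")
    F = trace.F[sel]
    if np.ptp(F) > 1e-9:
        raise ValueError("force is not constant on the requested window")
    F0 = float(F[0])
    bp = extension_to_bp(trace.x[sel], F0, geometry, m)
    res = stats.linregress(trace.t[sel], bp)
    return RateMeasurement(
        F=F0, v=float(res.slope), v_err=float(res.stderr), condition=condition,
        branch="association" if res.slope >= 0 else "dissociation",
    )


def _model_rates(theta, F, F_unz, conc, geometry, m):
    kon, koff, dzon, dzoff = theta
    p = KineticParameters(
        k_on_per_nM=kon, k_off=koff, dz_on=dzon, dz_off=dzoff,
        F_unz=F_unz, concentration=conc, geometry=geometry,
    )
    return net_rate(F, p, m)


def _single_fit(F, v, sigma, F_unz, conc, geometry, m, x0):
    def resid(theta):
        return (_model_rates(theta, F, F_unz, conc, geometry, m) - v) / sigma

    return optimize.least_squares(
        resid, x0, bounds=([0.0, 0.0, 0.0, 0.0], [np.inf] * 4),
        x_scale=np.maximum(np.abs(x0), 1e-3), max_nfev=2000,
    )


def _starts(F, v, conc):
    """Heuristic multi-start grid for (kon, koff, dz_on, dz_off)."""
    vmax = max(float(np.max(v)), 1e-3)
    vmin = min(float(np.min(v)), -1e-3)
    kon0 = max(vmax / max(conc, 1e-9), 1e-4)
    koff0 = max(-vmin, 1e-3)
    starts = []
    for dzon in (1.0, 3.0, 6.0):
        for dzoff in (0.5, 1.5, 3.0):
            starts.append(np.array([kon0 * (1 + dzon), koff0 * (1 + dzoff), dzon, dzoff]))
    return starts


def fit_eq1(
    measurements,
    F_unz: float,
    conc: float,
    m: ElasticityModel | None = None,
    geometry: str = "hairpin",
    n_bootstrap: int = 200,
    seed: int = 0,
    footprint: float = 23.0,
) -> FitResult:
    """Weighted nonlinear least squares of the signed net-rate model.

    Fits (k_on_per_nM, k_off, dz_on, dz_off) with F_unz fixed.  Inverse
    -variance weights when every measurement carries an error, otherwise
    unweighted.  Bootstrap over measurements (seeded) provides standard
    errors and 95% percentile intervals.
    """
    m = m or ElasticityModel()
    meas = list(measurements)
    if len(meas) < 4:
        raise ValueError("need at least 4 measurements to fit 4 parameters")
    F = np.array([mm.F for mm in meas], dtype=float)
    v = np.array([mm.v for mm in meas], dtype=float)
    errs = np.array([mm.v_err for mm in meas], dtype=float)
    sigma = errs if np.all(errs > 0) else np.ones_like(v)

    best = None
    for x0 in _starts(F, v, conc):
        try:
            res = _single_fit(F, v, sigma, F_unz, conc, geometry, m, x0)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitConvergenceError("no optimizer start converged")

    theta = best.x
    resid = _model_rates(theta, F, F_unz, conc, geometry, m) - v

    rng = np.random.default_rng(seed)
    boot = []
    n = len(meas)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(F[idx])) < 4:
            continue
        try:
            r = _single_fit(F[idx], v[idx], sigma[idx], F_unz, conc, geometry, m, theta)
        except Exception:
            continue
        if r.success:
            boot.append(r.x)
    boot = np.array(boot) if boot else np.empty((0, 4))

    names = ["k_on_per_nM", "k_off", "dz_on", "dz_off"]
    errors, ci = {}, {}
    if len(boot) >= 10:
        for i, name in enumerate(names):
            errors[name] = float(np.std(boot[:, i], ddof=1))
            lo, hi = np.percentile(boot[:, i], [2.5, 97.5])
            ci[name] = (float(lo), float(hi))

    params = KineticParameters(
        k_on_per_nM=float(theta[0]), k_off=float(theta[1]),
        dz_on=float(theta[2]), dz_off=float(theta[3]),
        F_unz=F_unz, concentration=conc, geometry=geometry, footprint=footprint,
    )
    try:
        F_equi = equilibrium_force(params, m)
    except (NoEquilibriumError, Exception):
        F_equi = None
    at_bounds = [name for name, val in zip(names, theta) if val < 1e-8]
    return FitResult(
        params=params, errors=errors, ci=ci, F_equi_derived=F_equi,
        residual_rms=float(np.sqrt(np.mean(resid**2))), n_points=n,
        n_bootstrap=len(boot), seed=seed, at_bounds=at_bounds,
    )


def standardize_kon(k_on_at_Funz: float, conc: float) -> float:
    """Per-nM association pre-factor from the rate at one concentration."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    return k_on_at_Funz / conc


def unstandardize_kon(k_on_per_nM: float, conc: float) -> float:
    """Inverse of :func:`standardize_kon`."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    return k_on_per_nM * conc
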