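"""Stochastic simulation of bead-tracked fork traces.

The fork state is the number of opened base pairs ``n`` on a lattice
[0, hairpin_size].  Opening/closing events of one protein footprint occur
at per-event rates equal to the two Arrhenius branches of the net-rate
model divided by the footprint, so that the ensemble-mean velocity in
bp/s reproduces the continuous model exactly (Gillespie simulation).
Extension is rendered as ``c(F) * n`` plus i.i.d. Gaussian camera noise
per sample; sliding events render a drift-diffusion closure instead of an
abrupt one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elasticity import ElasticityModel, conversion_factor
from .kinetics import (
    KineticParameters,
    NoEquilibriumError,
    closing_rate,
    equilibrium_force,
    net_rate,
    opening_rate,
)
from .ratefit import RateMeasurement

__all__ = [
    "Trace",
    "SimulationConfig",
    "simulate_fork_trace",
    "simulate_rate_dataset",
    "simulate_sliding_trace",
]


@dataclass
class Trace:
    """Uniformly sampled time/extension/force series."""

    t: np.ndarray  # s
    x: np.ndarray  # nm
    F: np.ndarray  # pN, piecewise constant
    sample_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.F)):
            raise ValueError("t, x, F must have equal length")
        if np.any(self.F <= 0):
            raise ValueError("forces must be positive")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("extension contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SimulationConfig:
    """Configuration of one Gillespie fork-trace simulation."""

    kinetic: KineticParameters
    elasticity: ElasticityModel = field(default_factory=ElasticityModel)
    hairpin_size: int = 488  # bp
    noise_sd: float = 5.0  # nm per sample
    sample_rate: float = 300.0  # Hz
    seed: int = 0
    force_schedule: list = field(default_factory=lambda: [(60.0, 13.2)])
    initial_open_bp: float = 0.0
    drift_nm_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kinetic.footprint > self.hairpin_size:
            raise ValueError("footprint exceeds hairpin size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not self.force_schedule:
            raise ValueError("force schedule is empty")
        for dur, F in self.force_schedule:
            if dur <= 0 or F <= 0:
                raise ValueError("schedule entries must have positive duration and force")
        if not 0 <= self.initial_open_bp <= self.hairpin_size:
            raise ValueError("initial_open_bp outside [0, hairpin_size]")


def _gillespie_segment(rng, n, N, fp, r_open, r_close, t0, t1):
    """Jump events in (t0, t1] at constant per-event rates; returns events."""
    events = []
    t = t0
    while True:
        ro = r_open if n < N else 0.0
        rc = r_close if n > 0 else 0.0
        rtot = ro + rc
        if rtot <= 0:
            break
        t = t + rng.exponential(1.0 / rtot)
        if t >= t1:
            break
        if rng.random() < ro / rtot:
            n = min(n + fp, N)
        else:
            n = max(n - fp, 0.0)
        events.append((t, n))
    return events, n


def simulate_fork_trace(cfg: SimulationConfig) -> Trace:
    """Gillespie simulation of footprint-sized fork opening/closing events.

    Per-event rates are the model's bp/s branches divided by the
    footprint; steps are clamped (reflecting) at the closed and fully
    open boundaries.  Ground-truth events are stored in
    ``trace.meta["events"]`` as (time, opened_bp_after) pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    p, m = cfg.kinetic, cfg.elasticity
    fp = float(p.footprint)
    N = float(cfg.hairpin_size)

    n = float(cfg.initial_open_bp)
    events = []
    t_cursor = 0.0
    seg_bounds = []
    for dur, F in cfg.force_schedule:
        r_open = float(opening_rate(F, p, m)) / fp
        r_close = float(closing_rate(F, p, m)) / fp
        segment_events, n = _gillespie_segment(
            rng, n, N, fp, r_open, r_close, t_cursor, t_cursor + dur
        )
        events.extend(segment_events)
        seg_bounds.append((t_cursor, t_cursor + dur, F))
        t_cursor += dur

    total = t_cursor
    n_samples = int(np.floor(total * cfg.sample_rate))
    t = np.arange(n_samples) / cfg.sample_rate

    # piecewise-constant opened-bp trajectory on the sample grid
    if events:
        ev_t = np.array([e[0] for e in events])
        ev_n = np.array([e[1] for e in events])
        idx = np.searchsorted(ev_t, t, side="right")
        n_grid = np.where(idx == 0, cfg.initial_open_bp, ev_n[np.maximum(idx - 1, 0)])
    else:
        n_grid = np.full_like(t, cfg.initial_open_bp)

    F_grid = np.empty_like(t)
    for lo, hi, F in seg_bounds:
        F_grid[(t >= lo) & (t < hi)] = F
    F_grid[t >= seg_bounds[-1][1]] = seg_bounds[-1][2]

    c = conversion_factor(F_grid, p.geometry, m)
    x = c * n_grid + cfg.drift_nm_per_s * t
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=len(t))

    meta = {
        "seed": cfg.seed,
        "sample_rate": cfg.sample_rate,
        "hairpin_size": cfg.hairpin_size,
        "noise_sd": cfg.noise_sd,
        "footprint": p.footprint,
        "geometry": p.geometry,
        "events": [(float(tt), float(nn)) for tt, nn in events],
    }
    return Trace(t=t, x=x, F=F_grid, sample_rate=cfg.sample_rate, meta=meta)


def simulate_rate_dataset(
    forces,
    p: KineticParameters,
    noise_cv: float = 0.0,
    seed: int = 0,
    m: ElasticityModel | None = None,
    condition: str = "",
):
    """Noisy net-rate observations on a force grid (fitting fixture).

    ``v = v_net(F) * (1 + eps)`` with ``eps ~ N(0, noise_cv^2)``; the
    reported error is ``|v_net| * noise_cv``.  Branch labels follow the
    equilibrium force when one exists, else the sign of the rate.
    """
    m = m or ElasticityModel()
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("empty force grid")
    rng = np.random.default_rng(seed)
    try:
        F_equi = equilibrium_force(p, m)
    except (NoEquilibriumError, Exception):
        F_equi = None
    out = []
    for F in forces:
        v_true = float(net_rate(F, p, m))
        v = v_true * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else v_true
        if F_equi is not None:
            branch = "association" if F > F_equi else "dissociation"
        else:
            branch = "association" if v >= 0 else "dissociation"
        out.append(
            RateMeasurement(
                F=float(F), v=v, v_err=abs(v_true) * noise_cv,
                branch=branch, condition=condition,
            )
        )
    return out


def simulate_sliding_trace(
    zeta: float,
    F_low: float,
    F_unz: float,
    hairpin_size: int = 488,
    n_cycles: int = 10,
    sliding_probability: float = 0.1,
    noise_sd: float = 5.0,
    sample_rate: float = 300.0,
    seed: int = 0,
    m: ElasticityModel | None = None,
    F_high: float = 22.5,
    t_high: float = 1.0,
    t_low: float = 3.0,
    nt_per_unit: float = 0.56,
):
    """Force-cycling trace with occasional friction-limited closures.

    Each cycle opens the hairpin abruptly at ``F_high`` and then drops to
    ``F_low``.  With probability ``sliding_probability`` the closure is a
    drift-diffusion of the fork position (a protein pushed ahead of the
    rezipping fork): drift ``(F_unz - F_low)/zeta`` nt/s toward closed,
    diffusion ``D = (kBT/nt_per_unit)/zeta`` nt^2/s, absorbing at fully
    closed.  Otherwise closure is a single abrupt transition.

    Returns ``(trace, labels)`` where labels is a list of dicts with the
    ground-truth classification and drift velocity per cycle.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if not F_low < F_unz:
        raise ValueError("F_low must be below F_unz")
    m = m or ElasticityModel()
    rng = np.random.default_rng(seed)
    N = float(hairpin_size)
    v_drift = (F_unz - F_low) / zeta  # nt/s
    D = (m.kBT / nt_per_unit) / zeta  # nt^2/s
    dt = 1.0 / sample_rate
    n_hi = int(round(t_high * sample_rate))
    n_lo = int(round(t_low * sample_rate))

    c_hi = float(conversion_factor(F_high, "hairpin", m, warn_nonpositive=False))
    c_lo = float(conversion_factor(F_low, "hairpin", m))

    xs, Fs, labels = [], [], []
    for cyc in range(n_cycles):
        # open phase: hairpin unzips mechanically, essentially instantly
        xs.append(np.full(n_hi, c_hi * N))
        Fs.append(np.full(n_hi, F_high))
        gradual = bool(rng.random() < sliding_probability)
        n_traj = np.zeros(n_lo)
        n_traj[0] = N  # closure starts after the force drop is rendered
        if gradual:
            pos = N
            sd_step = np.sqrt(2.0 * D * dt)
            steps = rng.normal(0.0, sd_step, size=n_lo)
            for i in range(1, n_lo):
                if pos <= 0:
                    n_traj[i:] = 0.0
                    break
                pos = min(pos - v_drift * dt + steps[i], N)
                n_traj[i] = max(pos, 0.0)
        # abrupt: a single sharp transition right after the force drop
        xs.append(c_lo * n_traj)
        Fs.append(np.full(n_lo, F_low))
        labels.append(
            {
                "cycle_index": cyc,
                "gradual": gradual,
                "v_drift": v_drift if gradual else None,
                "F_low": F_low,
                "F_push": F_unz - F_low,
            }
        )

    x = np.concatenate(xs)
    F = np.concatenate(Fs)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    t = np.arange(len(x)) / sample_rate
    meta = {
        "seed": seed,
        "sample_rate": sample_rate,
        "hairpin_size": hairpin_size,
        "zeta": zeta,
        "F_low": F_low,
        "F_high": F_high,
        "F_unz": F_unz,
        "sliding_probability": sliding_probability,
        "labels": labels,
    }
    return Trace(t=t, x=x, F=F, sample_rate=sample_rate, meta=meta), labels
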