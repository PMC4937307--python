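"""Classification of closing cycles and the friction (pushing) analysis.

A rezipping fork can push a bound protein ahead of itself; friction then
limits the closure to a roughly constant velocity instead of the usual
abrupt transition.  Gradual closures are detected by their duration, the
force-velocity law F_push = zeta * v is fit through per-force mean
velocities, and the Einstein relation converts zeta to a diffusion
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .elasticity import ElasticityModel, conversion_factor

__all__ = [
    "SlidingEvent",
    "FrictionFit",
    "classify_closing_cycles",
    "fit_friction",
]


@dataclass
class SlidingEvent:
    """One closing cycle: abrupt, or gradual (friction-limited)."""

    cycle_index: int
    gradual: bool
    velocity: float | None  # nt/s, None for abrupt closures
    F_low: float  # pN
    duration: float  # s, closure duration estimate
    amplitude_nt: float  # nt closed


@dataclass
class FrictionFit:
    """Linear force-velocity fit and derived friction/diffusion."""

    zeta: float  # pN nt^-1 s
    zeta_err: float
    intercept: float  # nt/s at zero pushing force
    r_squared: float
    D: float  # nt^2/s via Einstein relation
    n_events: int


def _segments(F):
    """(start, stop, force) runs of the piecewise-constant force series."""
    F = np.asarray(F)
    edges = np.flatnonzero(np.diff(F) != 0) + 1
    bounds = np.concatenate([[0], edges, [len(F)]])
    return [(int(bounds[i]), int(bounds[i + 1]), float(F[bounds[i]])) for i in range(len(bounds) - 1)]


def _smooth(y, w):
    if w <= 1:
        return y
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(np.asarray(y, dtype=float), w, mode="nearest")


def classify_closing_cycles(
    trace,
    threshold_multiple: float = 10.0,
    abrupt_ref: float | None = None,
    m: ElasticityModel | None = None,
    smooth_window: int = 5,
    min_amplitude_nm: float = 50.0,
):
    """Find high->low force transitions and classify each closure.

    The closure duration is measured between the 90% and 10% crossings of
    the (smoothed) extension amplitude within the low-force segment and
    rescaled to the full amplitude.  A cycle is gradual when its duration
    exceeds ``threshold_multiple`` times the abrupt-closure reference
    time (default: 10 samples, the instrument-limited transition time).
    Velocity = nt closed / closure duration.
    """
    m = m or ElasticityModel()
    if abrupt_ref is None:
        abrupt_ref = 10.0 / trace.sample_rate
    segs = _segments(trace.F)
    events: list[SlidingEvent] = []
    cycle = 0
    for k in range(1, len(segs)):
        i, j, F_low = segs[k]
        F_prev = segs[k - 1][2]
        if F_low >= F_prev:  # not a force drop
            continue
        y = _smooth(trace.x[i:j], smooth_window)
        if len(y) < 2 * smooth_window:
            continue
        top, bot = float(np.max(y)), float(np.min(y))
        amp = top - bot
        if amp < min_amplitude_nm:
            continue  # no closure in this segment
        hi_level = bot + 0.9 * amp
        lo_level = bot + 0.1 * amp
        below_hi = np.flatnonzero(y < hi_level)
        below_lo = np.flatnonzero(y < lo_level)
        if below_hi.size == 0 or below_lo.size == 0:
            continue
        t_hi = below_hi[0]
        t_lo = below_lo[below_lo >= t_hi][0] if np.any(below_lo >= t_hi) else below_lo[-1]
        dur_80 = max(t_lo - t_hi, 1) / trace.sample_rate
        duration = dur_80 / 0.8  # rescale 90->10% crossing to full amplitude
        c = float(conversion_factor(F_low, "hairpin", m))
        amp_nt = amp / c
        gradual = duration > threshold_multiple * abrupt_ref
        velocity = amp_nt / duration if gradual else None
        events.append(
            SlidingEvent(
                cycle_index=cycle, gradual=gradual, velocity=velocity,
                F_low=F_low, duration=duration, amplitude_nt=amp_nt,
            )
        )
        cycle += 1
    return events


def fit_friction(
    events,
    F_unz: float,
    m: ElasticityModel | None = None,
    nt_per_unit: float = 0.56,
) -> FrictionFit:
    """Fit v vs F_push through per-force mean velocities; zeta = 1/slope.

    ``F_push = F_unz - F_low``.  Requires >= 3 gradual events spanning at
    least two distinct pushing forces.  ``D = (kBT/nt_per_unit)/zeta``
    converts to a diffusion coefficient in nt^2/s; the nt length scale of
    that conversion is configurable (default ssDNA contour per nt).
    """
    m = m or ElasticityModel()
    grad = [e for e in events if e.gradual and e.velocity is not None]
    if len(grad) < 3:
        raise ValueError(f"need at least 3 gradual events, got {len(grad)}")
    F_push = np.array([F_unz - e.F_low for e in grad])
    v = np.array([e.velocity for e in grad])
    uniq = np.unique(np.round(F_push, 6))
    if len(uniq) < 2:
        raise ValueError("gradual events span fewer than 2 distinct forces")
    mean_v = np.array([np.mean(v[np.isclose(F_push, u)]) for u in uniq])
    res = stats.linregress(uniq, mean_v)
    if res.slope <= 0:
        raise ValueError("non-positive force-velocity slope: invalid friction fit")
    zeta = 1.0 / res.slope
    zeta_err = res.stderr / res.slope**2 if res.stderr is not None else float("nan")
    D = (m.kBT / nt_per_unit) / zeta
    return FrictionFit(
        zeta=float(zeta), zeta_err=float(zeta_err), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), D=float(D), n_events=len(grad),
    )
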