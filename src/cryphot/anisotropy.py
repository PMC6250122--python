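"""Polarization anisotropy of pump-probe signals.

With linearly polarized pump and probe, photoselection makes the parallel
and perpendicular difference signals unequal; their combination

    r = (dA_par - dA_perp) / (dA_par + 2 dA_perp)

is the anisotropy, which for a fixed pair of pump/probe transition dipoles
at angle theta takes the value r = 0.4 P2(cos theta) = 0.2 (3 cos^2
theta - 1), bounded in [-0.2, 0.4].  The magic-angle combination (dA_par +
2 dA_perp)/3 cancels photoselection and returns pure population kinetics.
Population-weighted averages of theoretical anisotropies are what
identifies which radical-pair state carries the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataio import TAMatrix
from .globalfit import IRF, KineticBasis, design_matrix

__all__ = [
    "PolarizedPair",
    "anisotropy_surface",
    "magic_angle",
    "theoretical_r",
    "averaged_r",
    "fit_r_decay",
]


@dataclass
class PolarizedPair:
    """Parallel and perpendicular TA matrices on identical grids."""

    parallel: TAMatrix
    perpendicular: TAMatrix

    def __post_init__(self) -> None:
        a, b = self.parallel, self.perpendicular
        if not (
            np.array_equal(a.wavelengths, b.wavelengths)
            and np.array_equal(a.times, b.times)
            and a.time_unit == b.time_unit
        ):
            raise ValueError("parallel and perpendicular grids differ")
        if a.polarization != "parallel" or b.polarization != "perpendicular":
            raise ValueError("polarization tags must be parallel/perpendicular")


def anisotropy_surface(
    p: PolarizedPair, denominator_threshold_od: float = 1e-3
) -> TAMatrix:
    """r(lambda, t) with cells masked where the isotropic signal is too
    small to divide by (default 1 mOD: anisotropy diverges at isosbestic
    and bleach-cancellation points)."""
    par = p.parallel.values
    perp = p.perpendicular.values
    denom = par + 2.0 * perp
    bad = np.abs(denom) < denominator_threshold_od
    bad |= p.parallel.effective_mask() | p.perpendicular.effective_mask()
    r = np.zeros_like(denom)
    r[~bad] = (par[~bad] - perp[~bad]) / denom[~bad]
    return TAMatrix(
        wavelengths=p.parallel.wavelengths,
        times=p.parallel.times,
        values=r,
        polarization="unpolarized",
        mask=bad if bad.any() else None,
        time_unit=p.parallel.time_unit,
        meta={"quantity": "anisotropy"},
    )


def magic_angle(p: PolarizedPair) -> TAMatrix:
    """(dA_par + 2 dA_perp) / 3: the pure population signal."""
    values = (p.parallel.values + 2.0 * p.perpendicular.values) / 3.0
    mask = p.parallel.effective_mask() | p.perpendicular.effective_mask()
    return TAMatrix(
        wavelengths=p.parallel.wavelengths,
        times=p.parallel.times,
        values=values,
        polarization="magic",
        mask=mask if mask.any() else None,
        time_unit=p.parallel.time_unit,
        meta={"constructed": "from polarized pair"},
    )


def theoretical_r(theta_deg: float) -> float:
    """Photoselection anisotropy for a dipole pair at angle theta:
    r = 0.2 (3 cos^2 theta - 1); 0.4 at 0 deg, -0.2 at 90 deg, 0 at the
    magic angle 54.71 deg."""
    if not np.all(np.isfinite(theta_deg)):
        raise ValueError("theta must be finite")
    c = np.cos(np.deg2rad(theta_deg))
    return 0.2 * (3.0 * c * c - 1.0)


def averaged_r(components: Sequence[tuple[float, float]]) -> float:
    """Population/extinction-weighted mean anisotropy.

    ``components`` is a list of ``(r_i, weight_i)``; equal band shapes are
    assumed so the weights multiply directly.  Used e.g. to predict the
    anisotropy of an equilibrated pair of radicals.
    """
    r = np.array([c[0] for c in components], dtype=float)
    w = np.array([c[1] for c in components], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("all-zero weights")
    return float((r * w).sum() / w.sum())


def fit_r_decay(
    r_trace: np.ndarray,
    t: np.ndarray,
    rates: KineticBasis,
    irf: Optional[IRF] = None,
) -> dict:
    """Fit an r(t) trace with amplitudes on a *fixed* exponential basis.

    The rate constants come from the magic-angle global fit; only the
    linear amplitudes are solved (ordinary least squares).  Returns a dict
    with ``amplitudes``, ``fit``, ``residuals`` and ``rss``.
    """
    r_trace = np.asarray(r_trace, dtype=float)
    t = np.asarray(t, dtype=float)
    F = design_matrix(t, rates, irf)
    amps, *_ = np.linalg.lstsq(F, r_trace, rcond=None)
    fit = F @ amps
    resid = r_trace - fit
    return {
        "amplitudes": amps,
        "fit": fit,
        "residuals": resid,
        "rss": float(resid @ resid),
    }
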