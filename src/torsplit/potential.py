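"""Periodic torsional potentials and their surgical modifications.

A torsional potential ``V(tau)`` is a 360-degree-periodic one-dimensional
energy function of the internal-rotation dihedral, expressed in cm^-1
(energy via ``E = h c nu``).  The smooth part is a truncated real Fourier
series; on top of it two kinds of additive overlays may sit:

* rectangular barriers -- narrow, towering walls used to suppress tunneling
  through a chosen transition state ("artificial localization"),
* a piecewise-linear periodic correction -- produced when the energies of
  the stationary points are replaced by refined values and the connecting
  potential segments are shifted linearly in the dihedral to match
  ("anchor rescaling").

Angles are degrees on input and output throughout; trigonometry happens in
radians internally.  The energy zero of the smooth part is its minimum on a
0.1-degree evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PeriodicPotential",
    "StationaryPoint",
    "RectangularBarrier",
    "fit_fourier",
    "find_stationary_points",
    "symmetrize",
    "rescale_to_anchors",
    "insert_rectangular_barrier",
    "excited_state_potential",
    "synth_double_well",
]

DEG = np.pi / 180.0
#: fine grid step (degrees) used for the energy-zero convention
_ZERO_GRID_STEP = 0.1


def _wrap(angle_deg):
    """Map angles onto [0, 360)."""
    return np.mod(angle_deg, 360.0)


@dataclass(frozen=True)
class RectangularBarrier:
    """Additive top-hat overlay: +height for |tau - center| <= width/2 (mod 360)."""

    center: float
    width: float = 1.0
    height: float = 1.0e6

    def __call__(self, tau_deg):
        d = np.abs((np.asarray(tau_deg, dtype=float) - self.center + 180.0) % 360.0 - 180.0)
        return np.where(d <= self.width / 2.0 + 1e-12, self.height, 0.0)


@dataclass(frozen=True)
class PiecewiseLinearCorrection:
    """Periodic additive correction, linear in tau between anchor angles.

    ``angles`` are strictly increasing in [0, 360); the segment from the last
    anchor wraps around to the first.
    """

    angles: tuple
    values: tuple

    def __call__(self, tau_deg):
        tau = _wrap(np.asarray(tau_deg, dtype=float))
        ang = np.asarray(self.angles, dtype=float)
        val = np.asarray(self.values, dtype=float)
        # close the circle: append first anchor at +360
        ang_ext = np.concatenate([ang, [ang[0] + 360.0]])
        val_ext = np.concatenate([val, [val[0]]])
        # shift tau below the first anchor into the wrap-around segment
        tau_shift = np.where(tau < ang[0], tau + 360.0, tau)
        return np.interp(tau_shift, ang_ext, val_ext)


@dataclass(frozen=True)
class StationaryPoint:
    """A located extremum of the smooth potential."""

    angle: float  # degrees in [0, 360)
    energy: float  # cm^-1, relative to the potential zero
    kind: str  # "minimum" | "maximum"
    label: str = ""


@dataclass(frozen=True, eq=False)
class PeriodicPotential:
    """Truncated real Fourier series V(tau) with optional additive overlays.

    ``a0 + sum_k a[k-1] cos(k tau) + b[k-1] sin(k tau)`` with tau in radians
    internally.  ``overlays`` compose additively at evaluation time and never
    alter the Fourier coefficients.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    overlays: tuple = ()
    grid_resolution: float = _ZERO_GRID_STEP
    known_stationary_points: tuple = field(default=(), compare=False)

    @property
    def order(self) -> int:
        return len(self.a)

    # -- evaluation ---------------------------------------------------------

    def fourier_part(self, tau_deg):
        tau = np.asarray(tau_deg, dtype=float) * DEG
        k = np.arange(1, self.order + 1)
        # broadcasting: (..., 1) * (K,)
        arg = tau[..., None] * k
        out = self.a0 + np.cos(arg) @ np.asarray(self.a) + np.sin(arg) @ np.asarray(self.b)
        return out

    def smooth_part(self, tau_deg):
        """Fourier series plus any piecewise-linear correction (no barriers)."""
        out = self.fourier_part(tau_deg)
        for ov in self.overlays:
            if isinstance(ov, PiecewiseLinearCorrection):
                out = out + ov(tau_deg)
        return out

    def __call__(self, tau_deg):
        out = self.fourier_part(tau_deg)
        for ov in self.overlays:
            out = out + ov(tau_deg)
        return out

    # -- derivatives of the Fourier part ------------------------------------

    def fourier_derivative(self, tau_deg, n: int = 1):
        """n-th derivative of the Fourier part w.r.t. tau in *degrees*."""
        tau = np.asarray(tau_deg, dtype=float) * DEG
        k = np.arange(1, self.order + 1)
        arg = tau[..., None] * k
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        if n == 1:
            out = -np.sin(arg) @ (k * a) + np.cos(arg) @ (k * b)
        elif n == 2:
            out = -np.cos(arg) @ (k**2 * a) - np.sin(arg) @ (k**2 * b)
        else:
            raise ValueError("only first and second derivatives supported")
        return out * DEG**n

    # -- helpers -------------------------------------------------------------

    def rezeroed(self) -> "PeriodicPotential":
        """Shift a0 so the minimum of the smooth part on the fine grid is 0."""
        grid = np.arange(0.0, 360.0, self.grid_resolution)
        vmin = float(np.min(self.smooth_part(grid)))
        return replace(self, a0=self.a0 - vmin)

    def with_overlay(self, overlay) -> "PeriodicPotential":
        return replace(self, overlays=self.overlays + (overlay,))

    def has_barriers(self) -> bool:
        return any(isinstance(ov, RectangularBarrier) for ov in self.overlays)

    def is_pure_fourier(self) -> bool:
        return not self.overlays

    def to_fourier(self, order: int) -> "PeriodicPotential":
        """Refit the *full* potential (overlays folded in) to a pure series.

        Discontinuous overlays (rectangular barriers) cannot be represented
        exactly; the refit is least squares on a 0.05-degree grid.
        """
        grid = np.arange(0.0, 360.0, 0.05)
        return fit_fourier(list(zip(grid, self(grid))), order=order)


# ---------------------------------------------------------------------------
# construction / fitting
# ---------------------------------------------------------------------------


def _design_matrix(angles_deg: np.ndarray, order: int) -> np.ndarray:
    tau = angles_deg * DEG
    k = np.arange(1, order + 1)
    arg = tau[:, None] * k
    return np.hstack([np.ones((len(tau), 1)), np.cos(arg), np.sin(arg)])


def fit_fourier(samples: Sequence[tuple], order: int) -> PeriodicPotential:
    """Least-squares Fourier fit of (angle deg, energy cm^-1) samples.

    Requires at least ``2*order + 1`` samples with distinct angles mod 360.
    The result is re-zeroed to its minimum; the RMS residual of the fit is
    stored on the returned object as ``fit_rms``.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be (angle, energy) pairs")
    angles, energies = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(energies)) or not np.all(np.isfinite(angles)):
        raise ValueError("non-finite values in samples")
    wrapped = _wrap(angles)
    if len(np.unique(np.round(wrapped, 9))) < len(wrapped):
        raise ValueError("duplicate angles modulo 360 degrees")
    if len(arr) < 2 * order + 1:
        raise ValueError(
            f"underdetermined fit: {len(arr)} samples for Fourier order {order} "
            f"(need >= {2 * order + 1})"
        )
    X = _design_matrix(wrapped, order)
    coef, *_ = np.linalg.lstsq(X, energies, rcond=None)
    resid = energies - X @ coef
    pot = PeriodicPotential(
        a0=float(coef[0]),
        a=np.array(coef[1 : order + 1]),
        b=np.array(coef[order + 1 :]),
    ).rezeroed()
    object.__setattr__(pot, "fit_rms", float(np.sqrt(np.mean(resid**2))))
    return pot


# ---------------------------------------------------------------------------
# stationary points
# ---------------------------------------------------------------------------

#: roots with |dV/dtau| above this (cm^-1 per degree) are rejected
_STAT_DERIV_TOL = 1e-8
#: stationary points closer than this (degrees) are merged (flat-top guard)
_STAT_MERGE_DEG = 0.5


def find_stationary_points(pot: PeriodicPotential) -> list:
    """Locate all extrema of the smooth Fourier part on [0, 360).

    Sign changes of dV/dtau are bracketed on a 0.05-degree grid and refined
    by bisection to <= 1e-4 degrees; classification is by the sign of the
    second derivative.  Overlays are ignored (barriers are discontinuous,
    anchor corrections have kinks at the anchors by construction).
    """
    grid = np.arange(0.0, 360.0, 0.05)
    d1 = pot.fourier_derivative(grid, 1)
    if np.max(np.abs(d1)) < _STAT_DERIV_TOL:
        raise ValueError("no isolated stationary points: potential is flat")

    f = lambda x: float(pot.fourier_derivative(np.array([x]), 1)[0])
    roots = []
    for i in range(len(grid)):
        x0, x1 = grid[i], grid[i] + 0.05
        y0, y1 = d1[i], d1[(i + 1) % len(grid)]
        if y0 == 0.0:
            roots.append(x0)
        elif y0 * y1 < 0:
            roots.append(brentq(f, x0, x1, xtol=1e-6))
    roots = sorted(_wrap(np.asarray(roots)))

    # merge near-coincident roots (flat tops)
    merged = []
    for r in roots:
        if merged and min(abs(r - merged[-1]), 360.0 - abs(r - merged[-1])) < _STAT_MERGE_DEG:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    if len(merged) > 1:
        gap = min(abs(merged[0] - merged[-1]), 360.0 - abs(merged[0] - merged[-1]))
        if gap < _STAT_MERGE_DEG:
            merged[0] = _wrap(0.5 * (merged[0] + merged[-1] - 360.0))
            merged.pop()

    pts = []
    for r in sorted(merged):
        curv = float(pot.fourier_derivative(np.array([r]), 2)[0])
        kind = "minimum" if curv > 0 else "maximum"
        pts.append(StationaryPoint(angle=float(r), energy=float(pot.fourier_part(np.array([r]))[0]), kind=kind))
    return pts


# ---------------------------------------------------------------------------
# surgical modifications
# ---------------------------------------------------------------------------


def symmetrize(pot: PeriodicPotential, ts_angle: float) -> PeriodicPotential:
    """Mirror-average the two half-potentials about a transition state.

    ``V_sym(ts + x) = [V(ts + x) + V(ts - x)] / 2`` -- exact in coefficient
    space: writing the series in the shifted coordinate ``phi = tau - ts``,
    the sin(k phi) components cancel and the cos(k phi) ones survive.
    The result is exactly mirror-symmetric about ``ts_angle`` and re-zeroed.
    """
    if not pot.is_pure_fourier():
        raise ValueError("symmetrize requires a pure Fourier potential; refit with to_fourier() first")
    _require_maximum(pot, ts_angle)
    k = np.arange(1, pot.order + 1)
    phase = k * ts_angle * DEG
    # cos(k phi) amplitude in the shifted frame
    A = np.asarray(pot.a) * np.cos(phase) + np.asarray(pot.b) * np.sin(phase)
    return PeriodicPotential(a0=pot.a0, a=A * np.cos(phase), b=A * np.sin(phase)).rezeroed()


def _require_maximum(pot: PeriodicPotential, angle: float, tol_deg: float = 0.5):
    pts = find_stationary_points(pot)
    for p in pts:
        if p.kind == "maximum":
            gap = abs(_wrap(angle) - p.angle)
            if min(gap, 360.0 - gap) <= tol_deg:
                return p
    raise ValueError(f"{angle} deg is not a stationary maximum of the potential")


def _anchor_angles_energies(pot, anchors):
    """Validate anchors against the potential's stationary set, sorted by angle."""
    stat = find_stationary_points(pot)
    stat_angles = np.array([p.angle for p in stat])
    items = []
    for sp, e_corr in anchors:
        gap = np.abs(stat_angles - _wrap(sp.angle))
        gap = np.minimum(gap, 360.0 - gap)
        if gap.min() > 0.5:
            raise ValueError(f"anchor at {sp.angle} deg is not a stationary point of the potential")
        items.append((_wrap(sp.angle), float(e_corr)))
    if len(items) != len(stat):
        raise ValueError(
            f"anchors must cover the full stationary set ({len(stat)} points, got {len(items)})"
        )
    items.sort()
    return items


def rescale_to_anchors(pot: PeriodicPotential, anchors: Sequence[tuple]) -> PeriodicPotential:
    """Shift the potential to pass exactly through corrected anchor energies.

    ``anchors`` is the complete alternating minimum/maximum set of the
    potential paired with refined energies (e.g. higher-level single points).
    Between consecutive anchors the additive correction is interpolated
    linearly in the dihedral, so every anchor lands exactly on its corrected
    energy while the connecting segments keep their shape.
    """
    items = _anchor_angles_energies(pot, anchors)
    angles = np.array([ang for ang, _ in items])
    corr = np.array([e - float(pot.smooth_part(np.array([ang]))[0]) for ang, e in items])
    correction = PiecewiseLinearCorrection(tuple(angles), tuple(corr))
    return pot.with_overlay(correction).rezeroed()


def insert_rectangular_barrier(
    pot: PeriodicPotential, center: float, width: float = 1.0, height: float = 1.0e6
) -> PeriodicPotential:
    """Add a narrow, towering top-hat wall (tunneling suppression).

    The overlay composes additively at evaluation time; the Fourier part is
    untouched and energies change only inside the barrier's support.
    """
    if width <= 0 or height <= 0:
        raise ValueError("barrier width and height must be positive")
    return pot.with_overlay(RectangularBarrier(center=_wrap(center), width=width, height=height))


def excited_state_potential(pot: PeriodicPotential, stretch_offsets: Sequence[tuple]) -> PeriodicPotential:
    """Adiabatic stretch-excited potential from per-stationary-point offsets.

    Each stationary point's energy is raised by its harmonic stretch
    wavenumber (the vibrational quantum being carried adiabatically along the
    torsion), then the connecting segments are shifted linearly to match --
    i.e. this delegates to :func:`rescale_to_anchors` with
    ``corrected = current + offset`` and re-zeroes.
    """
    anchors = []
    for sp, offset in stretch_offsets:
        current = float(pot.smooth_part(np.array([sp.angle]))[0])
        anchors.append((sp, current + float(offset)))
    return rescale_to_anchors(pot, anchors)


# ---------------------------------------------------------------------------
# synthetic fixture generator
# ---------------------------------------------------------------------------


def synth_double_well(
    barrier: float,
    asymmetry: float,
    well_separation: float,
    n_background: int = 4,
) -> PeriodicPotential:
    """Smooth two-well potential with a controlled low barrier and asymmetry.

    Emulates the hydroxy-rotor landscape of a chiral secondary alcohol: two
    near-degenerate gauche wells separated by ``well_separation`` degrees
    across a low transition state near 0 deg, with a much higher trans-region
    background hump at 180 deg.  The construction is a finite Fourier series:

        V = barrier * u(tau)^2 + 2*barrier * ((1 - cos tau)/2)^n + lam*sin(tau)

    with ``u = (cos tau - cos(s/2)) / (1 - cos(s/2))`` so that the two wells
    sit near +-s/2 with V ~ 0 and the top of the separating barrier near 0.
    ``lam`` is solved numerically so the two well minima differ by exactly
    ``asymmetry`` (signed: positive puts the well at +s/2 higher).

    The returned potential is re-zeroed and carries the exact stationary
    points found at solve time in ``known_stationary_points``.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if abs(asymmetry) >= barrier:
        raise ValueError("|asymmetry| must be smaller than the barrier")
    if not (0.0 < well_separation < 180.0):
        raise ValueError("well_separation must lie in (0, 180) degrees")
    if n_background < 1:
        raise ValueError("n_background must be >= 1")

    s2 = well_separation / 2.0
    c = np.cos(s2 * DEG)

    def build(lam: float) -> PeriodicPotential:
        # barrier * u^2 expanded: u^2 = (cos t - c)^2 / (1-c)^2
        #   = [c^2 + 1/2 - 2 c cos t + (1/2) cos 2t] / (1-c)^2
        K = max(2, n_background)
        a = np.zeros(K)
        b = np.zeros(K)
        denom = (1.0 - c) ** 2
        a0 = barrier * (c**2 + 0.5) / denom
        a[0] += barrier * (-2.0 * c) / denom
        a[1] += barrier * 0.5 / denom
        # background: 2*barrier * ((1 - cos t)/2)^n via binomial expansion,
        # then cos^m t expanded into cos(k t) harmonics
        bg = 2.0 * barrier
        for m in range(n_background + 1):
            coef = bg * _binom(n_background, m) * (-0.5) ** m * 0.5 ** (n_background - m)
            # cos^m t = sum_k w_k cos(k t)
            for k_idx, w in _cos_power_harmonics(m):
                if k_idx == 0:
                    a0 += coef * w
                else:
                    a[k_idx - 1] += coef * w
        b[0] += lam
        return PeriodicPotential(a0=a0, a=a, b=b)

    def well_energies(pot):
        pts = find_stationary_points(pot)
        mins = [p for p in pts if p.kind == "minimum"]
        # the two low wells are the two lowest minima
        mins = sorted(mins, key=lambda p: p.energy)[:2]
        if len(mins) < 2:
            raise ValueError("infeasible parameters: no two-well solution")
        left = min(mins, key=lambda p: np.sin(p.angle * DEG))  # near -s/2 (i.e. 360-s/2)
        right = max(mins, key=lambda p: np.sin(p.angle * DEG))  # near +s/2
        return left, right

    def gap(lam):
        left, right = well_energies(build(lam))
        return right.energy - left.energy - asymmetry

    if asymmetry == 0.0:
        lam = 0.0
    else:
        hi = 0.9 * barrier  # beyond this the shallow well can vanish
        lo = -hi
        try:
            lam = brentq(gap, lo, hi, xtol=1e-12)
        except ValueError as exc:
            raise ValueError("infeasible parameter combination for the requested asymmetry") from exc

    pot = build(lam).rezeroed()
    pts = find_stationary_points(pot)
    # sanity: exactly two low minima below the background hump
    mins = [p for p in pts if p.kind == "minimum"]
    if len(mins) < 2:
        raise ValueError("infeasible parameter combination: lost a well")
    pts = [StationaryPoint(p.angle, float(pot.fourier_part(np.array([p.angle]))[0]), p.kind) for p in pts]
    return replace(pot, known_stationary_points=tuple(pts))


def _binom(n, k):
    from math import comb

    return comb(n, k)


def _cos_power_harmonics(m):
    """cos^m(t) = sum_k w_k cos(k t); yields (k, w_k) pairs."""
    from math import comb

    if m == 0:
        yield 0, 1.0
        return
    scale = 0.5 ** (m - 1)
    for j in range(m // 2 + 1):
        k = m - 2 * j
        w = scale * comb(m, j)
        if k == 0:
            yield 0, w / 2.0
        else:
            yield k, w
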