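"""Isotope-shift models and four-band torsional level schemes.

Two simple spectroscopic models connect OH and OD stretching spectra:

* a Morse-oscillator "ratio rule" for the isotope shift of the stretching
  fundamental, needing only the harmonic wavenumber, the anharmonicity and
  the reduced-mass ratio;
* combination differences, turning a four-band pattern (two transitions out
  of each tunneling component of the torsional ground state) into ground-
  and excited-state torsional splittings plus a band center of gravity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MorseParams",
    "LevelScheme",
    "morse_isotope_ratio",
    "map_oh_to_od",
    "map_od_to_oh",
    "combination_differences",
    "direct_isotope_correlation",
    "OD_OH_AXIS_RATIO",
]

#: fixed OD/OH fundamental ratio used for aligning wavenumber axes
OD_OH_AXIS_RATIO = 0.73778


@dataclass(frozen=True)
class MorseParams:
    """Morse-oscillator inputs for the isotope ratio of stretch fundamentals.

    ``omega_e`` -- harmonic wavenumber of the unmodified oscillator (cm^-1);
    ``two_omega_e_x_e`` -- 2*omega_e*x_e diagonal anharmonicity (cm^-1);
    ``r`` -- reduced-mass ratio mu_0 / mu_i (light over heavy for O-H -> O-D).
    """

    omega_e: float
    two_omega_e_x_e: float
    r: float

    def __post_init__(self):
        if not (self.omega_e > self.two_omega_e_x_e > 0):
            raise ValueError("require omega_e > 2*omega_e*x_e > 0")
        if self.r <= 0:
            raise ValueError("reduced-mass ratio must be positive")


def morse_isotope_ratio(p: MorseParams) -> float:
    """Ratio of isotopically modified to unmodified stretch fundamentals.

    For a Morse oscillator the fundamental is omega_e - 2*omega_e*x_e; under
    isotopic substitution omega_e scales with sqrt(r) and omega_e*x_e with r
    (r = mu_0/mu_i), giving

        nu_i / nu_0 = (sqrt(r) * omega_e - r * 2*omega_e*x_e)
                      / (omega_e - 2*omega_e*x_e)

    which reduces to sqrt(r) in the harmonic limit.
    """
    denom = p.omega_e - p.two_omega_e_x_e
    if denom <= 0:
        raise ValueError("fundamental denominator must be positive")
    return (math.sqrt(p.r) * p.omega_e - p.r * p.two_omega_e_x_e) / denom


def map_oh_to_od(wavenumber_oh: float, ratio: float = OD_OH_AXIS_RATIO) -> float:
    """Project an OH-stretch wavenumber onto the OD axis (multiply by ratio)."""
    if wavenumber_oh <= 0:
        raise ValueError("wavenumber must be positive")
    return wavenumber_oh * ratio

def map_od_to_oh(wavenumber_od: float, ratio: float = OD_OH_AXIS_RATIO) -> float:
    """Inverse of :func:`map_oh_to_od`."""
    if wavenumber_od <= 0:
        raise ValueError("wavenumber must be positive")
    return wavenumber_od / ratio


@dataclass(frozen=True)
class LevelScheme:
    """Four-band torsional level scheme.

    ``bands`` are stored descending and assigned (u1<-l0, l1<-l0, u1<-u0,
    l1<-u0): the two transitions out of the lower tunneling component l0
    lie highest, and within each pair the one terminating on the upper
    excited component u1 lies higher (valid when the ground splitting
    exceeds the excited one; ``assignment="excited_larger"`` swaps the two
    middle bands).  The redundancy of the four differences is exposed as
    ``residual``; a nonzero residual within the calibration accuracy is
    expected for real band maxima.
    """

    bands: tuple
    ground_splitting: float
    excited_splitting: float
    center_of_gravity: float
    residual: float
    warning: bool = False
    assignment: str = "ground_larger"


def combination_differences(
    bands,
    residual_threshold: float = 2.0,
    assignment: str = "ground_larger",
) -> LevelScheme:
    """Translate four band positions into torsional splittings.

    Sorting the bands descending as b1 > b2 > b3 > b4, combination
    differences give the ground-state splitting as b1-b3 (= b2-b4) and the
    excited-state splitting as b1-b2 (= b3-b4); each is reported as the mean
    of its two redundant estimates and the defect |(b1-b3)-(b2-b4)| as the
    residual.  The center of gravity is the plain mean of the four bands
    (invariant, to first order, under the tunneling coupling).  ``warning``
    is set when the residual exceeds ``residual_threshold`` (default 2 cm^-1,
    about twice a typical +-1 cm^-1 calibration accuracy).
    """
    b = sorted(float(x) for x in bands)
    if len(b) != 4:
        raise ValueError("exactly four band positions required")
    if any(x <= 0 for x in b):
        raise ValueError("band positions must be positive wavenumbers")
    if len(set(b)) != 4:
        raise ValueError("band positions must be distinct")
    b1, b2, b3, b4 = sorted(b, reverse=True)
    if assignment == "excited_larger":
        b2, b3 = b3, b2
    elif assignment != "ground_larger":
        raise ValueError("assignment must be 'ground_larger' or 'excited_larger'")
    ground = 0.5 * ((b1 - b3) + (b2 - b4))
    excited = 0.5 * ((b1 - b2) + (b3 - b4))
    residual = abs((b1 - b3) - (b2 - b4))
    cog = (b1 + b2 + b3 + b4) / 4.0
    return LevelScheme(
        bands=(b1, b2, b3, b4),
        ground_splitting=ground,
        excited_splitting=excited,
        center_of_gravity=cog,
        residual=residual,
        warning=residual > residual_threshold,
        assignment=assignment,
    )


def direct_isotope_correlation(splitting_h: float, regression: tuple) -> float:
    """Predict a deuterated splitting from a protiated one by a log-log fit.

    ``regression = (slope, intercept)`` on the log10 scale:
    Delta_D = 10**(slope * log10(Delta_H) + intercept).  The coefficients
    come from an external training set of H/D splitting pairs.
    """
    if splitting_h <= 0:
        raise ValueError("splitting must be positive")
    slope, intercept = regression
    return 10.0 ** (slope * math.log10(splitting_h) + intercept)


def fit_isotope_regression(points, zero_intercept: bool = False, weights=None) -> tuple:
    """Least-squares (slope, intercept) on log10 scale from (H, D) pairs.

    With ``zero_intercept`` the fit is constrained through the origin of the
    log-log plane (a pure power law with prefactor 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be (splitting_H, splitting_D) pairs")
    if np.any(pts <= 0):
        raise ValueError("splittings must be positive")
    x = np.log10(pts[:, 0])
    y = np.log10(pts[:, 1])
    w = np.ones_like(x) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    if zero_intercept:
        slope = float(np.sum(w**2 * x * y) / np.sum(w**2 * x * x))
        return slope, 0.0
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    return float(coef[0]), float(coef[1])
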