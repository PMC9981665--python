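"""Drude-oscillator and Lennard-Jones parameter transforms.

Polarizable force fields of the Drude type attach a mobile charged
particle to each polarizable atom by a harmonic spring.  The spring
constant ``k``, the Drude charge ``q_d`` (negative by convention) and the
atomic polarizability ``alpha`` are related through

    k = C * q_d**2 / alpha

with ``C = 1/(4 pi eps0)`` in internal units, so fixing ``k`` for all
atoms makes ``|q_d|`` grow as ``sqrt(alpha)``.  Because the induced
dipoles already carry part of the dispersion attraction, the LJ well
depths of polarizable atoms are scaled down as a function of their
polarizability (``scale_lj_epsilon``).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .units import DEFAULT_UNITS, UnitSystem

__all__ = [
    "drude_charge_from_polarizability",
    "drude_force_constant",
    "scale_lj_epsilon",
    "self_polarization_energy",
]


def drude_charge_from_polarizability(
    alpha: float, k: float, units: UnitSystem = DEFAULT_UNITS
) -> float:
    """Drude charge (e, negative) for polarizability ``alpha`` (A^3) at
    spring constant ``k`` (kcal/mol/A^2).

    Inverts k = C * q^2 / alpha.  Raises for non-positive ``alpha`` or ``k``.
    """
    if alpha <= 0:
        raise ValueError(f"polarizability must be > 0, got {alpha}")
    if k <= 0:
        raise ValueError(f"spring constant must be > 0, got {k}")
    return -math.sqrt(k * alpha / units.coulomb_constant)


def drude_force_constant(
    alpha: float, q_drude: float, units: UnitSystem = DEFAULT_UNITS
) -> float:
    """Spring constant (kcal/mol/A^2) from polarizability and Drude charge."""
    if alpha <= 0:
        raise ValueError(f"polarizability must be > 0, got {alpha}")
    return units.coulomb_constant * q_drude**2 / alpha


def scale_lj_epsilon(
    eps_nonpol: float, alpha: float, alpha_max: float, s: float
) -> float:
    """Polarizability-scaled LJ well depth.

    eps = eps_nonpol * (dAlpha + s*alpha_max) / (s*dAlpha + alpha_max)
    with dAlpha = alpha_max - alpha.  The scaling interpolates between the
    unscaled well depth at alpha = 0 and ``s * eps_nonpol`` for the most
    polarizable atom (alpha = alpha_max), monotonically in alpha.
    Magnitudes are used throughout; pass |alpha|.
    """
    if not 0 < s <= 1:
        raise ValueError(f"scaling factor s must be in (0, 1], got {s}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if alpha > alpha_max:
        raise ValueError(f"alpha={alpha} exceeds alpha_max={alpha_max}")
    d_alpha = alpha_max - alpha
    # ratio computed first so the alpha = 0 limit is exactly eps_nonpol
    return eps_nonpol * ((d_alpha + s * alpha_max) / (s * d_alpha + alpha_max))


def self_polarization_energy(
    displacements: Iterable[Sequence[float]], k: float
) -> float:
    """Total harmonic energy (kcal/mol) stored in all Drude springs.

    U = sum_i k * |d_i|^2 over the atom-Drude displacement vectors (A).
    """
    if k <= 0:
        raise ValueError(f"spring constant must be > 0, got {k}")
    d = np.atleast_2d(np.asarray(list(displacements), dtype=float))
    if d.size == 0:
        return 0.0
    return float(k * np.sum(d * d))
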