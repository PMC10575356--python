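"""Potential evaluation via the truncated Legendre series.

For an evaluation point at radius ``r`` (shell ``s``) and polar angle
``theta`` from the dipole axis,

    Phi = P / (4 pi sigma_1 r0^2)
          * sum_{l=1}^{L} (r0/R_1)^{l+1}
            * [A~_l^s (r/R_s)^l + B~_l^s (R_s/r)^{l+1}] * l * P_l(cos theta)

The decaying source factor ``(r0/R_1)^{l+1}`` is multiplied into the
(potentially growing) ``A~``/``B~`` columns before anything else, which keeps
every per-degree summand in range.  The series as implemented represents the
field for ``r >= r0``; points below the source radius are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonic_filters import HarmonicConstants
from .model_core import (
    FieldPoint,
    OutsideConductorError,
    RadialDipole,
    SphereModel,
    UnsupportedRegionError,
    validate_dipole,
    validate_model,
)

#: Default truncation degree for all user-facing entry points.
DEFAULT_DEGREE = 100

#: Relative threshold for the adaptive truncation rule: stop once the last
#: five summands each contribute less than this, relative to the partial sum.
ADAPTIVE_RTOL = 1e-12


@dataclass(frozen=True)
class PotentialResult:
    """Potential at one point."""

    value: float  # volts
    degree_used: int
    shell: int


def legendre_sequence(x, L: int) -> np.ndarray:
    """Legendre polynomials ``P_0(x) .. P_L(x)`` by the Bonnet recurrence.

    ``x`` may be a scalar or an array; the output has shape ``(L + 1,) +
    x.shape`` with degree on the leading axis.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0):
        raise ValueError("Legendre abscissa outside [-1, 1]")
    if L < 0:
        raise ValueError(f"L must be >= 0, got {L}")
    out = np.empty((L + 1,) + x.shape)
    out[0] = 1.0
    if L >= 1:
        out[1] = x
    for l in range(2, L + 1):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


def locate_shell(model: SphereModel, r: float) -> int:
    """Smallest shell index ``s`` (1-based) with ``r <= R_s``.

    A point exactly on a boundary belongs to the inner shell; by continuity
    of the potential the choice is immaterial.  A tiny relative tolerance
    absorbs round-off on the outer surface.
    """
    validate_model(model)
    if r < 0.0:
        raise ValueError(f"negative radius {r}")
    radii = model.radii_array()
    if r > radii[-1] * (1.0 + 1e-12):
        raise OutsideConductorError(
            f"r = {r:g} m lies outside the conductor (R_n = {radii[-1]:g} m)"
        )
    return int(np.searchsorted(radii, min(r, radii[-1]))) + 1 if r > radii[0] else 1


def degree_terms(
    model: SphereModel,
    constants: HarmonicConstants,
    dipole: RadialDipole,
    r: float,
    cos_theta,
) -> np.ndarray:
    """Per-degree summands of the potential (shape ``(L,) + cos_theta.shape``).

    Summing over the leading axis gives the potential in volts.  Exposed for
    truncation diagnostics and per-degree boundary-condition checks.
    """
    validate_model(model)
    validate_dipole(dipole, model)
    if constants.model != model:
        raise ValueError("constants were computed for a different model")
    cos_theta = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(cos_theta) > 1.0):
        raise ValueError("cos(theta) outside [-1, 1]")
    r = float(r)
    s = locate_shell(model, r)
    r0 = dipole.r0
    if r < r0 or r == 0.0:
        raise UnsupportedRegionError(
            f"r = {r:g} m is below the source radius r0 = {r0:g} m; the "
            "series only represents the region r >= r0 (> 0)"
        )
    R1 = model.radii[0]
    Rs = model.radii[s - 1]
    sigma1 = model.conductivities[0]
    L = constants.L
    ls = np.arange(1, L + 1, dtype=float)
    shape = (L,) + (1,) * cos_theta.ndim
    P = legendre_sequence(cos_theta, L)[1:]
    if r0 == 0.0:
        # Only the degree-1 term survives the r0 -> 0 limit: the factor
        # (r0/R_1)^{l+1} / r0^2 tends to 1/R_1^2 at l = 1 and to 0 beyond.
        terms = np.zeros(P.shape)
        bracket1 = constants.A_tilde[0, s - 1] * (r / Rs) + constants.B_tilde[
            0, s - 1
        ] * (Rs / r) ** 2
        terms[0] = dipole.moment / (4.0 * np.pi * sigma1 * R1**2) * bracket1 * P[0]
        return terms
    f = (r0 / R1) ** (ls + 1.0)
    ga = f * constants.A_tilde[:, s - 1]
    gb = f * constants.B_tilde[:, s - 1]
    bracket = ga * (r / Rs) ** ls + gb * (Rs / r) ** (ls + 1.0)
    pref = dipole.moment / (4.0 * np.pi * sigma1 * r0**2)
    return pref * (bracket * ls).reshape(shape) * P


def potential_at(
    model: SphereModel,
    constants: HarmonicConstants,
    dipole: RadialDipole,
    r: float,
    cos_theta,
) -> np.ndarray:
    """Potential (volts) at radius ``r`` for one or many polar angles."""
    return degree_terms(model, constants, dipole, r, cos_theta).sum(axis=0)


def potential(
    model: SphereModel,
    constants: HarmonicConstants,
    dipole: RadialDipole,
    point: FieldPoint,
    adaptive: bool = False,
) -> PotentialResult:
    """Potential at a Cartesian point.

    With ``adaptive=True`` the sum stops at the first degree where the last
    five summands each contribute relatively less than ``ADAPTIVE_RTOL``;
    the fixed truncation ``constants.L`` remains the reproducible default.
    """
    cos_theta = point.cos_angle_from(dipole.axis)
    terms = degree_terms(model, constants, dipole, point.r, cos_theta)
    shell = locate_shell(model, point.r)
    degree_used = constants.L
    if adaptive:
        partial = np.cumsum(terms)
        scale = np.maximum.accumulate(np.abs(partial))
        small = np.abs(terms) <= ADAPTIVE_RTOL * np.maximum(scale, np.finfo(float).tiny)
        for l in range(5, constants.L + 1):
            if small[l - 5 : l].all():
                degree_used = l
                break
        value = float(partial[degree_used - 1])
    else:
        value = float(terms.sum())
    return PotentialResult(value=value, degree_used=degree_used, shell=shell)


def surface_potential_profile(
    model: SphereModel,
    constants: HarmonicConstants,
    dipole: RadialDipole,
    thetas,
    radius: float | None = None,
) -> list[PotentialResult]:
    """Potential on a sphere of ``radius`` (default outer surface) at the
    given polar angles from the dipole axis."""
    r = model.outer_radius if radius is None else float(radius)
    shell = locate_shell(model, r)
    values = potential_at(model, constants, dipole, r, np.cos(np.asarray(thetas, dtype=float)))
    return [
        PotentialResult(value=float(v), degree_used=constants.L, shell=shell)
        for v in np.atleast_1d(values)
    ]
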