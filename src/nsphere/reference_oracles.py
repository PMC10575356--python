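"""Independent cross-validation paths for the n-shell recursion.

Four routes to the same physics live here:

* the explicit four-shell constants (historical closed chain of
  proportionality constants ``U, V, Y, Z``),
* the spatial-filter weights ``W_l^s`` (per-degree geometry filter),
* the homogeneous-sphere closed form (generating-function summation),
* a brute-force per-degree linear solve of the boundary conditions.

They share only trivial arithmetic with the main path, so agreement between
all of them and :mod:`nsphere.harmonic_filters` is a genuine check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonic_filters import HarmonicConstants
from .model_core import (
    DipoleError,
    ModelError,
    RadialDipole,
    SphereModel,
    validate_model,
)
from .potential_series import legendre_sequence, locate_shell


@dataclass(frozen=True)
class FourSphereConstants:
    """Explicit four-shell expansion coefficients, degree ``l = 1..L``.

    ``A``/``B`` are indexed ``[l - 1, s - 1]`` and carry the absolute
    normalization (the factor ``(r0/R_1)^{l+1}`` is folded in, so they are
    specific to one dipole radius).
    """

    model: SphereModel
    r0: float
    L: int
    A: np.ndarray
    B: np.ndarray
    U: np.ndarray
    V: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    Z_dot: np.ndarray


def naess_constants(model: SphereModel, r0: float, L: int) -> FourSphereConstants:
    """Four-shell constants via the explicit proportionality chain.

    The chain runs outside-in — ``U -> V -> Y -> (Z, Z_dot)`` — after which
    the ``A``/``B`` pairs are assembled inside-out.  Valid only for exactly
    four shells and ``0 < r0 < R_1``.
    """
    validate_model(model)
    if model.n != 4:
        raise ModelError(f"expected exactly 4 shells, got {model.n}")
    if not 0.0 < r0 < model.radii[0]:
        raise DipoleError(f"r0 = {r0:g} m not strictly inside shell 1")
    R = model.radii_array()
    sig = model.conductivity_array()
    ls = np.arange(1, L + 1, dtype=float)
    U = ls / (ls + 1.0)

    def ratio_powers(s: int) -> tuple[np.ndarray, np.ndarray]:
        # t = (R_s/R_{s+1})^l, u = (R_{s+1}/R_s)^{l+1}   (1-based s)
        return (R[s - 1] / R[s]) ** ls, (R[s] / R[s - 1]) ** (ls + 1.0)

    def step(kappa: float, t: np.ndarray, u: np.ndarray, X_next: np.ndarray) -> np.ndarray:
        G = (U * t - X_next * u) / (t + X_next * u)
        return (U * kappa - G) / (kappa + G)

    t3, u3 = ratio_powers(3)
    t2, u2 = ratio_powers(2)
    t1, u1 = ratio_powers(1)
    V = step(sig[2] / sig[3], t3, u3, U)
    Y = step(sig[1] / sig[2], t2, u2, V)
    Z = (1.0 / U) * (U * t1 - Y * u1) / (t1 + Y * u1)
    Z_dot = step(sig[0] / sig[1], t1, u1, Y)

    b1 = (r0 / R[0]) ** (ls + 1.0)
    kappa12 = sig[0] / sig[1]
    A = np.empty((L, 4))
    B = np.empty((L, 4))
    # A_l^1 = (l+1)/l * (kappa + U Z) / (kappa - Z) * (r0/R1)^{l+1}; this is
    # exactly 1/Z_dot, the form the proportionality chain itself dictates.
    A[:, 0] = (ls + 1.0) / ls * (kappa12 + U * Z) / (kappa12 - Z) * b1
    B[:, 0] = b1
    A[:, 1] = (A[:, 0] + b1) / (t1 + Y * u1)
    B[:, 1] = Y * A[:, 1]
    A[:, 2] = (A[:, 1] + B[:, 1]) / (t2 + V * u2)
    B[:, 2] = V * A[:, 2]
    A[:, 3] = (A[:, 2] + B[:, 2]) / (t3 + U * u3)
    B[:, 3] = U * A[:, 3]
    return FourSphereConstants(
        model=model, r0=r0, L=L, A=A, B=B, U=U, V=V, Y=Y, Z=Z, Z_dot=Z_dot
    )


def coefficient_potential(
    model: SphereModel,
    A: np.ndarray,
    B: np.ndarray,
    P_moment: float,
    r0: float,
    r: float,
    cos_theta,
) -> np.ndarray:
    """Series potential from absolute per-shell coefficients.

    Evaluates ``P/(4 pi sigma_1 r0^2) * sum_l [A_l^s (r/R_s)^l +
    B_l^s (R_s/r)^{l+1}] l P_l(cos theta)`` with ``s`` located from ``r``.
    Shared by every oracle that produces coefficient tables.
    """
    cos_theta = np.asarray(cos_theta, dtype=float)
    L = A.shape[0]
    s = locate_shell(model, r)
    Rs = model.radii[s - 1]
    ls = np.arange(1, L + 1, dtype=float)
    bracket = A[:, s - 1] * (r / Rs) ** ls + B[:, s - 1] * (Rs / r) ** (ls + 1.0)
    Pl = legendre_sequence(cos_theta, L)[1:]
    pref = P_moment / (4.0 * np.pi * model.conductivities[0] * r0**2)
    shape = (L,) + (1,) * cos_theta.ndim
    return pref * ((bracket * ls).reshape(shape) * Pl).sum(axis=0)


def four_sphere_potential(
    constants: FourSphereConstants, P_moment: float, r: float, cos_theta
) -> np.ndarray:
    """Potential from the explicit four-shell constants."""
    return coefficient_potential(
        constants.model, constants.A, constants.B, P_moment, constants.r0, r, cos_theta
    )


def yao_filter(
    constants: HarmonicConstants, model: SphereModel, r: float, l
) -> np.ndarray:
    """Spatial-filter weight(s) ``W_l^s`` at radius ``r``.

    ``W_l^s = A~_l^s / R_1^{l+1} * (r^{2l+1} / R_s^l + X_l^s R_s^{l+1})``,
    i.e. the per-degree bracket with the decaying source factor
    ``(r0/r)^{l+1}`` pulled out, so it depends on the conductor only.
    """
    ls = np.atleast_1d(np.asarray(l, dtype=float))
    if np.any(ls < 1) or np.any(ls > constants.L):
        raise ValueError(f"degree out of range 1..{constants.L}")
    s = locate_shell(model, r)
    idx = ls.astype(int) - 1
    R1 = model.radii[0]
    Rs = model.radii[s - 1]
    A = constants.A_tilde[idx, s - 1]
    X = constants.X[idx, s - 1]
    W = A / R1 ** (ls + 1.0) * (r ** (2.0 * ls + 1.0) / Rs**ls + X * Rs ** (ls + 1.0))
    return W if np.ndim(l) else float(W[0])


def yao_filter_expanded(
    constants: HarmonicConstants, model: SphereModel, r: float, l
) -> np.ndarray:
    """Same weight written out through ``B~`` instead of ``X`` (identity route)."""
    ls = np.atleast_1d(np.asarray(l, dtype=float))
    s = locate_shell(model, r)
    idx = ls.astype(int) - 1
    R1 = model.radii[0]
    Rs = model.radii[s - 1]
    A = constants.A_tilde[idx, s - 1]
    B = constants.B_tilde[idx, s - 1]
    W = (A * r ** (2.0 * ls + 1.0) / Rs**ls + B * Rs ** (ls + 1.0)) / R1 ** (ls + 1.0)
    return W if np.ndim(l) else float(W[0])


def spatial_filter_potential(
    model: SphereModel,
    constants: HarmonicConstants,
    dipole: RadialDipole,
    r: float,
    cos_theta,
) -> np.ndarray:
    """Potential reconstructed through the spatial-filter weights.

    Restores the common factor ``(r0/r)^{l+1}``:
    ``Phi = P/(4 pi sigma_1 r0^2) sum_l (r0/r)^{l+1} W_l^s l P_l``.
    """
    cos_theta = np.asarray(cos_theta, dtype=float)
    r0 = dipole.r0
    if r0 <= 0.0:
        raise DipoleError("spatial-filter route needs r0 > 0")
    L = constants.L
    ls = np.arange(1, L + 1, dtype=float)
    W = yao_filter(constants, model, r, np.arange(1, L + 1))
    Pl = legendre_sequence(cos_theta, L)[1:]
    weights = (r0 / r) ** (ls + 1.0) * W * ls
    pref = dipole.moment / (4.0 * np.pi * model.conductivities[0] * r0**2)
    shape = (L,) + (1,) * cos_theta.ndim
    return pref * (weights.reshape(shape) * Pl).sum(axis=0)


def homogeneous_closed_form(
    sigma: float, R: float, r0: float, theta, P_moment: float
) -> np.ndarray:
    """Surface potential of a radial dipole in a homogeneous sphere.

    Closed form obtained by summing ``sum_{l>=1} (2l+1) f^{l+1} P_l`` with
    the Legendre generating function (``f = r0/R``):

        Phi = P / (4 pi sigma r0 R)
              * [ (1 - f^2) / (1 - 2 f cos(theta) + f^2)^{3/2} - 1 ]
    """
    if not 0.0 < r0 < R:
        raise DipoleError(f"need 0 < r0 < R, got r0 = {r0:g}, R = {R:g}")
    theta = np.asarray(theta, dtype=float)
    f = r0 / R
    c = np.cos(theta)
    denom = (1.0 - 2.0 * f * c + f * f) ** 1.5
    return (
        P_moment
        / (4.0 * np.pi * sigma * r0 * R)
        * ((1.0 - f * f) / denom - 1.0)
    )


def boundary_system_solve(
    model: SphereModel, r0: float, l: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-degree coefficients by solving the boundary conditions directly.

    Unknowns are one ``(A, B)`` pair per shell with ``B`` of shell 1 pinned
    by the source expansion; equations are potential continuity and
    sigma-weighted radial-current continuity at each internal boundary plus
    zero radial current at the outer surface.  Shell-local scaling (the ``B``
    unknowns are scaled by the inner boundary radius) keeps every matrix
    entry O(l), so the solve stays well conditioned at high degree.

    Returns ``(A, B)`` in the absolute normalization of
    :func:`coefficient_potential` (``B_1 = (r0/R_1)^{l+1}``).
    """
    validate_model(model)
    if l < 1:
        raise ValueError(f"degree must be >= 1, got {l}")
    if not 0.0 < r0 < model.radii[0]:
        raise DipoleError(f"r0 = {r0:g} m not strictly inside shell 1")
    R = model.radii_array()
    sig = model.conductivity_array()
    n = model.n
    # phi_s(r) = a_s (r/R_s)^l + b_s (Rin_s / r)^{l+1}; Rin_s = R_{s-1}
    # (Rin_1 = R_1 so that the pinned source term is exactly b_1 = 1).
    Rin = np.concatenate(([R[0]], R[:-1]))
    m = 2 * n - 1
    M = np.zeros((m, m))
    rhs = np.zeros(m)

    def ia(s: int) -> int:
        return s - 1

    def ib(s: int) -> int:
        return n + s - 2  # only s >= 2 is unknown

    row = 0
    for s in range(1, n):
        Rb = R[s - 1]
        ca_in = (Rb / R[s - 1]) ** l  # = 1
        cb_in = (Rin[s - 1] / Rb) ** (l + 1)
        ca_out = (Rb / R[s]) ** l
        cb_out = (Rin[s] / Rb) ** (l + 1)  # = 1
        # potential continuity
        M[row, ia(s)] = ca_in
        if s == 1:
            rhs[row] -= cb_in
        else:
            M[row, ib(s)] = cb_in
        M[row, ia(s + 1)] = -ca_out
        M[row, ib(s + 1)] = -cb_out
        row += 1
        # sigma-weighted radial derivative continuity (common 1/Rb dropped)
        M[row, ia(s)] = sig[s - 1] * l * ca_in
        db = -sig[s - 1] * (l + 1) * cb_in
        if s == 1:
            rhs[row] -= db
        else:
            M[row, ib(s)] = db
        M[row, ia(s + 1)] = -sig[s] * l * ca_out
        M[row, ib(s + 1)] = sig[s] * (l + 1) * cb_out
        row += 1
    # no current through the outer surface
    M[row, ia(n)] = l
    if n == 1:
        rhs[row] = l + 1  # from the pinned b_1 = 1, Rin_1 = R_1 = R_n
    else:
        M[row, ib(n)] = -(l + 1) * (Rin[n - 1] / R[n - 1]) ** (l + 1)
    sol = np.linalg.solve(M, rhs)
    scale = (r0 / R[0]) ** (l + 1)
    A = sol[:n] * scale
    B = np.empty(n)
    B[0] = scale
    for s in range(2, n + 1):
        B[s - 1] = sol[ib(s)] * (Rin[s - 1] / R[s - 1]) ** (l + 1) * scale
    return A, B


def boundary_residuals(
    model: SphereModel, A: np.ndarray, B: np.ndarray, l: int
) -> float:
    """Largest scaled boundary-condition residual of a coefficient set."""
    R = model.radii_array()
    sig = model.conductivity_array()
    n = model.n

    def val(s: int, r: float) -> tuple[float, float]:
        t1 = A[s - 1] * (r / R[s - 1]) ** l
        t2 = B[s - 1] * (R[s - 1] / r) ** (l + 1)
        return t1, t2

    worst = 0.0
    for s in range(1, n):
        r = R[s - 1]
        ti = val(s, r)
        to = val(s + 1, r)
        scale = max(abs(ti[0]), abs(ti[1]), abs(to[0]), abs(to[1]))
        worst = max(worst, abs(sum(ti) - sum(to)) / scale)
        di = sig[s - 1] * (l * ti[0] - (l + 1) * ti[1])
        do = sig[s] * (l * to[0] - (l + 1) * to[1])
        dscale = max(
            sig[s - 1] * l * abs(ti[0]),
            sig[s - 1] * (l + 1) * abs(ti[1]),
            sig[s] * l * abs(to[0]),
            sig[s] * (l + 1) * abs(to[1]),
        )
        worst = max(worst, abs(di - do) / dscale)
    tn = val(n, R[-1])
    worst = max(
        worst,
        abs(l * tn[0] - (l + 1) * tn[1]) / max(l * abs(tn[0]), (l + 1) * abs(tn[1])),
    )
    return worst


def boundary_series_potential(
    model: SphereModel,
    dipole: RadialDipole,
    r: float,
    cos_theta,
    L: int,
) -> np.ndarray:
    """Potential with every degree solved from the boundary-condition system."""
    A = np.empty((L, model.n))
    B = np.empty((L, model.n))
    for l in range(1, L + 1):
        A[l - 1], B[l - 1] = boundary_system_solve(model, dipole.r0, l)
    return coefficient_potential(
        model, A, B, dipole.moment, dipole.r0, r, cos_theta
    )
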