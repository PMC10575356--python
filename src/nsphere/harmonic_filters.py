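"""Per-degree harmonic constants for an n-shell spherical conductor.

For each Legendre degree ``l`` and shell ``s`` the potential contribution is
``A~_l^s (r/R_s)^l + B~_l^s (R_s/r)^{l+1}`` (times the source factor handled
in :mod:`nsphere.potential_series`).  The ratio ``X_l^s = B~_l^s / A~_l^s``
is fixed by the boundary conditions outward of shell ``s`` alone, so it can
be computed by a single inward recursion from the outer surface; the source
normalization ``B~_l^1 = 1`` then fixes the ``A~`` by an outward recursion.
Neither depends on the dipole position, so the constants are computed once
per ``(model, L)`` and cached.

Numerical form of the inward step: with ``U = l/(l+1)``,
``kappa = sigma_s / sigma_{s+1}`` and ``p = (R_s / R_{s+1})^{2l+1}``,

    X_l^s = (U*(kappa - 1)*p + (U*kappa + 1)*X_l^{s+1})
            / ((kappa + U)*p + (kappa - 1)*X_l^{s+1})

which is the textbook two-fraction expression cleared of the inner
denominator.  Only the bounded power ``p <= 1`` appears, so the step neither
overflows nor cancels catastrophically at zero-contrast boundaries (at
``kappa = 1`` it reduces exactly to ``X^{s+1} / p``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ModelError, SphereModel, validate_model


class DegenerateModelError(ModelError):
    """A propagation constant vanished where the recursion must divide by it."""


@dataclass(frozen=True)
class HarmonicConstants:
    """Degree-by-shell constants for one conductor.

    Arrays are indexed ``[l - 1, s - 1]`` for degree ``l = 1..L`` and shell
    ``s = 1..n`` (the ``l = 0`` monopole term is absent for a dipole source).
    """

    model: SphereModel
    L: int
    X: np.ndarray
    A_tilde: np.ndarray
    B_tilde: np.ndarray

    @property
    def degrees(self) -> np.ndarray:
        return np.arange(1, self.L + 1)


def propagation_constants(model: SphereModel, L: int) -> np.ndarray:
    """Inward recursion for ``X_l^s``; returns an array of shape ``(L, n)``.

    ``X[l-1, n-1] = l/(l+1)`` at the outer surface (no current leaves the
    conductor); inner shells follow the recursion described in the module
    docstring.
    """
    validate_model(model)
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    radii = model.radii_array()
    sigma = model.conductivity_array()
    n = model.n
    ls = np.arange(1, L + 1, dtype=float)
    U = ls / (ls + 1.0)
    X = np.empty((L, n))
    X[:, n - 1] = U
    for s in range(n - 1, 0, -1):
        rho = radii[s - 1] / radii[s]
        kappa = sigma[s - 1] / sigma[s]
        p = rho ** (2.0 * ls + 1.0)
        Xo = X[:, s]
        X[:, s - 1] = (U * (kappa - 1.0) * p + (U * kappa + 1.0) * Xo) / (
            (kappa + U) * p + (kappa - 1.0) * Xo
        )
    return X


def expansion_coefficients(
    model: SphereModel, X: np.ndarray, L: int
) -> HarmonicConstants:
    """Outward recursion for ``A~_l^s`` and ``B~_l^s = X_l^s A~_l^s``.

    The source normalization gives ``A~_l^1 = 1 / X_l^1`` (hence
    ``B~_l^1 = 1``); crossing each boundary then multiplies ``A~`` by
    ``(1 + X^{s-1}) / ((R_{s-1}/R_s)^l + X^s (R_s/R_{s-1})^{l+1})``.

    Values are stored as-is in double precision; this is safe for
    ``L <= 300`` on models whose adjacent radius ratios are at least 0.5.
    """
    validate_model(model)
    if X.shape != (L, model.n):
        raise ValueError(f"X has shape {X.shape}, expected {(L, model.n)}")
    radii = model.radii_array()
    ls = np.arange(1, L + 1, dtype=float)
    A = np.empty_like(X)
    B = np.empty_like(X)
    if np.any(X[:, 0] == 0.0) or not np.all(np.isfinite(X[:, 0])):
        raise DegenerateModelError(
            "propagation constant X_l^1 vanished or diverged; the model is "
            "degenerate for at least one degree"
        )
    A[:, 0] = 1.0 / X[:, 0]
    B[:, 0] = X[:, 0] * A[:, 0]  # 1 up to rounding; keeps B = X*A bitwise
    for s in range(2, model.n + 1):
        rho = radii[s - 2] / radii[s - 1]
        A[:, s - 1] = A[:, s - 2] * (1.0 + X[:, s - 2]) / (
            rho**ls + X[:, s - 1] * (1.0 / rho) ** (ls + 1.0)
        )
        B[:, s - 1] = X[:, s - 1] * A[:, s - 1]
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise DegenerateModelError(
            "non-finite expansion coefficients; check the L <= 300 / "
            "radius-ratio >= 0.5 guard"
        )
    return HarmonicConstants(model=model, L=L, X=X, A_tilde=A, B_tilde=B)


_CACHE: dict[tuple[SphereModel, int], HarmonicConstants] = {}


def harmonic_constants(model: SphereModel, L: int = 100) -> HarmonicConstants:
    """Constants for ``(model, L)``, computed once and cached."""
    key = (model, L)
    hit = _CACHE.get(key)
    if hit is None:
        hit = expansion_coefficients(model, propagation_constants(model, L), L)
        if len(_CACHE) > 64:
            _CACHE.clear()
        _CACHE[key] = hit
    return hit


def constants_table(constants: HarmonicConstants) -> pd.DataFrame:
    """Long-format table of the constants (columns l, s, X, A_tilde, B_tilde)."""
    L, n = constants.X.shape
    ls, ss = np.meshgrid(np.arange(1, L + 1), np.arange(1, n + 1), indexing="ij")
    return pd.DataFrame(
        {
            "l": ls.ravel(),
            "s": ss.ravel(),
            "X": constants.X.ravel(),
            "A_tilde": constants.A_tilde.ravel(),
            "B_tilde": constants.B_tilde.ravel(),
        }
    )
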