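"""Conductor geometry, current sources, and evaluation points.

Everything is SI: radii in meters, conductivities in S/m, dipole moments in
A·m, potentials in volts.  A conductor is a set of ``n`` concentric,
homogeneous, isotropic spherical shells; shell ``s`` (1-based) is the region
bounded outwardly by radius ``R_s``, and the space beyond ``R_n`` is vacuum
(zero conductivity, never stored).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


class ModelError(ValueError):
    """Base class for invalid conductor / source / point specifications."""


class EmptyModelError(ModelError):
    """Model with no shells."""


class GeometryError(ModelError):
    """Radii not strictly increasing and positive."""


class ConductivityError(ModelError):
    """Non-positive or non-finite shell conductivity."""


class RegistryError(KeyError):
    """Unknown canonical model name."""


class DipoleError(ModelError):
    """Invalid dipole specification for a given conductor."""


class OutsideConductorError(ModelError):
    """Evaluation point beyond the outermost shell."""


class UnsupportedRegionError(ModelError):
    """Evaluation point below the source radius (series branch not covered)."""


class PlacementError(ModelError):
    """Electrode too far from the outer surface to be projected honestly."""


@dataclass(frozen=True)
class SphereModel:
    """Concentric-sphere volume conductor.

    Parameters
    ----------
    radii
        Boundary radii ``R_1 < ... < R_n`` in meters.
    conductivities
        Shell conductivities ``sigma_1 ... sigma_n`` in S/m, where
        ``sigma_s`` fills the region bounded outwardly by ``R_s``.
    """

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        object.__setattr__(
            self, "conductivities", tuple(float(c) for c in self.conductivities)
        )

    @property
    def n(self) -> int:
        """Number of shells."""
        return len(self.radii)

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    def radii_array(self) -> np.ndarray:
        return np.asarray(self.radii, dtype=float)

    def conductivity_array(self) -> np.ndarray:
        return np.asarray(self.conductivities, dtype=float)


@dataclass(frozen=True)
class RadialDipole:
    """Radial current dipole strictly inside the innermost shell.

    The orientation is the radius through ``position`` (positive ``moment``
    points outward).  A dipole exactly at the origin has no radius to point
    along, so ``orientation`` must then be supplied explicitly.
    """

    position: tuple[float, float, float]
    moment: float = 1.0
    orientation: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3:
            raise DipoleError("dipole position must be a 3-vector")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", float(self.moment))
        if self.orientation is not None:
            ori = np.asarray(self.orientation, dtype=float)
            nrm = np.linalg.norm(ori)
            if not np.isfinite(nrm) or nrm == 0.0:
                raise DipoleError("explicit orientation must be a nonzero vector")
            object.__setattr__(self, "orientation", tuple(ori / nrm))

    @property
    def r0(self) -> float:
        """Distance from the center (meters)."""
        return float(np.linalg.norm(self.position))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the dipole axis."""
        r0 = self.r0
        if r0 > 0.0:
            return np.asarray(self.position) / r0
        if self.orientation is None:
            raise DipoleError(
                "a dipole at the origin needs an explicit orientation"
            )
        return np.asarray(self.orientation)

    def eccentricity(self, model: SphereModel) -> float:
        """``r0 / R_1``, in ``[0, 1)`` for a valid source."""
        return self.r0 / model.radii[0]


@dataclass(frozen=True)
class FieldPoint:
    """Cartesian evaluation point inside the conductor."""

    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3:
            raise ModelError("field point must be a 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.position))

    def cos_angle_from(self, axis: np.ndarray) -> float:
        """Cosine of the polar angle between this point and ``axis``."""
        r = self.r
        if r == 0.0:
            return 1.0
        c = float(np.dot(self.position, axis) / r)
        return float(np.clip(c, -1.0, 1.0))


def validate_model(model: SphereModel) -> SphereModel:
    """Check all SphereModel invariants; return the model unchanged.

    Raises
    ------
    EmptyModelError, GeometryError, ConductivityError
    """
    if model.n < 1:
        raise EmptyModelError("a conductor needs at least one shell")
    radii = model.radii_array()
    sigma = model.conductivity_array()
    if len(model.conductivities) != model.n:
        raise ConductivityError(
            f"{model.n} radii but {len(model.conductivities)} conductivities"
        )
    if not np.all(np.isfinite(radii)) or radii[0] <= 0.0 or np.any(np.diff(radii) <= 0.0):
        raise GeometryError(f"radii must be positive and strictly increasing, got {model.radii}")
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0.0):
        raise ConductivityError(
            f"conductivities must be positive and finite, got {model.conductivities}"
        )
    return model


def validate_dipole(dipole: RadialDipole, model: SphereModel) -> RadialDipole:
    """Check that the dipole sits strictly inside the innermost shell."""
    if not dipole.r0 < model.radii[0]:
        raise DipoleError(
            f"dipole radius {dipole.r0:g} m is not inside the innermost "
            f"shell (R_1 = {model.radii[0]:g} m)"
        )
    if dipole.r0 == 0.0 and dipole.orientation is None:
        raise DipoleError("a dipole at the origin needs an explicit orientation")
    return dipole


#: Canonical models.  The classic three-shell conductivities are
#: brain 1/3, skull 1/(3*80), scalp 1/3 S/m; the radii are a fixed registry
#: convention (87/92/100 mm), since the comparisons this package supports are
#: radius-agnostic.
_REGISTRY: dict[str, SphereModel] = {
    "three-shell-classic": SphereModel(
        radii=(0.087, 0.092, 0.100),
        conductivities=(1.0 / 3.0, 1.0 / 240.0, 1.0 / 3.0),
    ),
    "single-shell": SphereModel(radii=(0.100,), conductivities=(1.0 / 3.0,)),
}


def canonical_model(name: str) -> SphereModel:
    """Return a named model from the registry.

    Raises
    ------
    RegistryError
        If the name is unknown.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown model {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def random_model(n_shells: int, seed: int) -> SphereModel:
    """Deterministic random conductor for stress testing.

    Radii are drawn increasing within ``[0.05, 0.11]`` m; conductivities are
    drawn log-uniform in ``[1e-3, 1]`` S/m, independently per shell.
    """
    if n_shells < 1:
        raise ValueError(f"n_shells must be >= 1, got {n_shells}")
    rng = np.random.default_rng(seed)
    radii = np.sort(rng.uniform(0.05, 0.11, size=n_shells))
    while np.any(np.diff(radii) <= 0.0):  # pragma: no cover - measure zero
        radii = np.sort(rng.uniform(0.05, 0.11, size=n_shells))
    sigma = 10.0 ** rng.uniform(-3.0, 0.0, size=n_shells)
    return validate_model(SphereModel(tuple(radii), tuple(sigma)))


def split_shell(model: SphereModel, shell: int, fraction: float = 0.5) -> SphereModel:
    """Insert a fictitious boundary inside shell ``shell`` (1-based).

    The shell is split into two shells of identical conductivity at the
    radius ``R_inner + fraction * (R_shell - R_inner)``; the potential
    everywhere must be unchanged.  Useful for padding a model to a fixed
    shell count and for invariance tests.
    """
    validate_model(model)
    if not 1 <= shell <= model.n:
        raise ValueError(f"shell must be in 1..{model.n}, got {shell}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    inner = 0.0 if shell == 1 else model.radii[shell - 2]
    cut = inner + fraction * (model.radii[shell - 1] - inner)
    radii = list(model.radii)
    sigma = list(model.conductivities)
    radii.insert(shell - 1, cut)
    sigma.insert(shell - 1, sigma[shell - 1])
    return validate_model(SphereModel(tuple(radii), tuple(sigma)))


def load_model(path: str | Path) -> SphereModel:
    """Read a model from a JSON file.

    Expected keys: ``radii_m`` (ascending list) and
    ``conductivities_S_per_m`` (same length).
    """
    path = Path(path)
    with path.open() as fh:
        data = json.load(fh)
    try:
        radii = data["radii_m"]
        sigma = data["conductivities_S_per_m"]
    except (KeyError, TypeError) as exc:
        raise ModelError(
            f"{path}: expected JSON keys 'radii_m' and 'conductivities_S_per_m'"
        ) from exc
    return validate_model(SphereModel(tuple(radii), tuple(sigma)))


def save_model(model: SphereModel, path: str | Path) -> None:
    """Write a model to a JSON file (inverse of :func:`load_model`)."""
    with Path(path).open("w") as fh:
        json.dump(
            {
                "radii_m": list(model.radii),
                "conductivities_S_per_m": list(model.conductivities),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
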