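"""Hard-cylinder geometry for the coarse-grained G-quadruplex model.

A G4 unit is a hard cylinder (HC) of diameter ``D`` and length ``L`` carrying
two attractive stacking sites on its symmetry axis, one beyond each flat base,
at ``L/2 + 0.15*D/2`` from the center of mass.  The cylinder family is indexed
by a dimensionless shape factor ``K`` around the reference Tel22 dimensions
``D0 = 2.12 nm``, ``L0 = 3.10 nm`` via ``D = D0*K``, ``L = L0/K`` (the product
``D*L`` is K-invariant).  Sites of distinct particles interact through a
square well of depth ``u0`` and range ``delta``; the hard core is the cylinder
body alone (sites carry no excluded volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "CylinderShape",
    "CylinderParticle",
    "InteractionParams",
    "stacking_site_positions",
    "cylinders_overlap",
    "sw_pair_energy",
    "D0_REF",
    "L0_REF",
]

#: reference Tel22 hard-cylinder dimensions (nm)
D0_REF = 2.12
L0_REF = 3.10

#: stacking sites sit at L/2 + SITE_FACTOR * D/2 from the center, on the axis
SITE_FACTOR = 0.15

_AXIS_TOL = 1e-12


@dataclass(frozen=True)
class CylinderShape:
    """Shape of one hard cylinder, parametrized by the aspect factor K.

    Attributes
    ----------
    D0, L0 : float
        Reference diameter and length in nm.
    K : float
        Dimensionless shape factor; ``D = D0*K`` and ``L = L0/K`` so that the
        product ``D*L`` is preserved along the family.
    """

    D0: float = D0_REF
    L0: float = L0_REF
    K: float = 1.0

    def __post_init__(self):
        if self.D0 <= 0 or self.L0 <= 0 or self.K <= 0:
            raise ValueError("D0, L0, K must all be positive")

    @property
    def D(self) -> float:
        """Diameter D0*K in nm."""
        return self.D0 * self.K

    @property
    def L(self) -> float:
        """Length L0/K in nm."""
        return self.L0 / self.K

    @property
    def radius(self) -> float:
        return 0.5 * self.D

    @property
    def half_length(self) -> float:
        return 0.5 * self.L

    @property
    def site_offset(self) -> float:
        """Axial distance of each stacking site from the center (nm)."""
        return 0.5 * self.L + SITE_FACTOR * 0.5 * self.D

    @property
    def volume(self) -> float:
        """pi (D/2)^2 L in nm^3 (varies with K; D*L does not)."""
        return np.pi * self.radius**2 * self.L

    @property
    def circumscribed_radius(self) -> float:
        return float(np.hypot(self.half_length, self.radius))

    @property
    def gyration_radius(self) -> float:
        """Scalar Rg of a uniform cylinder: sqrt(L^2/12 + D^2/8)."""
        return float(np.sqrt(self.L**2 / 12.0 + self.D**2 / 8.0))


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > _AXIS_TOL:
        raise ValueError(f"{name} must be a unit vector (|norm - 1| <= {_AXIS_TOL}); got norm {n!r}")
    return v


@dataclass
class CylinderParticle:
    """One hard cylinder: center (nm), unit axis, shape, optional rim frame.

    ``frame`` is a unit vector perpendicular to ``axis`` fixing the azimuth of
    the covalent rim sites; it is only meaningful in trimer mode.
    """

    center: np.ndarray
    axis: np.ndarray
    shape: CylinderShape = field(default_factory=CylinderShape)
    frame: np.ndarray | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axis = _as_unit(self.axis, "axis")
        if self.frame is not None:
            self.frame = _as_unit(self.frame, "frame")
            if abs(float(self.frame @ self.axis)) > 1e-9:
                raise ValueError("frame must be perpendicular to axis")

    def rim_site_positions(self) -> np.ndarray:
        """(2, 3) covalent rim sites at axial +-L/2, radial D/2 along frame."""
        if self.frame is None:
            raise ValueError("rim sites require a body frame (trimer mode)")
        radial = self.shape.radius * self.frame
        axial = self.shape.half_length * self.axis
        return np.stack([self.center + axial + radial,
                         self.center - axial + radial])


def stacking_site_positions(p: CylinderParticle) -> np.ndarray:
    """(2, 3) array of the two stacking sites: center +- axis*(L/2 + 0.15 D/2)."""
    off = p.shape.site_offset * p.axis
    return np.stack([p.center + off, p.center - off])


def cylinders_overlap(a: CylinderParticle, b: CylinderParticle) -> bool:
    """Exact overlap predicate for two closed finite cylinders (flat caps).

    Uses a GJK query on the two convex bodies with a bounding-sphere prefilter;
    exact touching (separation below ~1e-10 of the body scale) counts as
    non-overlapping.  Symmetric in its arguments.  Periodic images are the
    caller's responsibility.
    """
    d = b.center - a.center
    reach = a.shape.circumscribed_radius + b.shape.circumscribed_radius
    if float(d @ d) >= reach * reach:
        return False
    return bool(_kernels.gjk_cylinders_overlap(
        a.center, a.axis, a.shape.half_length, a.shape.radius,
        b.center, b.axis, b.shape.half_length, b.shape.radius))


@dataclass(frozen=True)
class InteractionParams:
    """Square-well stacking interaction (plus covalent tether in trimer mode).

    Attributes
    ----------
    delta : float
        Well range / site diameter in nm (0.5 nm for self-assembling monomers;
        0.25*D0 in trimer mode).
    u0 : float
        Well depth; the natural energy unit (energies are reported in u0).
    Tstar : float
        Reduced temperature k_B T / u0.
    delta_cov : float or None
        Covalent tether cutoff in nm (0.5*D0 in trimer mode): the potential is
        infinite beyond it and zero inside.  None outside trimer mode.
    """

    delta: float = 0.5
    u0: float = 1.0
    Tstar: float = 0.1
    delta_cov: float | None = None

    def __post_init__(self):
        if self.delta <= 0 or self.Tstar <= 0 or self.u0 <= 0:
            raise ValueError("delta, u0 and Tstar must be positive")
        if self.delta_cov is not None and self.delta_cov <= 0:
            raise ValueError("delta_cov must be positive when given")

    @classmethod
    def monomer(cls, Tstar: float, delta: float = 0.5) -> "InteractionParams":
        return cls(delta=delta, Tstar=Tstar)

    @classmethod
    def trimer(cls, Tstar: float, D0: float = D0_REF) -> "InteractionParams":
        """Trimer-mode defaults: delta = 0.25*D0, covalent cutoff 0.5*D0."""
        return cls(delta=0.25 * D0, Tstar=Tstar, delta_cov=0.5 * D0)


def sw_pair_energy(a: CylinderParticle, b: CylinderParticle,
                   params: InteractionParams) -> float:
    """Square-well energy between all stacking site pairs of two particles.

    Each site pair closer than ``delta`` (strictly) contributes ``-u0``; the
    boundary ``r == delta`` is outside the well.  Overlap of the hard cores is
    handled separately (infinite energy) and is not checked here.
    """
    sa = stacking_site_positions(a)
    sb = stacking_site_positions(b)
    d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=-1)
    return -params.u0 * float(np.count_nonzero(d < params.delta))
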