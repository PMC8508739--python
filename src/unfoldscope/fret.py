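"""Trp–Trp FRET geometry: indole centers, 1La dipoles, kappa^2, efficiency.

The orientation factor between a donor and an acceptor transition dipole is

    kappa^2 = (cos(theta) - 3 cos(theta_A) cos(theta_D))^2

with ``theta`` the angle between the dipoles and ``theta_A``/``theta_D`` the
angles each dipole makes with the vector joining the indole centers; the
transfer efficiency at separation R is

    E = 1 / (1 + (2/3) / kappa^2 * (R / R0)^6),

defined as 0 in the limit kappa^2 -> 0.  The Förster radius for the Trp–Trp
pair defaults to 7.8 Å.

The 1La transition dipole of indole is approximated as an in-plane unit
vector obtained by rotating the projected CE3→NE1 long-axis reference about
the ring normal by a configurable angle (default −38°, a common literature
convention); because the convention is not unique, a sensitivity scan over
the angle is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError, IncompleteResidueError
from .structure import ProteinStructure, TRP_RING_ATOMS, _require_residue

__all__ = [
    "IndoleGeometry",
    "FretPair",
    "DistanceDistribution",
    "indole_center",
    "indole_geometry",
    "la_dipole",
    "kappa_squared",
    "fret_efficiency",
    "fret_pair",
    "kappa2_sensitivity",
    "distance_distribution",
    "DEFAULT_R0",
    "DEFAULT_LA_ANGLE_DEG",
]

DEFAULT_R0 = 7.8  # Angstrom, Trp-Trp Förster radius
DEFAULT_LA_ANGLE_DEG = -38.0
ATOMIC_MASS = {"C": 12.011, "N": 14.007}


@dataclass(frozen=True)
class IndoleGeometry:
    """Geometry of one indole ring: atoms, center, plane normal, 1La dipole."""

    ring_atoms: dict[str, np.ndarray]  # the 9 ring atoms
    center: np.ndarray  # Angstrom
    plane_normal: np.ndarray  # unit
    dipole: np.ndarray  # unit, in-plane


@dataclass(frozen=True)
class FretPair:
    donor: IndoleGeometry
    acceptor: IndoleGeometry
    R: float  # Angstrom
    kappa2: float
    efficiency: float
    R0: float = DEFAULT_R0

    def __post_init__(self):
        if self.R <= 0:
            raise DomainError("separation R must be positive")
        if not 0.0 <= self.kappa2 <= 4.0 + 1e-12:
            raise DomainError("kappa^2 must lie in [0, 4]")
        if not 0.0 <= self.efficiency <= 1.0:
            raise DomainError("efficiency must lie in [0, 1]")


@dataclass
class DistanceDistribution:
    """Per-frame indole center separations and their histogram."""

    distances: np.ndarray  # Angstrom, one per frame
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    @property
    def frames(self) -> int:
        return self.distances.size

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=0))

    @property
    def min(self) -> float:
        return float(self.distances.min())

    @property
    def max(self) -> float:
        return float(self.distances.max())


def _ring_coordinates(
    structure: ProteinStructure, trp: tuple[str, int], model_index: int
) -> dict[str, np.ndarray]:
    own = _require_residue(structure, trp)
    xyz = structure.coords[model_index]
    ring: dict[str, np.ndarray] = {}
    for i in np.nonzero(own)[0]:
        if structure.atom_name[i] in TRP_RING_ATOMS:
            ring[structure.atom_name[i]] = xyz[i]
    missing = set(TRP_RING_ATOMS) - set(ring)
    if missing:
        raise IncompleteResidueError(
            f"residue {trp[0]}:{trp[1]} lacks ring atoms {sorted(missing)}"
        )
    return ring


def indole_center(
    ring_atoms: dict[str, np.ndarray], mass_weighted: bool = False
) -> np.ndarray:
    """Centroid of the nine indole ring atoms (optionally mass-weighted)."""
    missing = set(TRP_RING_ATOMS) - set(ring_atoms)
    if missing:
        raise IncompleteResidueError(f"missing ring atoms {sorted(missing)}")
    coords = np.array([ring_atoms[a] for a in TRP_RING_ATOMS])
    if mass_weighted:
        masses = np.array(
            [ATOMIC_MASS["N" if a.startswith("N") else "C"]
             for a in TRP_RING_ATOMS]
        )
        return (coords * masses[:, None]).sum(axis=0) / masses.sum()
    return coords.mean(axis=0)


def _plane_normal(coords: np.ndarray, ring: dict[str, np.ndarray]
                  ) -> np.ndarray:
    """Best-fit plane normal with a deterministic orientation."""
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-8 * max(svals[0], 1e-30):
        raise GeometryError("ring atoms are collinear; plane undefined")
    normal = vt[2]
    # orient by the ring's own chirality so rigid motion maps normals rigidly
    reference = np.cross(ring["NE1"] - ring["CG"], ring["CD2"] - ring["CG"])
    if np.dot(normal, reference) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def la_dipole(
    ring_atoms: dict[str, np.ndarray],
    angle_deg: float = DEFAULT_LA_ANGLE_DEG,
) -> np.ndarray:
    """In-plane 1La unit vector: projected CE3→NE1 axis rotated by angle_deg.

    The rotation is about the ring plane normal (Rodrigues), so the result is
    exactly orthogonal to the normal for any angle.
    """
    coords = np.array([ring_atoms[a] for a in TRP_RING_ATOMS])
    normal = _plane_normal(coords, ring_atoms)
    axis = ring_atoms["NE1"] - ring_atoms["CE3"]
    axis = axis - np.dot(axis, normal) * normal  # project into the plane
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise GeometryError("long-axis reference degenerate")
    axis /= norm
    theta = np.radians(angle_deg)
    rotated = (
        axis * np.cos(theta)
        + np.cross(normal, axis) * np.sin(theta)
        + normal * np.dot(normal, axis) * (1.0 - np.cos(theta))
    )
    return rotated / np.linalg.norm(rotated)


def indole_geometry(
    structure: ProteinStructure,
    trp: tuple[str, int],
    angle_deg: float = DEFAULT_LA_ANGLE_DEG,
    mass_weighted: bool = False,
    model_index: int = 0,
) -> IndoleGeometry:
    """Extract center, plane normal and 1La dipole for one tryptophan."""
    ring = _ring_coordinates(structure, trp, model_index)
    coords = np.array([ring[a] for a in TRP_RING_ATOMS])
    return IndoleGeometry(
        ring_atoms=ring,
        center=indole_center(ring, mass_weighted=mass_weighted),
        plane_normal=_plane_normal(coords, ring),
        dipole=la_dipole(ring, angle_deg=angle_deg),
    )


def kappa_squared(donor, acceptor) -> float:
    """Orientation factor between two dipoles.

    Accepts :class:`IndoleGeometry` objects, or ``(dipole, center)`` tuples of
    vectors for constructed geometries.
    """
    mu_d, r_d = _dipole_center(donor)
    mu_a, r_a = _dipole_center(acceptor)
    sep = r_a - r_d
    dist = np.linalg.norm(sep)
    if dist < 1e-9:
        raise GeometryError("donor and acceptor centers coincide")
    rhat = sep / dist
    cos_t = float(np.dot(mu_d, mu_a))
    cos_d = float(np.dot(mu_d, rhat))
    cos_a = float(np.dot(mu_a, rhat))
    k2 = (cos_t - 3.0 * cos_a * cos_d) ** 2
    return float(min(k2, 4.0))


def _dipole_center(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, IndoleGeometry):
        mu, c = obj.dipole, obj.center
    else:
        mu, c = obj
    mu = np.asarray(mu, dtype=float)
    norm = np.linalg.norm(mu)
    if norm == 0:
        raise GeometryError("zero dipole vector")
    return mu / norm, np.asarray(c, dtype=float)


def fret_efficiency(kappa2: float, R: float, R0: float = DEFAULT_R0) -> float:
    """Transfer efficiency E = 1 / (1 + (2/3)/kappa^2 (R/R0)^6); E(0) = 0."""
    if R <= 0 or R0 <= 0:
        raise DomainError("R and R0 must be positive")
    if kappa2 < 0:
        raise DomainError("kappa^2 must be non-negative")
    if kappa2 == 0.0:
        return 0.0
    return float(1.0 / (1.0 + (2.0 / 3.0) / kappa2 * (R / R0) ** 6))


def fret_pair(
    structure: ProteinStructure,
    donor: tuple[str, int],
    acceptor: tuple[str, int],
    R0: float = DEFAULT_R0,
    angle_deg: float = DEFAULT_LA_ANGLE_DEG,
    mass_weighted: bool = False,
    model_index: int = 0,
) -> FretPair:
    """Full FRET geometry for a tryptophan pair in one model."""
    d = indole_geometry(structure, donor, angle_deg, mass_weighted, model_index)
    a = indole_geometry(structure, acceptor, angle_deg, mass_weighted,
                        model_index)
    r = float(np.linalg.norm(a.center - d.center))
    k2 = kappa_squared(d, a)
    return FretPair(d, a, r, k2, fret_efficiency(k2, r, R0), R0)


def kappa2_sensitivity(
    structure: ProteinStructure,
    donor: tuple[str, int],
    acceptor: tuple[str, int],
    angle_deg: float = DEFAULT_LA_ANGLE_DEG,
    half_width_deg: float = 15.0,
    n_grid: int = 31,
    model_index: int = 0,
) -> tuple[float, float]:
    """(min, max) of kappa^2 over dipole angles angle_deg ± half_width_deg."""
    angles = np.linspace(angle_deg - half_width_deg,
                         angle_deg + half_width_deg, n_grid)
    vals = []
    for ang in angles:
        d = indole_geometry(structure, donor, ang, model_index=model_index)
        a = indole_geometry(structure, acceptor, ang, model_index=model_index)
        vals.append(kappa_squared(d, a))
    return float(np.min(vals)), float(np.max(vals))


def distance_distribution(
    structure: ProteinStructure,
    trp_a: tuple[str, int],
    trp_b: tuple[str, int],
    bin_width: float = 0.25,
    mass_weighted: bool = True,
) -> DistanceDistribution:
    """Indole center–center distance per frame plus a histogram.

    Trajectory analysis uses mass-weighted ring centers by default; bins are
    aligned to multiples of ``bin_width``.
    """
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    dists = np.empty(structure.n_models)
    for m in range(structure.n_models):
        try:
            ring_a = _ring_coordinates(structure, trp_a, m)
            ring_b = _ring_coordinates(structure, trp_b, m)
        except (IncompleteResidueError, KeyError) as exc:
            raise IncompleteResidueError(f"frame {m}: {exc}") from exc
        ca = indole_center(ring_a, mass_weighted=mass_weighted)
        cb = indole_center(ring_b, mass_weighted=mass_weighted)
        dists[m] = np.linalg.norm(cb - ca)
    lo = np.floor(dists.min() / bin_width) * bin_width
    hi = np.ceil(dists.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return DistanceDistribution(distances=dists, bin_edges=edges,
                                bin_counts=counts)
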