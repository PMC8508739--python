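"""Seedable generators for every input the analysis consumes.

The generators reproduce the statistical structure the fitting stages assume:

* TCSPC decay bundles — the reconvolution forward model evaluated on the
  instrument grid (0.027 ns/channel, emission 320–410 nm in 5 nm steps,
  Gaussian excitation profile of 1.2 ns FWHM) with Poisson photon noise.
  Default lifetimes 5.1/1.9/0.1 ns; the default amplitude bands put the
  spectral weight of the two resolvable components near 45%/55% with the
  sub-resolution component carrying ~10%.
* denaturation transition curves — double-Boltzmann truth with multiplicative
  Gaussian noise, emulating two unfolding transitions near 1.5 and 4 M urea;
* toy indole-pair structures — idealised planar indole rings at controlled
  separation/orientation plus random non-overlapping background atoms,
  PDB-writable;
* jittered trajectories — i.i.d. Gaussian per-atom displacement per frame.

All randomness flows through a single integer seed per spec; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DomainError, PlacementError
from .structure import ProteinStructure, TRP_RING_ATOMS
from .tcspc import (
    DEFAULT_CHANNEL_WIDTH_NS,
    DecayTrace,
    InstrumentResponse,
    MultiExpModel,
    convolve_decay,
)
from .transitions import DoubleBoltzmannParams, TransitionCurve, double_boltzmann

__all__ = [
    "DecaySimSpec",
    "CurveSimSpec",
    "IndolePairSpec",
    "ToyStructureSpec",
    "DecayBundle",
    "simulate_decays",
    "simulate_transition_curve",
    "build_toy_structure",
    "simulate_trajectory",
    "indole_template",
]

# default amplitude bands (center nm, sigma nm, amplitude): the amplitudes
# solve mean_lambda f_i = (0.405, 0.495, 0.100) on the 320-410 nm grid for the
# default lifetimes, i.e. a 45:55 split between the two resolvable components
# with the sub-resolution component carrying 10% of the spectral weight
_DEFAULT_BANDS = (
    (355.0, 25.0, 0.0360745),
    (340.0, 25.0, 0.1921976),
    (330.0, 25.0, 1.0),
)


@dataclass(frozen=True)
class DecaySimSpec:
    """Conditions for a synthetic multi-wavelength TCSPC measurement."""

    lifetimes: tuple[float, ...] = (5.1, 1.9, 0.1)  # ns
    amplitude_spectra: tuple[tuple[float, float, float], ...] = _DEFAULT_BANDS
    wavelengths: tuple[float, ...] = tuple(np.arange(320.0, 411.0, 5.0))
    irf_center: float = 1.5  # ns
    irf_fwhm: float = 1.2  # ns (instrument pulse duration)
    irf_peak_counts: float = 1.0e4
    peak_counts: float = 1.0e4  # expected maximum counts over all traces
    background_rate: float = 2.0  # counts/channel
    channel_width: float = DEFAULT_CHANNEL_WIDTH_NS  # ns
    n_channels: int = 1024
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(t <= 0 for t in self.lifetimes):
            raise DomainError("lifetimes must be positive")
        if self.peak_counts <= 0:
            raise DomainError("peak_counts must be positive")
        if len(self.amplitude_spectra) != len(self.lifetimes):
            raise DomainError("one amplitude band per lifetime component")


@dataclass
class DecayBundle:
    """Simulated decays plus everything needed to judge recovery."""

    traces: list[DecayTrace]
    irf: InstrumentResponse
    true_model: MultiExpModel
    spec: DecaySimSpec


def _gaussian_irf(spec: DecaySimSpec) -> InstrumentResponse:
    t = np.arange(spec.n_channels) * spec.channel_width
    sigma = spec.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.exp(-0.5 * ((t - spec.irf_center) / sigma) ** 2)
    counts = np.round(profile * spec.irf_peak_counts)
    return InstrumentResponse(counts=counts, channel_width=spec.channel_width)


def simulate_decays(spec: DecaySimSpec) -> DecayBundle:
    """Poisson-noised reconvolved decays at every emission wavelength.

    The channel-wise expectation equals the reconvolution forward model for
    the returned ``true_model``; counts are drawn Poisson per channel (or the
    expectation rounded when ``poisson_noise`` is off).
    """
    rng = np.random.default_rng(spec.seed)
    irf = _gaussian_irf(spec)
    wl = np.asarray(spec.wavelengths, dtype=float)
    taus = np.asarray(spec.lifetimes, dtype=float)
    amps_raw = np.empty((wl.size, taus.size))
    for i, (center, sigma, amp) in enumerate(spec.amplitude_spectra):
        amps_raw[:, i] = amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)

    expected_raw = np.empty((wl.size, spec.n_channels))
    for k in range(wl.size):
        model = MultiExpModel(lifetimes=taus, amplitudes=amps_raw[k],
                              background=0.0)
        expected_raw[k] = convolve_decay(model, irf, spec.n_channels)
    peak_raw = expected_raw.max()
    scale = max(spec.peak_counts - spec.background_rate, 0.0) / peak_raw
    amps = amps_raw * scale
    expected = expected_raw * scale + spec.background_rate

    traces = []
    for k in range(wl.size):
        counts = (
            rng.poisson(expected[k]).astype(float)
            if spec.poisson_noise
            else np.round(expected[k])
        )
        traces.append(DecayTrace(wavelength=float(wl[k]), counts=counts,
                                 channel_width=spec.channel_width))
    true_model = MultiExpModel(
        lifetimes=taus, amplitudes=amps,
        background=np.full(wl.size, spec.background_rate), wavelengths=wl,
    )
    return DecayBundle(traces=traces, irf=irf, true_model=true_model, spec=spec)


@dataclass(frozen=True)
class CurveSimSpec:
    """Conditions for a synthetic denaturation transition curve."""

    truth: DoubleBoltzmannParams = field(
        default_factory=lambda: DoubleBoltzmannParams(
            y0=6.0, A=-2.5, p=0.5, c1=1.5, c2=4.0, k1=0.3, k2=0.3
        )
    )
    urea_grid: tuple[float, ...] = tuple(np.linspace(0.0, 8.0, 24))
    noise_sd: float = 0.01  # relative (multiplicative Gaussian)
    signal_name: str = "tau1_ns"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def simulate_transition_curve(spec: CurveSimSpec) -> TransitionCurve:
    """Double-Boltzmann truth with multiplicative Gaussian noise, seeded."""
    u = np.asarray(spec.urea_grid, dtype=float)
    y = np.asarray(double_boltzmann(u, spec.truth), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y * (1.0 + spec.noise_sd * rng.standard_normal(u.size))
    return TransitionCurve(denaturant=u, signal=y,
                           signal_name=spec.signal_name)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def indole_template() -> dict[str, np.ndarray]:
    """Idealised planar indole ring, 1.40 Å bonds, centered at its centroid.

    Built as a regular hexagon (benzene ring) fused with a regular pentagon
    (pyrrole ring) sharing the CD2–CE2 edge, oriented with the plane normal
    along +z and the projected CE3→NE1 long axis along +x.
    """
    side = 1.40
    hexagon_names = ["CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2"]
    ring: dict[str, np.ndarray] = {}
    for k, name in enumerate(hexagon_names):
        ang = np.radians(60.0 * k)
        ring[name] = side * np.array([np.cos(ang), np.sin(ang), 0.0])
    # pentagon fused on the CD2-CE2 edge, on the side away from the hexagon
    mid = 0.5 * (ring["CD2"] + ring["CE2"])
    outward = mid / np.linalg.norm(mid)
    apothem = side / (2.0 * np.tan(np.radians(36.0)))
    circum = side / (2.0 * np.sin(np.radians(36.0)))
    center5 = mid + apothem * outward
    ang_ce2 = np.arctan2(*(ring["CE2"] - center5)[[1, 0]])
    ang_cd2 = np.arctan2(*(ring["CD2"] - center5)[[1, 0]])
    step = np.radians(72.0)
    # walk CE2 -> NE1 -> CD1 -> CG -> CD2 around the pentagon
    diff = (ang_cd2 - ang_ce2) % (2 * np.pi)
    sign = 1.0 if np.isclose(diff, 4 * step % (2 * np.pi), atol=1e-6) else -1.0
    for j, name in enumerate(["NE1", "CD1", "CG"], start=1):
        ang = ang_ce2 + sign * step * j
        ring[name] = center5 + circum * np.array(
            [np.cos(ang), np.sin(ang), 0.0]
        )
    coords = np.array([ring[a] for a in TRP_RING_ATOMS])
    centroid = coords.mean(axis=0)
    # rotate the long axis (CE3 -> NE1) onto +x within the plane
    axis = ring["NE1"] - ring["CE3"]
    phi = np.arctan2(axis[1], axis[0])
    rot = Rotation.from_euler("z", -phi).as_matrix()
    return {a: rot @ (ring[a] - centroid) for a in TRP_RING_ATOMS}


@dataclass(frozen=True)
class IndolePairSpec:
    """One donor/acceptor indole pair at controlled distance/orientation.

    The donor lies in the xy-plane (normal +z, long axis +x); the acceptor is
    rotated by intrinsic xyz Euler angles and translated by ``separation``
    along +z, so identity angles give parallel in-plane dipoles perpendicular
    to the separation vector (kappa^2 = 1).
    """

    separation: float = 7.8  # Angstrom, center-to-center
    acceptor_euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.separation <= 0:
            raise DomainError("pair separation must be positive")


@dataclass(frozen=True)
class ToyStructureSpec:
    """Synthetic structure: indole pairs plus random background atoms."""

    indole_pairs: tuple[IndolePairSpec, ...] = (IndolePairSpec(),)
    n_background_atoms: int = 0
    placement_box: float = 40.0  # Angstrom cube edge
    min_separation: float = 2.0  # Angstrom between placed atoms
    background_chain: str = "A"
    seed: int = 0
    max_retries: int = 200


def build_toy_structure(spec: ToyStructureSpec) -> ProteinStructure:
    """Assemble the toy structure (coordinates rounded to PDB precision)."""
    template = indole_template()
    chain, resname, resnum, name, element, xyz = [], [], [], [], [], []

    def add_ring(res_id: int, rot: np.ndarray, offset: np.ndarray):
        for atom in TRP_RING_ATOMS:
            chain.append("A")
            resname.append("TRP")
            resnum.append(res_id)
            name.append(atom)
            element.append("N" if atom.startswith("N") else "C")
            xyz.append(rot @ template[atom] + offset)

    pair_spacing = 30.0  # keep pairs from interacting
    res_id = 0
    for i, pair in enumerate(spec.indole_pairs):
        base = np.array([pair_spacing * i, 0.0, 0.0])
        res_id = 10 * i + 1
        add_ring(res_id, np.eye(3), base)
        rot = Rotation.from_euler(
            "xyz", pair.acceptor_euler_deg, degrees=True
        ).as_matrix()
        add_ring(res_id + 1, rot, base + np.array([0.0, 0.0, pair.separation]))

    rng = np.random.default_rng(spec.seed)
    placed = np.array(xyz) if xyz else np.empty((0, 3))
    bg_start = res_id + 10
    for j in range(spec.n_background_atoms):
        for attempt in range(spec.max_retries + 1):
            cand = rng.uniform(0.0, spec.placement_box, 3)
            if placed.size == 0 or np.min(
                np.linalg.norm(placed - cand, axis=1)
            ) >= spec.min_separation:
                break
        else:
            raise PlacementError(
                f"could not place background atom {j} after "
                f"{spec.max_retries} retries"
            )
        placed = np.vstack([placed, cand])
        chain.append(spec.background_chain)
        resname.append("GLY")
        resnum.append(bg_start + j)
        name.append("CA")
        element.append("C")
        xyz.append(cand)

    coords = np.round(np.array(xyz), 3)[None]
    return ProteinStructure(
        chain=np.array(chain, dtype=object),
        residue_name=np.array(resname, dtype=object),
        residue_number=np.array(resnum, dtype=int),
        atom_name=np.array(name, dtype=object),
        element=np.array(element, dtype=object),
        coords=coords,
    )


def simulate_trajectory(
    base: ProteinStructure,
    n_frames: int,
    jitter_sd: float,
    seed: int = 0,
) -> ProteinStructure:
    """Frame series: base coordinates + i.i.d. Gaussian displacement per atom.

    Emulates only the frame bookkeeping of an MD trajectory, not its physics.
    Coordinates are rounded to PDB precision so PDB round-trips are lossless.
    """
    if n_frames < 1:
        raise DomainError("need at least one frame")
    if jitter_sd < 0:
        raise DomainError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    frames = np.empty((n_frames, base.n_atoms, 3))
    for f in range(n_frames):
        frames[f] = base_xyz + rng.normal(0.0, jitter_sd, base_xyz.shape)
    return ProteinStructure(
        chain=base.chain, residue_name=base.residue_name,
        residue_number=base.residue_number, atom_name=base.atom_name,
        element=base.element, coords=np.round(frames, 3), icode=base.icode,
        chain_roles=base.chain_roles,
        secondary_structure=base.secondary_structure,
    )
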