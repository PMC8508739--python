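"""Tryptophan microenvironment descriptors on protein structures.

For every tryptophan the module computes the descriptors used to rationalise
intrinsic-fluorescence differences between homologous proteins:

* ``N_sigma`` — protein atoms within a cutoff (default 7 Å) of any atom of the
  tryptophan (own residue excluded);
* ``N_pol`` — the polar (N, O) atoms among them;
* absolute and relative solvent-accessible surface area (Shrake–Rupley);
* ``N_C-term`` — microenvironment atoms belonging to a configurable domain
  (default the alpha-subunit C-terminal domain, residues 236–355);
* ``N_sec`` — percentage of microenvironment atoms in helix/strand residues;
* ``N_beta-sub`` — atoms of the other subunit within the cutoff of the
  side-chain atoms;
* contacts with recognised side-chain and backbone quenchers of indole
  fluorescence (proton transfer from Lys/Tyr, electron transfer to Cys
  sulfur, His/Gln/Asn amide or Asp/Glu carboxyl groups, and the backbone
  carbonyl near the ring CE3 atom).

Hydrogens are excluded from all counts and areas by default so that crystal
structures and MD frames are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError, IncompleteResidueError, ResidueLookupError

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "DomainDefinition",
    "QuencherContact",
    "MicroenvReport",
    "VDW_RADII",
    "find_tryptophans",
    "count_neighbors",
    "compute_sasa",
    "relative_sasa",
    "assign_secondary_structure",
    "secondary_structure_fraction",
    "screen_quenchers",
    "microenv_report",
]

# fixed published van der Waals radii, Angstrom
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

AMINO3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model, in PDB conventions."""

    chain: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    coords: np.ndarray  # Angstrom, shape (3,)
    model_index: int = 0
    icode: str = ""
    occupancy: float = 1.0


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive residue interval on one chain (default: C-terminal domain)."""

    chain: str
    start: int = 236
    end: int = 355

    def __post_init__(self):
        if self.start > self.end:
            raise DomainError("domain start must not exceed end")


class ProteinStructure:
    """Columnar atom table with one or more coordinate models.

    Per-atom annotations (chain, residue, atom name, element) are shared by
    all models; ``coords`` has shape ``(n_models, n_atoms, 3)``.
    """

    def __init__(
        self,
        chain: np.ndarray,
        residue_name: np.ndarray,
        residue_number: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
        coords: np.ndarray,
        icode: np.ndarray | None = None,
        chain_roles: dict[str, str] | None = None,
        secondary_structure: dict[tuple[str, int], str] | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise DomainError("coords must have shape (n_models, n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise DomainError("coordinates must be finite")
        n = coords.shape[1]
        self.chain = np.asarray(chain, dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray([str(e).upper() for e in element], dtype=object)
        self.icode = (
            np.asarray(icode, dtype=object)
            if icode is not None
            else np.full(n, "", dtype=object)
        )
        for arr in (self.chain, self.residue_name, self.residue_number,
                    self.atom_name, self.element, self.icode):
            if arr.shape != (n,):
                raise DomainError("annotation arrays must match atom count")
        self.coords = coords
        self.chain_roles = dict(chain_roles) if chain_roles else {}
        for ch in self.chain_roles:
            if ch not in set(self.chain.tolist()):
                raise DomainError(f"chain_roles names absent chain {ch!r}")
        self.secondary_structure = dict(secondary_structure or {})

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.element == "H"

    def residue_mask(self, chain: str, resnum: int) -> np.ndarray:
        return (self.chain == chain) & (self.residue_number == resnum)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_number, residue_name), file order."""
        seen, out = set(), []
        for ch, num, name in zip(self.chain, self.residue_number,
                                 self.residue_name):
            key = (ch, int(num))
            if key not in seen:
                seen.add(key)
                out.append((ch, int(num), name))
        return out

    def atom_records(self, model_index: int = 0) -> list[AtomRecord]:
        xyz = self.coords[model_index]
        return [
            AtomRecord(self.chain[i], self.residue_name[i],
                       int(self.residue_number[i]), self.atom_name[i],
                       self.element[i], xyz[i].copy(), model_index,
                       self.icode[i])
            for i in range(self.n_atoms)
        ]

    def subset(self, mask: np.ndarray) -> "ProteinStructure":
        return ProteinStructure(
            self.chain[mask], self.residue_name[mask],
            self.residue_number[mask], self.atom_name[mask],
            self.element[mask], self.coords[:, mask, :],
            icode=self.icode[mask],
            chain_roles={c: r for c, r in self.chain_roles.items()
                         if c in set(self.chain[mask].tolist())},
            secondary_structure=self.secondary_structure,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "ProteinStructure":
        """Rigid-body copy: x -> R x + t applied to every model."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new = self.coords @ rot.T + tr
        return ProteinStructure(
            self.chain, self.residue_name, self.residue_number,
            self.atom_name, self.element, new, icode=self.icode,
            chain_roles=self.chain_roles,
            secondary_structure=self.secondary_structure,
        )


@dataclass(frozen=True)
class QuencherContact:
    chain: str
    residue_name: str
    residue_number: int
    atom_name: str
    distance: float  # Angstrom
    mechanism: str


@dataclass
class MicroenvReport:
    """Per-tryptophan microenvironment descriptors (one row per model)."""

    table: pd.DataFrame
    quenchers: dict[tuple[str, int], list[QuencherContact]] = field(
        default_factory=dict
    )

    def summary(self) -> pd.DataFrame:
        """Mean ± sd over models for every numeric descriptor."""
        value_cols = [
            c for c in self.table.select_dtypes("number").columns
            if c not in ("model", "residue_number")
        ]
        grouped = self.table.groupby(["chain", "residue_number"])[value_cols]
        mean = grouped.mean().add_suffix("_mean")
        sd = grouped.std(ddof=0).add_suffix("_sd")
        return mean.join(sd).reset_index()


# ---------------------------------------------------------------------------
# Tryptophan inventory
# ---------------------------------------------------------------------------

def find_tryptophans(source) -> list[tuple[str, int]]:
    """Locate tryptophans in a structure or amino-acid sequence(s).

    Accepts a :class:`ProteinStructure` (residues named TRP), a plain
    sequence string (returns 1-based positions of ``W`` on pseudo-chain
    ``A``), or a mapping ``chain -> sequence``.  Unknown residue letters in
    sequences are skipped with a warning.  Results are ordered by chain then
    residue number.
    """
    if isinstance(source, ProteinStructure):
        hits = {
            (ch, num)
            for ch, num, name in source.residues()
            if name == "TRP"
        }
        return sorted(hits)
    if isinstance(source, str):
        seqs = {"A": source}
    elif isinstance(source, dict):
        seqs = source
    else:
        raise TypeError("expected ProteinStructure, str, or {chain: sequence}")
    out: list[tuple[str, int]] = []
    valid = set(AMINO3.values())
    for ch in sorted(seqs):
        for i, aa in enumerate(seqs[ch].upper(), start=1):
            if aa == "W":
                out.append((ch, i))
            elif aa not in valid:
                warnings.warn(
                    f"unknown residue code {aa!r} at {ch}:{i}; skipped",
                    stacklevel=2,
                )
    return out


# ---------------------------------------------------------------------------
# Neighbor counting
# ---------------------------------------------------------------------------

def _require_residue(structure: ProteinStructure, trp: tuple[str, int]
                     ) -> np.ndarray:
    mask = structure.residue_mask(*trp)
    if not mask.any():
        raise ResidueLookupError(f"residue {trp[0]}:{trp[1]} not found")
    return mask


def _microenv_candidates(
    structure: ProteinStructure,
    trp: tuple[str, int],
    cutoff: float,
    reference: str,
    model_index: int,
    include_hydrogens: bool,
) -> np.ndarray:
    """Boolean mask of non-own atoms within ``cutoff`` of the reference set."""
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    own = _require_residue(structure, trp)
    xyz = structure.coords[model_index]
    ref_mask = own.copy()
    if reference == "sidechain_atoms":
        ref_mask &= ~np.isin(structure.atom_name, list(BACKBONE_ATOMS))
    elif reference != "all_atoms":
        raise DomainError("reference must be 'all_atoms' or 'sidechain_atoms'")
    if not ref_mask.any():
        raise IncompleteResidueError(
            f"residue {trp[0]}:{trp[1]} has no {reference} reference atoms"
        )
    cand = ~own
    if not include_hydrogens:
        cand &= ~structure.is_hydrogen
    result = np.zeros(structure.n_atoms, dtype=bool)
    idx = np.nonzero(cand)[0]
    if idx.size == 0:
        return result
    tree = cKDTree(xyz[ref_mask])
    dmin, _ = tree.query(xyz[idx])
    result[idx[dmin <= cutoff]] = True
    return result


def count_neighbors(
    structure: ProteinStructure,
    trp: tuple[str, int],
    cutoff: float = 7.0,
    reference: str = "all_atoms",
    selection=None,
    model_index: int = 0,
    include_hydrogens: bool = False,
) -> int:
    """Atoms within ``cutoff`` of the tryptophan's reference atom set.

    ``selection`` is an optional boolean mask or a callable
    ``structure -> mask`` restricting which atoms are counted (polar atoms,
    a domain, another subunit, ...).  The tryptophan's own atoms never count.
    """
    near = _microenv_candidates(
        structure, trp, cutoff, reference, model_index, include_hydrogens
    )
    if selection is not None:
        sel = selection(structure) if callable(selection) else np.asarray(selection)
        near = near & sel
    return int(near.sum())


def select_polar(structure: ProteinStructure,
                 include_sulfur: bool = False) -> np.ndarray:
    elems = ("N", "O", "S") if include_sulfur else ("N", "O")
    return np.isin(structure.element, elems)


def select_domain(domain: DomainDefinition):
    def _sel(structure: ProteinStructure) -> np.ndarray:
        return (
            (structure.chain == domain.chain)
            & (structure.residue_number >= domain.start)
            & (structure.residue_number <= domain.end)
        )
    return _sel


def select_other_subunit(own_chain: str):
    def _sel(structure: ProteinStructure) -> np.ndarray:
        if structure.chain_roles:
            own_role = structure.chain_roles.get(own_chain)
            return np.array(
                [structure.chain_roles.get(c) != own_role for c in structure.chain]
            )
        return structure.chain != own_chain
    return _sel


def select_secondary(structure: ProteinStructure,
                     labels: tuple[str, ...] = ("H", "E")) -> np.ndarray:
    ss = structure.secondary_structure
    return np.array(
        [ss.get((c, int(n)), "C") in labels
         for c, n in zip(structure.chain, structure.residue_number)]
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_radii(structure: ProteinStructure, mask: np.ndarray,
                default_radius: float) -> np.ndarray:
    radii = np.empty(int(mask.sum()))
    unknown = set()
    for j, el in enumerate(structure.element[mask]):
        r = VDW_RADII.get(el)
        if r is None:
            unknown.add(el)
            r = default_radius
        radii[j] = r
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}; using default vdW radius "
            f"{default_radius} A",
            stacklevel=3,
        )
    return radii


def compute_sasa(
    structure: ProteinStructure,
    probe: float = 1.4,
    n_points: int = 960,
    model_index: int = 0,
    include_hydrogens: bool = False,
    default_radius: float = DEFAULT_VDW_RADIUS,
) -> tuple[np.ndarray, dict[tuple[str, int], float]]:
    """Shrake–Rupley sphere-sampling solvent-accessible surface area.

    Returns per-atom areas (Å², zero for atoms excluded as hydrogens) and a
    per-residue dict keyed by ``(chain, residue_number)``.
    """
    if probe < 0:
        raise DomainError("probe radius must be non-negative")
    mask = np.ones(structure.n_atoms, dtype=bool)
    if not include_hydrogens:
        mask &= ~structure.is_hydrogen
    xyz = structure.coords[model_index][mask]
    radii = _atom_radii(structure, mask, default_radius) + probe
    n = xyz.shape[0]
    areas_sub = np.zeros(n)
    if n:
        pts = _sphere_points(n_points)
        rmax = radii.max()
        tree = cKDTree(xyz)
        neighbor_lists = tree.query_ball_point(xyz, 2.0 * rmax)
        for i in range(n):
            nbrs = [j for j in neighbor_lists[i] if j != i]
            sphere = xyz[i] + radii[i] * pts
            if nbrs:
                d = np.linalg.norm(
                    sphere[:, None, :] - xyz[nbrs][None, :, :], axis=2
                )
                exposed = np.all(d >= radii[nbrs][None, :], axis=1)
                frac = exposed.mean()
            else:
                frac = 1.0
            areas_sub[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    per_atom = np.zeros(structure.n_atoms)
    per_atom[mask] = areas_sub
    per_residue: dict[tuple[str, int], float] = {}
    for i in np.nonzero(mask)[0]:
        key = (structure.chain[i], int(structure.residue_number[i]))
        per_residue[key] = per_residue.get(key, 0.0) + per_atom[i]
    return per_atom, per_residue


def relative_sasa(
    structure: ProteinStructure,
    residue: tuple[str, int],
    probe: float = 1.4,
    n_points: int = 960,
    model_index: int = 0,
    include_hydrogens: bool = False,
) -> tuple[float, float]:
    """(absolute Å², percent of the residue's isolated surface).

    The reference is the residue with every other residue deleted, the most
    literal reading of "% of the total surface area of the residue".
    """
    own = _require_residue(structure, residue)
    _, per_res = compute_sasa(structure, probe, n_points, model_index,
                              include_hydrogens)
    abs_area = per_res.get((residue[0], residue[1]), 0.0)
    isolated = structure.subset(own)
    _, per_res_iso = compute_sasa(isolated, probe, n_points, model_index,
                                  include_hydrogens)
    ref = per_res_iso.get((residue[0], residue[1]), 0.0)
    rel = 100.0 * abs_area / ref if ref > 0 else float("nan")
    return abs_area, min(rel, 100.0) if np.isfinite(rel) else rel


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def assign_secondary_structure(
    structure: ProteinStructure, model_index: int = 0
) -> dict[tuple[str, int], str]:
    """Fallback phi/psi-window assignment (H/E; coil elsewhere).

    A residue is provisionally helical for phi in (-100, -30) and psi in
    (-80, -5), strand for phi in (-180, -80) and psi in (90, 180) or below
    -170; runs shorter than 3 consecutive residues are demoted to coil.
    """
    xyz = structure.coords[model_index]
    backbone: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for i in range(structure.n_atoms):
        if structure.atom_name[i] in ("N", "CA", "C"):
            key = (structure.chain[i], int(structure.residue_number[i]))
            backbone.setdefault(key, {})[structure.atom_name[i]] = xyz[i]
    labels: dict[tuple[str, int], str] = {}
    by_chain: dict[str, list[int]] = {}
    for ch, num in backbone:
        by_chain.setdefault(ch, []).append(num)
    for ch, nums in by_chain.items():
        nums = sorted(nums)
        raw = {}
        for num in nums:
            prev, nxt = (ch, num - 1), (ch, num + 1)
            here = backbone[(ch, num)]
            if (
                prev in backbone and nxt in backbone
                and {"N", "CA", "C"} <= set(here)
                and "C" in backbone[prev] and "N" in backbone[nxt]
            ):
                phi = _dihedral(backbone[prev]["C"], here["N"], here["CA"],
                                here["C"])
                psi = _dihedral(here["N"], here["CA"], here["C"],
                                backbone[nxt]["N"])
                if -100 < phi < -30 and -80 < psi < -5:
                    raw[num] = "H"
                elif -180 <= phi < -80 and (90 < psi <= 180 or psi < -170):
                    raw[num] = "E"
        for label in ("H", "E"):
            run: list[int] = []
            for num in nums + [None]:
                if num is not None and raw.get(num) == label and (
                    not run or num == run[-1] + 1
                ):
                    run.append(num)
                else:
                    if len(run) >= 3:
                        for r in run:
                            labels[(ch, r)] = label
                    run = [num] if num is not None and raw.get(num) == label else []
    return labels


def secondary_structure_fraction(
    structure: ProteinStructure,
    trp: tuple[str, int],
    cutoff: float = 7.0,
    model_index: int = 0,
    include_hydrogens: bool = False,
    fallback: bool = True,
) -> float:
    """Percent of microenvironment atoms belonging to helix/strand residues.

    Uses annotated secondary structure when present, otherwise the phi/psi
    fallback assigner (unless disabled).  Returns NaN with a warning when no
    assignment or no neighbors are available.
    """
    st = structure
    if not st.secondary_structure:
        if not fallback:
            warnings.warn(
                "no secondary-structure annotation and fallback disabled",
                stacklevel=2,
            )
            return float("nan")
        st = ProteinStructure(
            structure.chain, structure.residue_name, structure.residue_number,
            structure.atom_name, structure.element, structure.coords,
            icode=structure.icode, chain_roles=structure.chain_roles,
            secondary_structure=assign_secondary_structure(structure,
                                                           model_index),
        )
    near = _microenv_candidates(st, trp, cutoff, "all_atoms", model_index,
                                include_hydrogens)
    n_sigma = int(near.sum())
    if n_sigma == 0:
        warnings.warn("empty microenvironment; fraction undefined",
                      stacklevel=2)
        return float("nan")
    in_sec = near & select_secondary(st)
    return 100.0 * int(in_sec.sum()) / n_sigma


# ---------------------------------------------------------------------------
# Quencher screening
# ---------------------------------------------------------------------------

# (residue, atom) -> mechanism label for side-chain quenchers of indole
SIDECHAIN_QUENCHERS: dict[tuple[str, str], str] = {
    ("LYS", "NZ"): "proton-transfer-amine",
    ("TYR", "OH"): "proton-transfer-hydroxyl",
    ("CYS", "SG"): "electron-transfer-sulfur",
    ("HIS", "ND1"): "electron-transfer-amide",
    ("HIS", "NE2"): "electron-transfer-amide",
    ("GLN", "OE1"): "electron-transfer-amide",
    ("GLN", "NE2"): "electron-transfer-amide",
    ("ASN", "OD1"): "electron-transfer-amide",
    ("ASN", "ND2"): "electron-transfer-amide",
    ("ASP", "OD1"): "electron-transfer-carboxyl",
    ("ASP", "OD2"): "electron-transfer-carboxyl",
    ("ASP", "CG"): "electron-transfer-carboxyl",
    ("GLU", "OE1"): "electron-transfer-carboxyl",
    ("GLU", "OE2"): "electron-transfer-carboxyl",
    ("GLU", "CD"): "electron-transfer-carboxyl",
}


def screen_quenchers(
    structure: ProteinStructure,
    trp: tuple[str, int],
    cutoff: float = 5.5,
    model_index: int = 0,
) -> list[QuencherContact]:
    """Contacts between the indole ring and recognised quenching groups.

    Side-chain quenchers are measured as the minimum distance from any of the
    nine ring atoms; backbone-carbonyl quenching is measured from the ring
    CE3 atom to carbonyl carbons (the tryptophan's own backbone included).
    Contacts are sorted by distance; the list is empty when none fall within
    ``cutoff``.
    """
    own = _require_residue(structure, trp)
    xyz = structure.coords[model_index]
    ring = own & np.isin(structure.atom_name, list(TRP_RING_ATOMS))
    if not ring.any():
        raise IncompleteResidueError(
            f"residue {trp[0]}:{trp[1]} has no indole ring atoms"
        )
    ring_xyz = xyz[ring]
    contacts: list[QuencherContact] = []
    ce3 = own & (structure.atom_name == "CE3")
    ce3_xyz = xyz[ce3][0] if ce3.any() else None
    for i in range(structure.n_atoms):
        key = (structure.residue_name[i], structure.atom_name[i])
        if key in SIDECHAIN_QUENCHERS and not own[i]:
            d = float(np.min(np.linalg.norm(ring_xyz - xyz[i], axis=1)))
            if d <= cutoff:
                contacts.append(QuencherContact(
                    structure.chain[i], structure.residue_name[i],
                    int(structure.residue_number[i]), structure.atom_name[i],
                    d, SIDECHAIN_QUENCHERS[key],
                ))
        if structure.atom_name[i] == "C" and ce3_xyz is not None:
            d = float(np.linalg.norm(ce3_xyz - xyz[i]))
            if d <= cutoff:
                contacts.append(QuencherContact(
                    structure.chain[i], structure.residue_name[i],
                    int(structure.residue_number[i]), "C", d,
                    "backbone-carbonyl",
                ))
    contacts.sort(key=lambda c: c.distance)
    return contacts


# ---------------------------------------------------------------------------
# Full per-tryptophan report
# ---------------------------------------------------------------------------

def microenv_report(
    structure: ProteinStructure,
    tryptophans: list[tuple[str, int]] | None = None,
    neighbor_cutoff: float = 7.0,
    quencher_cutoff: float = 5.5,
    probe: float = 1.4,
    n_points: int = 960,
    domain: DomainDefinition | None = None,
    include_hydrogens: bool = False,
) -> MicroenvReport:
    """All microenvironment descriptors, one row per tryptophan per model."""
    trps = tryptophans if tryptophans is not None else find_tryptophans(structure)
    rows = []
    quenchers: dict[tuple[str, int], list[QuencherContact]] = {}
    for m in range(structure.n_models):
        for trp in trps:
            n_sigma = count_neighbors(structure, trp, neighbor_cutoff,
                                      model_index=m,
                                      include_hydrogens=include_hydrogens)
            n_pol = count_neighbors(structure, trp, neighbor_cutoff,
                                    selection=select_polar, model_index=m,
                                    include_hydrogens=include_hydrogens)
            sasa_abs, sasa_rel = relative_sasa(
                structure, trp, probe=probe, n_points=n_points, model_index=m,
                include_hydrogens=include_hydrogens,
            )
            dom = domain or DomainDefinition(chain=trp[0])
            n_cterm = count_neighbors(structure, trp, neighbor_cutoff,
                                      selection=select_domain(dom),
                                      model_index=m,
                                      include_hydrogens=include_hydrogens)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n_sec = secondary_structure_fraction(
                    structure, trp, neighbor_cutoff, model_index=m,
                    include_hydrogens=include_hydrogens,
                )
            n_beta = count_neighbors(structure, trp, neighbor_cutoff,
                                     reference="sidechain_atoms",
                                     selection=select_other_subunit(trp[0]),
                                     model_index=m,
                                     include_hydrogens=include_hydrogens)
            rows.append({
                "chain": trp[0], "residue_number": trp[1], "model": m,
                "n_sigma": n_sigma, "n_pol": n_pol,
                "sasa_abs_A2": sasa_abs, "sasa_rel_pct": sasa_rel,
                "n_cterm": n_cterm, "n_sec_pct": n_sec,
                "n_beta_sub": n_beta,
            })
            if m == 0:
                quenchers[trp] = screen_quenchers(
                    structure, trp, quencher_cutoff, model_index=m
                )
    return MicroenvReport(table=pd.DataFrame(rows), quenchers=quenchers)
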