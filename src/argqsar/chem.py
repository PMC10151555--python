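"""Molecular data model and structure-level primitives.

This module owns everything the descriptor layer consumes: structure
parsing (SDF/MOL/SMILES), 3D embedding for connectivity-only inputs,
bond-graph shortest paths, ring/donor/hybridization typing, Gasteiger
partial charges, centre of mass and Shrake-Rupley surface areas.

Structures are held in a light :class:`Molecule` container decoupled
from the underlying toolkit so that graph-level operations (and their
tests) can run on hand-built molecules without any chemistry toolkit
involvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdPartialCharges

log = logging.getLogger(__name__)

# RDKit is chatty about records it cannot kekulize; we report parse
# failures ourselves with record ids.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Bondi van der Waals radii (Å), the conventional set for surface areas.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "B": 1.92,
    "Si": 2.10,
    "Se": 1.90,
}

VDW_RADIUS_SETS: dict[str, dict[str, float]] = {"bondi": BONDI_RADII}

#: |partial charge| at or below which a hydrogen counts as lipophilic.
LIPOPHILIC_H_CHARGE_CUTOFF = 0.200


class StructureError(ValueError):
    """Raised for unusable structure input."""


@dataclass
class SurfaceParams:
    """Parameters of the Shrake-Rupley surface calculation.

    probe_radius
        Solvent probe radius in Å; 1.4 Å is the conventional water
        probe.  A probe of 0 yields the van der Waals (molecular)
        surface used for the MSA half of the ``rsa`` descriptor.
    vdw_radius_set
        Name of the van der Waals radius table (``"bondi"``).
    sample_points_per_atom
        Number of test points per atomic sphere; area converges as
        this grows.
    """

    probe_radius: float = 1.4
    vdw_radius_set: str = "bondi"
    sample_points_per_atom: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.sample_points_per_atom < 92:
            raise ValueError("sample_points_per_atom must be >= 92")
        if self.vdw_radius_set not in VDW_RADIUS_SETS:
            raise ValueError(f"unknown vdw_radius_set {self.vdw_radius_set!r}")

    @property
    def radii(self) -> dict[str, float]:
        return VDW_RADIUS_SETS[self.vdw_radius_set]


@dataclass
class Atom:
    """One atom with coordinates, charge and the category flags the
    descriptors test against."""

    index: int
    element: str
    coords: np.ndarray
    mass: float
    partial_charge: float | None = None
    is_ring: bool = False
    is_ring_nitrogen: bool = False
    is_ring_carbon: bool = False
    is_donor: bool = False
    is_sp2_oxygen: bool = False
    is_lipophilic_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be positive")
        if self.is_ring_nitrogen and not (self.is_ring and self.element == "N"):
            raise ValueError(f"atom {self.index}: is_ring_nitrogen requires a ring N")
        if self.is_ring_carbon and not (self.is_ring and self.element == "C"):
            raise ValueError(f"atom {self.index}: is_ring_carbon requires a ring C")


@dataclass
class Molecule:
    """A small molecule: atoms, a bond graph and optional activity.

    ``bonds`` is a list of ``(i, j, order)`` tuples over atom indices.
    ``ic50_nM``/``pic50`` are linked by pIC50 = 9 - log10(IC50/nM).
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    ic50_nM: float | None = None
    pic50: float | None = None
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id}: invalid bond ({i}, {j})")
        if self.ic50_nM is not None:
            if self.ic50_nM <= 0:
                raise ValueError(f"molecule {self.id}: IC50 must be positive")
            expected = 9.0 - math.log10(self.ic50_nM)
            if self.pic50 is None:
                self.pic50 = expected
            elif abs(self.pic50 - expected) > 1e-6:
                raise ValueError(
                    f"molecule {self.id}: pic50={self.pic50} inconsistent with "
                    f"ic50_nM={self.ic50_nM} (expected {expected:.6f})"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        q = [a.partial_charge for a in self.atoms]
        if any(v is None for v in q):
            raise StructureError(f"molecule {self.id}: partial charges not assigned")
        return np.array(q, dtype=float)


@dataclass
class ParseFailure:
    """A structure record that could not be turned into a Molecule."""

    record_id: str
    reason: str


# ---------------------------------------------------------------------------
# Structure input


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: f.GetNumAtoms())


def _prepare_rdmol(rdmol: Chem.Mol, mol_id: str, embed_seed: int) -> Chem.Mol:
    """Largest fragment, explicit hydrogens, 3D coordinates."""
    rdmol = _largest_fragment(rdmol)
    Chem.SanitizeMol(rdmol)
    has_conf = rdmol.GetNumConformers() > 0 and rdmol.GetConformer().Is3D()
    rdmol = Chem.AddHs(rdmol, addCoords=has_conf)
    if rdmol.GetNumConformers() == 0 or not rdmol.GetConformer().Is3D():
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise StructureError(f"3D embedding failed for {mol_id}")
        try:
            AllChem.MMFFOptimizeMolecule(rdmol)
        except Exception:  # pragma: no cover - MMFF setup failure is rare
            AllChem.UFFOptimizeMolecule(rdmol)
    return rdmol


def molecule_from_rdkit(
    rdmol: Chem.Mol,
    mol_id: str,
    *,
    assign_charges: bool = True,
    embed_seed: int = 42,
    prepare: bool = True,
) -> Molecule:
    """Build a :class:`Molecule` from an RDKit mol.

    With ``prepare=True`` the structure is reduced to its largest
    fragment, given explicit hydrogens and (if needed) embedded in 3D
    with a seeded distance-geometry run followed by MMFF94 relaxation.
    """
    if prepare:
        rdmol = _prepare_rdmol(rdmol, mol_id, embed_seed)
    conf = rdmol.GetConformer()
    atoms: list[Atom] = []
    for a in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                mass=a.GetMass(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    mol = Molecule(id=mol_id, atoms=atoms, bonds=bonds, rdmol=rdmol)
    perceive_rings(mol)
    _perceive_donors_and_sp2_oxygen(mol)
    if assign_charges:
        assign_partial_charges(mol)
    return mol


def parse_structures(
    path: str | Path,
    format: str | None = None,
    *,
    embed_seed: int = 42,
) -> tuple[list[Molecule], list[ParseFailure]]:
    """Read molecules from an SDF/MOL/SMILES file.

    Per-record failures are collected (not raised) so one corrupt
    record does not sink a library; an input yielding zero valid
    molecules is a hard error.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower().lstrip(".")
        format = {"sdf": "sdf", "mol": "mol", "smi": "smiles", "smiles": "smiles"}.get(
            ext, "smiles"
        )
    mols: list[Molecule] = []
    failures: list[ParseFailure] = []

    def _ingest(rdmol: Chem.Mol | None, rec_id: str) -> None:
        if rdmol is None:
            failures.append(ParseFailure(rec_id, "unparsable record"))
            return
        try:
            mols.append(molecule_from_rdkit(rdmol, rec_id, embed_seed=embed_seed))
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            failures.append(ParseFailure(rec_id, str(exc)))

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, rdmol in enumerate(supplier):
            rec_id = f"record_{i}"
            if rdmol is not None and rdmol.HasProp("_Name") and rdmol.GetProp("_Name"):
                rec_id = rdmol.GetProp("_Name")
            _ingest(rdmol, rec_id)
    elif format == "mol":
        _ingest(Chem.MolFromMolFile(str(path), removeHs=False), path.stem)
    elif format == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                rec_id = parts[1] if len(parts) > 1 else f"record_{i}"
                _ingest(Chem.MolFromSmiles(smiles), rec_id)
    else:
        raise ValueError(f"unknown format {format!r}")

    for f in failures:
        log.warning("skipping %s: %s", f.record_id, f.reason)
    if not mols:
        raise StructureError(f"no valid structures in {path}")
    return mols, failures


# ---------------------------------------------------------------------------
# Graph and typing operations


def bond_distance_matrix(mol: Molecule) -> np.ndarray:
    """All-pairs shortest bond-path lengths.

    Returns an (n, n) float matrix: 0 on the diagonal, ``inf`` for
    atoms in different fragments.
    """
    n = mol.n_atoms
    if n == 0:
        raise ValueError("molecule has no atoms")
    rows, cols = [], []
    for i, j, _ in mol.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="BF", unweighted=True, directed=False)


def perceive_rings(mol: Molecule) -> Molecule:
    """Set SSSR ring membership flags on every atom (in place)."""
    if mol.rdmol is not None:
        ring_info = mol.rdmol.GetRingInfo()
        in_ring = {i for ring in ring_info.AtomRings() for i in ring}
    else:
        # toolkit-free fallback: an atom is in a ring iff it lies on a cycle
        in_ring = _cycle_atoms(mol)
    for atom in mol.atoms:
        atom.is_ring = atom.index in in_ring
        atom.is_ring_nitrogen = atom.is_ring and atom.element == "N"
        atom.is_ring_carbon = atom.is_ring and atom.element == "C"
    return mol


def _cycle_atoms(mol: Molecule) -> set[int]:
    """Atoms on at least one cycle, via repeated leaf pruning."""
    deg = [0] * mol.n_atoms
    nbrs: list[set[int]] = [set() for _ in range(mol.n_atoms)]
    for i, j, _ in mol.bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)
    for i in range(mol.n_atoms):
        deg[i] = len(nbrs[i])
    leaves = [i for i in range(mol.n_atoms) if deg[i] <= 1]
    alive = set(range(mol.n_atoms))
    while leaves:
        leaf = leaves.pop()
        if leaf not in alive:
            continue
        alive.discard(leaf)
        for nb in nbrs[leaf]:
            if nb in alive:
                deg[nb] -= 1
                if deg[nb] <= 1:
                    leaves.append(nb)
    return alive


def _perceive_donors_and_sp2_oxygen(mol: Molecule) -> None:
    """Flag hydrogen-bond donors (N/O with >=1 H) and sp2 oxygens
    (oxygen in a double bond)."""
    h_neighbours: dict[int, int] = {a.index: 0 for a in mol.atoms}
    for i, j, order in mol.bonds:
        if mol.atoms[j].element == "H":
            h_neighbours[i] += 1
        if mol.atoms[i].element == "H":
            h_neighbours[j] += 1
    double_bonded_o: set[int] = set()
    for i, j, order in mol.bonds:
        if order == 2.0:
            if mol.atoms[i].element == "O":
                double_bonded_o.add(i)
            if mol.atoms[j].element == "O":
                double_bonded_o.add(j)
    for atom in mol.atoms:
        atom.is_donor = atom.element in ("N", "O") and h_neighbours[atom.index] >= 1
        atom.is_sp2_oxygen = atom.index in double_bonded_o


def assign_partial_charges(mol: Molecule, model: str = "gasteiger") -> Molecule:
    """Assign Gasteiger-Marsili partial charges (in place).

    Also refreshes the lipophilic-hydrogen flags, defined as hydrogens
    with |q| <= 0.200.
    """
    if model != "gasteiger":
        raise ValueError(f"unknown charge model {model!r}")
    if mol.rdmol is None:
        raise StructureError(
            f"molecule {mol.id}: charge assignment needs a toolkit-backed structure"
        )
    rdPartialCharges.ComputeGasteigerCharges(mol.rdmol, throwOnParamFailure=False)
    for atom, rdatom in zip(mol.atoms, mol.rdmol.GetAtoms()):
        q = rdatom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            raise StructureError(
                f"molecule {mol.id}: no charge parameters for element "
                f"{rdatom.GetSymbol()}"
            )
        atom.partial_charge = q
        atom.is_lipophilic_hydrogen = (
            atom.element == "H" and abs(q) <= LIPOPHILIC_H_CHARGE_CUTOFF
        )
    return mol


def center_of_mass(mol: Molecule) -> np.ndarray:
    """Mass-weighted mean position over all atoms, hydrogens included."""
    m = mol.masses
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# Surface areas


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1.0 - (2 * i + 1.0) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_area(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_points: int = 960,
) -> float:
    """Total exposed area (Å²) of the union of probe-inflated spheres.

    A test point on atom i is buried when strictly inside a
    neighbouring sphere; points exactly on a coincident neighbour's
    surface are assigned to the lower-indexed atom so that perfectly
    overlapping spheres contribute one surface, not two.
    """
    coords = np.asarray(coords, dtype=float)
    big_r = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    pts = _sphere_points(n_points)
    total = 0.0
    for i in range(n):
        ri = big_r[i]
        if ri <= 0:
            continue
        surface = coords[i] + ri * pts
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.nonzero((d < ri + big_r + 1e-9) & (np.arange(n) != i))[0]
        exposed = np.ones(n_points, dtype=bool)
        for j in nb:
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            r2 = big_r[j] ** 2
            tol = 1e-9 * max(r2, 1.0)
            buried = d2 < r2 - tol
            if j < i:
                buried |= d2 <= r2 + tol
            exposed &= ~buried
        total += 4.0 * np.pi * ri * ri * exposed.mean()
    return float(total)


def surface_areas(
    mol: Molecule, params: SurfaceParams | None = None
) -> tuple[float, float]:
    """(MSA, SASA) in Å²: van der Waals surface (probe 0) and
    solvent-accessible surface at the configured probe radius."""
    params = params or SurfaceParams()
    radii = []
    for el in mol.elements:
        if el not in params.radii:
            raise StructureError(
                f"molecule {mol.id}: no van der Waals radius for element {el}"
            )
        radii.append(params.radii[el])
    radii_arr = np.array(radii)
    coords = mol.coords
    msa = shrake_rupley_area(coords, radii_arr, 0.0, params.sample_points_per_atom)
    sasa = shrake_rupley_area(
        coords, radii_arr, params.probe_radius, params.sample_points_per_atom
    )
    return msa, sasa


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write toolkit-backed molecules to an SD file."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            if mol.rdmol is None:
                raise StructureError(f"molecule {mol.id} has no toolkit structure")
            rd = Chem.Mol(mol.rdmol)
            rd.SetProp("_Name", mol.id)
            writer.write(rd)
    finally:
        writer.close()
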