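"""Molecular data model, XYZ/SMILES I/O, flexibility counting, and
synthetic-ensemble fixtures.

The containers here are deliberately small and explicit: a :class:`Molecule`
is an ordered atom list plus a bond graph and a formal charge; a
:class:`Conformer` is one geometry of that molecule; an :class:`Ensemble` is
an ordered conformer collection tagged with the charge-model rank it belongs
to. All coordinates are in Å and all energies in kcal/mol.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from ._elements import (
    ELEMENT_SYMBOLS,
    covalent_radius,
    vdw_radius,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "Conformer",
    "Ensemble",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "parse_smiles",
    "rotatable_bonds",
    "rotatable_bond_count",
    "clash_energy",
    "synth_ensemble",
]


class XYZParseError(ValueError):
    """Raised when an XYZ file violates the 2-header-line dialect."""


@dataclass
class Atom:
    """One atom: a chemical symbol and a Cartesian position in Å."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_SYMBOLS:
            raise ValueError(f"unknown element symbol: {self.element!r}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.element}")


@dataclass
class Molecule:
    """An ordered atom list with a bond graph and a formal charge.

    Bonds are stored as ``(i, j, order)`` with ``i < j``. Only neutral
    molecules and singly charged adducts are in scope, so ``formal_charge``
    is restricted to {-1, 0, +1}.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    formal_charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        if self.formal_charge not in (-1, 0, 1):
            raise ValueError(
                f"formal_charge must be -1, 0, or +1, got {self.formal_charge}"
            )
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int, int]] = []
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                raise ValueError(f"duplicate bond ({a},{b})")
            seen.add((a, b))
            norm.append((a, b, int(order)))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds)
        return g

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return sorted(out)

    def hydrogen_neighbors(self, idx: int) -> list[int]:
        return [k for k in self.neighbors(idx) if self.atoms[k].element == "H"]

    def heavy_neighbors(self, idx: int) -> list[int]:
        return [k for k in self.neighbors(idx) if self.atoms[k].element != "H"]

    def copy(self) -> "Molecule":
        return copy.deepcopy(self)

    def to_conformer(self, conf_id: str = "conf_0", energy: float | None = None) -> "Conformer":
        return Conformer(conf_id=conf_id, coords=self.coords, energy=energy)


@dataclass
class Conformer:
    """One geometry (N×3, Å) with optional energy and predicted CCS."""

    conf_id: str
    coords: np.ndarray
    energy: float | None = None
    ccs_pred: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 1:
            raise ValueError(f"coords must be N×3 with N >= 1, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("energy must be finite when present")
        if self.ccs_pred is not None:
            if not np.isfinite(self.ccs_pred) or self.ccs_pred <= 0:
                raise ValueError("ccs_pred must be finite and positive when present")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class Ensemble:
    """Ordered conformer collection sharing one atom ordering.

    ``rank_label`` is the charge-model rank *n* the ensemble belongs to
    (the *n* in the ``opt_Rank[n]`` output folders).
    """

    molecule: Molecule
    conformers: list[Conformer] = field(default_factory=list)
    rank_label: int = 1

    def __post_init__(self) -> None:
        n = self.molecule.n_atoms
        ids = set()
        for c in self.conformers:
            if c.n_atoms != n:
                raise ValueError(
                    f"conformer {c.conf_id} has {c.n_atoms} atoms, molecule has {n}"
                )
            if c.conf_id in ids:
                raise ValueError(f"duplicate conf_id {c.conf_id!r}")
            ids.add(c.conf_id)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    @property
    def energies(self) -> list[float | None]:
        return [c.energy for c in self.conformers]


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path: str | Path, name: str | None = None, perceive_bonds: bool = True) -> Molecule:
    """Read a strict 2-header-line XYZ file into a Molecule.

    The first line must parse as a positive atom count; the second line is
    kept verbatim as ``Molecule.comment``. Trailing columns after x/y/z are
    ignored. Bonds, absent from XYZ, are optionally perceived from the
    geometry with a covalent-radius cutoff so that graph operations
    (titratable-site enumeration, rotatable-bond counting) work on XYZ input.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file (line 1)")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1: atom count not an integer: {lines[0]!r}")
    if count <= 0:
        raise XYZParseError(f"{path}: line 1: atom count must be positive, got {count}")
    if len(lines) < count + 2:
        raise XYZParseError(
            f"{path}: line {len(lines) + 1}: expected {count} atom lines, found {len(lines) - 2}"
        )
    comment = lines[1] if len(lines) > 1 else ""
    atoms: list[Atom] = []
    for k in range(count):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected 'El x y z', got {lines[k + 2]!r}")
        el = parts[0]
        if el not in ELEMENT_SYMBOLS:
            raise XYZParseError(f"{path}: line {lineno}: unknown element symbol {el!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: line {lineno}: non-numeric coordinate in {lines[k + 2]!r}")
        atoms.append(Atom(el, np.array(xyz)))
    if name is None:
        # the writer puts the molecule name first on the comment line;
        # fall back to the file stem for foreign XYZ files
        tokens = comment.split()
        name = tokens[0] if tokens and "=" not in tokens[0] else path.stem
    mol = Molecule(name=name, atoms=atoms, comment=comment)
    if perceive_bonds:
        mol.bonds = _perceive_bonds(mol)
    return mol


def _perceive_bonds(mol: Molecule, tolerance: float = 0.45) -> list[tuple[int, int, int]]:
    """Distance-based bond perception: bonded if d < r_cov,i + r_cov,j + tol.

    All perceived bonds get order 1; order matters only for rotatable-bond
    counting, where a geometry-only input cannot distinguish bond orders
    anyway (a documented limitation of XYZ input).
    """
    coords = mol.coords
    radii = np.array([covalent_radius(e) for e in mol.elements])
    bonds = []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if 0.3 < d < radii[i] + radii[j] + tolerance:
                bonds.append((i, j, 1))
    return bonds


def write_xyz(molecule: Molecule, path: str | Path, conformer: Conformer | None = None) -> Path:
    """Write one geometry as standard XYZ with fixed 6-decimal coordinates.

    The comment line carries ``<name> rank=<n> energy=<E>`` metadata when
    available so downstream stages can round-trip energies through files.
    """
    path = Path(path)
    coords = conformer.coords if conformer is not None else molecule.coords
    if molecule.n_atoms == 0:
        raise ValueError("cannot write a molecule with 0 atoms")
    if coords.shape[0] != molecule.n_atoms:
        raise ValueError("conformer atom count does not match molecule")
    parts = [molecule.name]
    if conformer is not None and conformer.energy is not None:
        parts.append(f"energy={conformer.energy:.6f}")
    comment = " ".join(parts)
    rows = [f"{molecule.n_atoms}", comment]
    for el, (x, y, z) in zip(molecule.elements, coords):
        rows.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# SMILES input


def parse_smiles(smiles: str, name: str | None = None, seed: int = 2024) -> Molecule:
    """Parse a neutral SMILES, add explicit hydrogens, and embed one 3-D
    geometry with a deterministic distance-geometry seed.

    Net-charged SMILES are rejected: the pipeline builds its own singly
    charged adducts from a neutral input.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if Chem.GetFormalCharge(rdmol) != 0:
        raise ValueError(
            f"SMILES {smiles!r} carries a net charge; the input must be the neutral molecule "
            "(charged adducts are constructed internally)"
        )
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31 - 1)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        # retry with random coords for pathological inputs; still seeded
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise ValueError(f"3-D embedding failed for SMILES {smiles!r}")
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    conf = rdmol.GetConformer()
    atoms = [
        Atom(a.GetSymbol(), np.array(conf.GetAtomPosition(a.GetIdx())))
        for a in rdmol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(round(b.GetBondTypeAsDouble())))
        for b in rdmol.GetBonds()
    ]
    return Molecule(name=name or smiles, atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# Flexibility


def rotatable_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Acyclic single bonds between two non-terminal heavy atoms.

    Each endpoint must have at least one heavy neighbor besides the other
    endpoint; bonds to hydrogen are never rotatable. Amide C–N bonds are
    counted (the simplest consistent rule; see the methods note).
    """
    g = mol.graph()
    ring_edges: set[tuple[int, int]] = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add((min(a, b), max(a, b)))
    out = []
    for i, j, order in mol.bonds:
        if order != 1 or (i, j) in ring_edges:
            continue
        if mol.atoms[i].element == "H" or mol.atoms[j].element == "H":
            continue
        hi = [k for k in mol.heavy_neighbors(i) if k != j]
        hj = [k for k in mol.heavy_neighbors(j) if k != i]
        if hi and hj:
            out.append((i, j))
    return out


def rotatable_bond_count(mol: Molecule) -> int:
    """ROT, the flexibility count that scales the normal-walk step number."""
    return len(rotatable_bonds(mol))


# ---------------------------------------------------------------------------
# Clash-score energy

CLASH_FORCE_CONSTANT = 100.0  # kcal mol^-1 Å^-2
CLASH_CONTACT_SCALE = 0.8


def clash_energy(mol: Molecule, coords: np.ndarray | None = None) -> float:
    """Purely repulsive steric-clash score in kcal/mol.

    E = Σ over nonbonded pairs of k · max(0, 0.8·(r_vdw,i + r_vdw,j) − d)²,
    k = 100 kcal mol⁻¹ Å⁻². Pairs separated by one or two bonds (1-2 and 1-3)
    are excluded — their short distances are bonded structure, not clashes.
    Zero for any geometry with all nonbonded contacts open; grows
    quadratically as atoms interpenetrate. This is the package's built-in
    deterministic energy model; quantum or ML energies plug in through the
    scorer and generator contracts.
    """
    if coords is None:
        coords = mol.coords
    coords = np.asarray(coords, dtype=float)
    n = mol.n_atoms
    if coords.shape != (n, 3):
        raise ValueError(f"coords shape {coords.shape} does not match {n} atoms")
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _ in mol.bonds:
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    for i in range(n):
        for j in adj[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    radii = np.array([vdw_radius(e) for e in mol.elements])
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            overlap = CLASH_CONTACT_SCALE * (radii[i] + radii[j]) - d
            if overlap > 0:
                energy += CLASH_FORCE_CONSTANT * overlap * overlap
    return energy


# ---------------------------------------------------------------------------
# Synthetic fixtures


def synth_ensemble(
    molecule: Molecule,
    base: Conformer | None = None,
    n: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
    rank_label: int = 1,
) -> Ensemble:
    """Seeded synthetic ensemble: Gaussian coordinate noise plus a random
    rigid rotation/translation per member, energies from the clash score.

    Intended as a test fixture and benchmark input — it emulates an ensemble
    of near-degenerate conformers scattered around one basin, not genuine
    torsional diversity.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if base is None:
        base = molecule.to_conformer()
    rng = np.random.default_rng(seed)
    conformers = []
    for i in range(n):
        coords = base.coords.copy()
        if noise_sd > 0:
            coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        rot = _random_rotation(rng)
        shift = rng.normal(0.0, 2.0, size=3)
        center = coords.mean(axis=0)
        coords = (coords - center) @ rot.T + center + shift
        conformers.append(
            Conformer(conf_id=f"synth_{i}", coords=coords, energy=clash_energy(molecule, coords))
        )
    return Ensemble(molecule=molecule, conformers=conformers, rank_label=rank_label)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
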