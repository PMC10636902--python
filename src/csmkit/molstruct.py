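"""Molecule data model, file I/O, bond perception and graph equivalence classes.

A :class:`Molecule` is a plain container: element symbols, Cartesian
coordinates in angstrom, and an undirected bond graph stored as a frozenset
of sorted index pairs.  Connectivity is read from the file when the format
carries it (SDF bond block, PDB ``CONECT`` records) and can otherwise be
perceived from covalent radii with :func:`infer_bonds`.

Equivalence classes — maximal sets of atoms interchangeable by element and
graph environment — are computed by iterative neighbour-colour refinement
(:func:`equivalence_classes`) and drive every permutation search in the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "EquivalencePartition",
    "MoleculeParseError",
    "read_molecule",
    "write_xyz",
    "infer_bonds",
    "select_atoms",
    "equivalence_classes",
    "geometric_center",
    "normalization_factor",
    "bond_preservation",
    "COVALENT_RADII",
]

# Single-bond covalent radii in angstrom (Cordero et al. consensus values).
# Fixed internal table; versioned with the package.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Ce": 2.04, "W": 1.62, "Re": 1.51,
    "Os": 1.44, "Ir": 1.41, "Pt": 1.36, "Au": 1.36, "Hg": 1.32, "Tl": 1.45,
    "Pb": 1.46, "Bi": 1.48, "U": 1.96,
}

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)


class MoleculeParseError(ValueError):
    """Raised when a structure file cannot be parsed or validated."""


@dataclass(frozen=True)
class Molecule:
    """Elements, Cartesian coordinates (angstrom) and an undirected bond graph.

    Atom indices are 0-based throughout the library; human-readable reports
    shift to 1-based.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    bonds: frozenset[tuple[int, int]] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        elements = tuple(self.elements)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        n = len(elements)
        if n < 1 or coords.shape[0] != n:
            raise ValueError("need at least one atom and matching coords")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for el in elements:
            if el not in _ELEMENTS:
                raise MoleculeParseError(f"unknown element symbol: {el!r}")
        bonds = frozenset(
            (min(i, j), max(i, j)) for i, j in self.bonds
        )
        for i, j in bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i}, {j})")
        coords.setflags(write=False)
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "bonds", bonds)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix of the bond graph."""
        n = self.n_atoms
        adj = np.zeros((n, n), dtype=bool)
        for i, j in self.bonds:
            adj[i, j] = adj[j, i] = True
        return adj

    def centered_coords(self) -> np.ndarray:
        """Coordinates translated so the geometric center sits at the origin."""
        return self.coords - self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float),
                       name=self.name if name is None else name)


@dataclass(frozen=True)
class EquivalencePartition:
    """Per-atom class labels from neighbour-colour refinement.

    ``class_id[i] == class_id[j]`` means atoms *i* and *j* share element and
    (refined) graph environment, so a structure-preserving permutation may
    exchange them.
    """

    class_id: np.ndarray
    n_classes: int

    def members(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_classes)]
        for i, c in enumerate(self.class_id):
            out[int(c)].append(i)
        return out


# ---------------------------------------------------------------------------
# file I/O


def _parse_xyz(text: str, name: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise MoleculeParseError("empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise MoleculeParseError("XYZ line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise MoleculeParseError(
            f"XYZ: expected {n + 2} lines, found {len(lines)}")
    elements, coords = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise MoleculeParseError(f"XYZ line {ln}: expected 'El x y z'")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise MoleculeParseError(
                f"XYZ line {ln}: non-numeric coordinate") from None
        elements.append(parts[0])
        coords.append(xyz)
    label = lines[1].strip() or name
    return Molecule(tuple(elements), np.array(coords), frozenset(), label)


def _from_rdkit(rdmol, name: str) -> Molecule:
    conf = rdmol.GetConformer()
    elements = tuple(a.GetSymbol() for a in rdmol.GetAtoms())
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(rdmol.GetNumAtoms())]
    )
    bonds = frozenset(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()
    )
    return Molecule(elements, coords, bonds, name)


def read_molecule(path: str | Path, format: str = "auto") -> Molecule:
    """Read a molecule from XYZ, MOL/SDF (V2000) or PDB.

    ``format='auto'`` dispatches on the file extension.  Bonds are populated
    when the format carries them; XYZ yields an empty bond set.
    """
    from rdkit import Chem

    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        fmt = {"xyz": "xyz", "sdf": "sdf", "mol": "sdf", "pdb": "pdb"}.get(ext)
        if fmt is None:
            raise MoleculeParseError(
                f"cannot infer format from extension {path.suffix!r}")
    name = path.stem
    if fmt == "xyz":
        return _parse_xyz(path.read_text(), name)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        rdmol = next(iter(supplier), None)
        if rdmol is None:
            raise MoleculeParseError(f"unreadable SDF/MOL file: {path}")
        return _from_rdkit(rdmol, name)
    if fmt == "pdb":
        rdmol = Chem.MolFromPDBFile(
            str(path), sanitize=False, removeHs=False, proximityBonding=False)
        if rdmol is None:
            raise MoleculeParseError(f"unreadable PDB file: {path}")
        return _from_rdkit(rdmol, name)
    raise MoleculeParseError(f"unknown format {format!r}")


def write_xyz(mol: Molecule, path: str | Path, comment: str | None = None) -> None:
    """Write the molecule in plain XYZ (bonds are not representable)."""
    lines = [str(mol.n_atoms), comment if comment is not None else mol.name]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bond perception and atom selection


def infer_bonds(mol: Molecule, tolerance: float = 0.4) -> Molecule:
    """Perceive bonds from covalent radii.

    Atoms *i*, *j* are bonded iff ``|Q_i - Q_j| <= r_cov(i) + r_cov(j) +
    tolerance``.  The default 0.4 angstrom slack is the common cheminformatics
    heuristic.  Existing bonds are replaced.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    radii = []
    for el in mol.elements:
        r = COVALENT_RADII.get(el)
        if r is None:
            raise ValueError(f"no tabulated covalent radius for element {el!r}")
        radii.append(r)
    r = np.array(radii)
    d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    cut = r[:, None] + r[None, :] + tolerance
    ii, jj = np.nonzero(np.triu(d <= cut, k=1))
    return replace(mol, bonds=frozenset(zip(ii.tolist(), jj.tolist())))


def select_atoms(
    mol: Molecule,
    drop_hydrogens: bool = False,
    drop_indices: Iterable[int] = (),
) -> Molecule:
    """Induced substructure after dropping hydrogens and/or explicit indices."""
    drop = set(int(i) for i in drop_indices)
    for i in drop:
        if not (0 <= i < mol.n_atoms):
            raise IndexError(f"atom index {i} out of range")
    if drop_hydrogens:
        drop |= {i for i, el in enumerate(mol.elements) if el == "H"}
    keep = [i for i in range(mol.n_atoms) if i not in drop]
    if not keep:
        raise ValueError("atom selection would leave an empty molecule")
    remap = {old: new for new, old in enumerate(keep)}
    bonds = frozenset(
        (remap[i], remap[j]) for i, j in mol.bonds if i in remap and j in remap
    )
    return Molecule(
        tuple(mol.elements[i] for i in keep), mol.coords[keep], bonds, mol.name
    )


# ---------------------------------------------------------------------------
# graph equivalence classes


def equivalence_classes(mol: Molecule) -> EquivalencePartition:
    """Neighbour-colour refinement starting from element symbols.

    Colours are refined by the multiset of neighbour colours until a fixpoint
    (at most N rounds).  Final class ids are canonicalized by the smallest
    member index, so the output is deterministic for a given atom order.
    """
    n = mol.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    order = {el: k for k, el in enumerate(sorted(set(mol.elements)))}
    colors = [order[el] for el in mol.elements]
    for _ in range(n):
        sigs = [
            (colors[i], tuple(sorted(colors[j] for j in adj[i])))
            for i in range(n)
        ]
        relabel = {s: k for k, s in enumerate(sorted(set(sigs)))}
        new = [relabel[s] for s in sigs]
        if new == colors:
            break
        colors = new
    first_seen: dict[int, int] = {}
    canon = []
    for c in colors:
        if c not in first_seen:
            first_seen[c] = len(first_seen)
        canon.append(first_seen[c])
    return EquivalencePartition(np.array(canon, dtype=int), len(first_seen))


# ---------------------------------------------------------------------------
# geometry


def geometric_center(mol: Molecule) -> np.ndarray:
    """Unweighted arithmetic mean of the atomic coordinates."""
    return mol.coords.mean(axis=0)


def normalization_factor(mol: Molecule) -> float:
    """Sum of squared distances from the geometric center (the CSM denominator D)."""
    q = mol.centered_coords()
    d = float(np.sum(q * q))
    if d <= 1e-300:
        raise ValueError(
            "degenerate geometry: all atoms coincide, the symmetry measure "
            "is undefined")
    return d


def bond_preservation(mol: Molecule, mapping: Sequence[int]) -> float | None:
    """Percentage of bonds (i, j) whose image (pi(i), pi(j)) is also a bond.

    Returns ``None`` for a bond-free molecule, where the metric is undefined.
    """
    if not mol.bonds:
        return None
    mapping = list(mapping)
    kept = sum(
        1 for i, j in mol.bonds
        if (min(mapping[i], mapping[j]), max(mapping[i], mapping[j])) in mol.bonds
    )
    return 100.0 * kept / len(mol.bonds)
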