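"""Deterministic synthetic molecules with known symmetry properties.

Generators are pure: the same arguments always produce the bit-identical
molecule.  Perfectly symmetric fixtures (rings, prisms, the C60 cage) come
with exact point-group symmetry by construction, so every engine must report
S = 0 for the design group; seeded Gaussian distortion then produces
controlled departures from symmetry for benchmarking.
"""

from __future__ import annotations

import math

import numpy as np

from .molstruct import Molecule

__all__ = [
    "make_ring",
    "make_prism",
    "make_two_element_pair",
    "make_truncated_icosahedron",
    "make_chiral_toy",
    "distort",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0


def make_ring(n: int, radius: float = 1.4, element: str = "C") -> Molecule:
    """n identical atoms on an exact C_n ring in the z = 0 plane, ring-bonded."""
    if n < 3:
        raise ValueError("a ring needs at least 3 atoms")
    ang = 2.0 * math.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                              np.zeros(n)])
    bonds = frozenset((i, (i + 1) % n) for i in range(n))
    return Molecule((element,) * n, coords, bonds, f"ring{n}")


def make_prism(n: int, radius: float = 1.4, height: float = 1.5,
               element: str = "C") -> Molecule:
    """Two stacked C_n rings joined by vertical bonds (an n-gonal prism)."""
    ring = make_ring(n, radius, element)
    top = ring.coords + np.array([0.0, 0.0, height / 2.0])
    bot = ring.coords - np.array([0.0, 0.0, height / 2.0])
    coords = np.vstack([top, bot])
    bonds = set()
    for i in range(n):
        bonds.add((i, (i + 1) % n))
        bonds.add((n + i, n + (i + 1) % n))
        bonds.add((i, n + i))
    return Molecule((element,) * (2 * n), coords, frozenset(bonds),
                    f"prism{n}")


def make_two_element_pair(separation: float = 1.0,
                          elements: tuple[str, str] = ("H", "F")) -> Molecule:
    """Two distinct atoms on the z axis; mirror-symmetric (C_s) but not C_i."""
    coords = np.array([[0.0, 0.0, separation / 2.0],
                       [0.0, 0.0, -separation / 2.0]])
    return Molecule(elements, coords, frozenset({(0, 1)}), "pair")


def make_truncated_icosahedron() -> Molecule:
    """The C60 cage: 60 carbons on truncated-icosahedron vertices, 90 bonds.

    Vertices are the cyclic permutations of (0, +-1, +-3 phi),
    (+-1, +-(2 + phi), +-2 phi) and (+-2, +-(1 + 2 phi), +-phi) with phi the
    golden ratio, scaled to a 1.4 angstrom edge.  The bond graph is the
    3-regular polyhedron skeleton, a vertex-transitive graph (one equivalence
    class).
    """
    base = []
    for (a, b, c) in [(0.0, 1.0, 3.0 * _PHI),
                      (1.0, 2.0 + _PHI, 2.0 * _PHI),
                      (2.0, 1.0 + 2.0 * _PHI, _PHI)]:
        for sa in ((1.0,) if a == 0.0 else (1.0, -1.0)):
            for sb in (1.0, -1.0):
                for sc in (1.0, -1.0):
                    v = (sa * a, sb * b, sc * c)
                    base.append(v)
                    base.append((v[1], v[2], v[0]))
                    base.append((v[2], v[0], v[1]))
    coords = np.array(sorted(set(base)))
    assert coords.shape == (60, 3)
    scale = 1.4 / 2.0  # canonical edge length is 2
    coords = coords * scale
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    edge = d[d > 1e-9].min()
    ii, jj = np.nonzero(np.triu(d < edge * 1.05, k=1))
    bonds = frozenset(zip(ii.tolist(), jj.tolist()))
    assert len(bonds) == 90
    return Molecule(("C",) * 60, coords, bonds, "C60")


def make_chiral_toy(seed: int = 0) -> Molecule:
    """A 4-atom, 4-element non-planar structure with no improper symmetry.

    Four distinct elements force the identity as the only structure-
    preserving permutation, so the chirality measure reduces to the distance
    from planarity and is strictly positive for this geometry.
    """
    rng = np.random.default_rng(seed)
    base = np.array([
        [0.10, 0.05, 0.60],
        [0.95, 0.20, -0.35],
        [-0.55, 0.90, -0.30],
        [-0.50, -0.85, -0.40],
    ])
    coords = base + rng.normal(scale=0.05, size=base.shape)
    bonds = frozenset({(0, 1), (0, 2), (0, 3)})
    return Molecule(("C", "H", "N", "O"), coords, bonds, "chiral-toy")


def distort(mol: Molecule, sigma: float, seed: int) -> Molecule:
    """Add independent zero-mean Gaussian noise (std sigma, angstrom) per
    coordinate; bonds unchanged, fully determined by the seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = mol.coords + rng.normal(scale=sigma, size=mol.coords.shape) \
        if sigma > 0 else mol.coords
    return mol.with_coords(coords, name=f"{mol.name} (sigma={sigma:g})")
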