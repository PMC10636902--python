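"""Shared fixtures: small seeded molecules with known symmetry content."""

from __future__ import annotations

import numpy as np
import pytest

from csmkit.molstruct import Molecule
from csmkit import synthgen


@pytest.fixture
def ring5():
    return synthgen.make_ring(5)


@pytest.fixture
def ring6():
    return synthgen.make_ring(6)


@pytest.fixture
def c60():
    return synthgen.make_truncated_icosahedron()


def random_small_molecule(seed: int, n: int = 6) -> Molecule:
    """A seeded distorted ring with mixed elements (bonds along the ring)."""
    rng = np.random.default_rng(seed)
    base = synthgen.make_ring(n, radius=1.4)
    elements = tuple(["C", "N"][i % 2] if n % 2 == 0 else "C"
                     for i in range(n))
    coords = base.coords + rng.normal(scale=0.08, size=base.coords.shape)
    return Molecule(elements, coords, base.bonds, f"rand{seed}")


def mirror_fixture(seed: int, pairs: int = 3, sigma: float = 0.05) -> Molecule:
    """A distorted mirror-symmetric molecule: ``pairs`` atoms above z = 0,
    their reflections below, partner bonds plus a chain on each side."""
    rng = np.random.default_rng(seed)
    top = np.column_stack([
        rng.uniform(-1.5, 1.5, pairs),
        rng.uniform(-1.5, 1.5, pairs),
        rng.uniform(0.6, 1.6, pairs),
    ])
    coords = np.vstack([top, top * np.array([1.0, 1.0, -1.0])])
    elements = tuple(rng.choice(["C", "N", "O"], size=pairs).tolist()) * 2
    bonds = {(i, pairs + i) for i in range(pairs)}
    for i in range(pairs - 1):
        bonds.add((i, i + 1))
        bonds.add((pairs + i, pairs + i + 1))
    mol = Molecule(elements, coords, frozenset(bonds), f"mirror{seed}")
    return synthgen.distort(mol, sigma, seed + 1000)


_FRUCHT_LCF = [-5, -2, -4, 2, 5, -2, 2, 5, -2, -5, 4, 2]


def asymmetric_cage(seed: int) -> Molecule:
    """A 12-carbon cage on the Frucht graph (cubic, trivial automorphism
    group) with a seeded random geometry.

    All atoms share one equivalence class (colour refinement cannot split a
    uniform cubic graph), yet the only structure-preserving permutation is
    the identity -- the desk-scale analogue of a topologically asymmetric
    fullerene cage.
    """
    bonds = {(i, (i + 1) % 12) for i in range(12)}
    for i, jump in enumerate(_FRUCHT_LCF):
        j = (i + jump) % 12
        bonds.add((min(i, j), max(i, j)))
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=1.5, size=(12, 3))
    return Molecule(("C",) * 12, coords, frozenset(bonds), f"cage{seed}")
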