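"""Point-group operations and the continuous symmetry measure (CSM) objective.

The CSM of a molecule with respect to a cyclic point group G generated by an
operation T (a proper or improper rotation by 360/n degrees about an axis) is

    S(G) = 100 * M(G) / D,

where M(G) is the minimal summed squared displacement between the molecule
and any T-invariant structure, and D is the summed squared distance of the
atoms from their geometric center.  For a fixed atom permutation pi and
operation T the minimizing T-invariant structure is the orbit average

    P_k = (1/g) * sum_{i=0..g-1} T^{-i} Q_{pi^i(k)},

with g the order of the group, and M equals the cycle-averaged objective

    M = (1/2g) * sum_{i=1..g} sum_k |T^i Q_k - Q_{pi^i(k)}|^2.

Approximate engines work with the single-operation surrogate (``mode='single'``
in :func:`symmetry_objective`) that keeps only the i=1 term.  It is normalized
so that it coincides with the full objective whenever the group has order two
and the permutation is an involution, which keeps lower/upper bounds directly
comparable with the reported measure.

This module also provides the analytic optimal-axis solve for a fixed
permutation, the Fibonacci sphere lattice of start directions, and the
educated initial guesses built from equivalence-class centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .molstruct import EquivalencePartition, Molecule

__all__ = [
    "PointGroupSpec",
    "SymmetryOperation",
    "Permutation",
    "DirectionSet",
    "CSMResult",
    "parse_group",
    "operation_matrix",
    "symmetry_objective",
    "csm_value",
    "nearest_symmetric_structure",
    "optimal_axis",
    "fibonacci_lattice",
    "initial_direction_guesses",
]


@dataclass(frozen=True)
class PointGroupSpec:
    """A cyclic point group: C_n (proper) or S_n (improper).

    S_1 is the reflection group C_s and S_2 the inversion group C_i.  For
    improper groups n must be 1 or even: an odd S_n (n > 1) generates a group
    containing a pure rotation of odd order and is not closed as written.
    """

    family: str  # "C" or "S"
    n: int

    def __post_init__(self) -> None:
        if self.family not in ("C", "S"):
            raise ValueError(f"family must be 'C' or 'S', got {self.family!r}")
        if self.family == "C" and self.n < 2:
            raise ValueError("proper groups require n >= 2")
        if self.family == "S" and not (self.n == 1 or (self.n >= 2 and self.n % 2 == 0)):
            raise ValueError("improper groups require n = 1 or even n >= 2")

    @property
    def proper(self) -> bool:
        return self.family == "C"

    @property
    def group_order(self) -> int:
        """Order g of the generated cyclic group (S_1 has order 2)."""
        if self.family == "S" and self.n == 1:
            return 2
        return self.n

    @property
    def angle(self) -> float:
        """Rotation angle of the generator, 2*pi/n."""
        return 2.0 * math.pi / self.n

    def __str__(self) -> str:
        if self.family == "S" and self.n == 1:
            return "Cs"
        if self.family == "S" and self.n == 2:
            return "Ci"
        return f"{self.family}{self.n}"


CS = PointGroupSpec("S", 1)
CI = PointGroupSpec("S", 2)


def parse_group(text: str) -> PointGroupSpec:
    """Parse 'c2', 'c5', 'cs', 'ci', 's4', ... into a :class:`PointGroupSpec`."""
    t = text.strip().lower()
    if t in ("cs", "sigma"):
        return CS
    if t == "ci":
        return CI
    if len(t) >= 2 and t[0] in "cs" and t[1:].isdigit():
        return PointGroupSpec(t[0].upper(), int(t[1:]))
    raise ValueError(f"cannot parse point-group request {text!r}")


@dataclass(frozen=True)
class SymmetryOperation:
    """A concrete generator: group spec, unit axis and orthogonal 3x3 matrix."""

    spec: PointGroupSpec
    axis: np.ndarray
    matrix: np.ndarray

    def power(self, i: int) -> np.ndarray:
        """T^i, built from the closed form at angle i * 2pi/n (stays orthogonal)."""
        return _op_matrix_at(self.spec, self.axis, i)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _op_matrix_at(spec: PointGroupSpec, axis: np.ndarray, i: int = 1) -> np.ndarray:
    rot = _rotation(axis, spec.angle * i)
    if spec.proper or i % 2 == 0:
        return rot
    # improper power: rotation composed with reflection through the plane
    # normal to the axis
    sigma = np.eye(3) - 2.0 * np.outer(axis, axis)
    return sigma @ rot


def operation_matrix(spec: PointGroupSpec, axis: Sequence[float]) -> SymmetryOperation:
    """Build the generator for ``spec`` about ``axis`` (normalized internally).

    Proper C_n: Rodrigues rotation by 2pi/n.  Improper S_n: the same rotation
    composed with reflection through the plane normal to the axis; S_1 is a
    pure reflection and S_2 the inversion -I.
    """
    v = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-300:
        raise ValueError("axis must be non-zero")
    v = v / norm
    return SymmetryOperation(spec, v, _op_matrix_at(spec, v, 1))


@dataclass(frozen=True)
class Permutation:
    """A bijection on {0..N-1} with its cycle-length multiset."""

    mapping: tuple[int, ...]
    cycle_lengths: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        m = tuple(int(v) for v in self.mapping)
        n = len(m)
        if sorted(m) != list(range(n)):
            raise ValueError("mapping is not a bijection on {0..N-1}")
        seen = [False] * n
        lengths = []
        for start in range(n):
            if seen[start]:
                continue
            ln, k = 0, start
            while not seen[k]:
                seen[k] = True
                k = m[k]
                ln += 1
            lengths.append(ln)
        object.__setattr__(self, "mapping", m)
        object.__setattr__(self, "cycle_lengths", tuple(sorted(lengths)))

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def array(self) -> np.ndarray:
        return np.array(self.mapping, dtype=int)

    def power(self, i: int) -> np.ndarray:
        out = np.arange(len(self.mapping))
        p = self.array
        for _ in range(i):
            out = p[out]
        return out

    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(tuple(range(n)))


@dataclass(frozen=True)
class DirectionSet:
    """A list of unit start directions with a provenance tag."""

    vectors: np.ndarray
    origin_tag: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("direction vectors must be unit norm")
        v.setflags(write=False)
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class CSMResult:
    """Outcome of a CSM computation.

    ``S`` is on the 0-100 scale.  ``M_full`` is the cycle-averaged objective
    (defined when the permutation is cycle-valid for the group); ``M_hat`` is
    the single-operation surrogate.  ``nearest`` holds the nearest symmetric
    structure in the centered frame.
    """

    S: float
    group: PointGroupSpec
    axis: np.ndarray
    permutation: Permutation
    nearest: np.ndarray
    M_hat: float
    D: float
    algorithm: str
    M_full: Optional[float] = None
    preservation: Optional[float] = None
    iterations: int = 0
    converged: bool = True
    cycle_valid: bool = True
    complete: bool = True
    trajectory: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# objectives


def csm_value(M: float, D: float) -> float:
    """S = 100 * M / D."""
    if D <= 0:
        raise ValueError("normalization factor D must be positive")
    return 100.0 * M / D


def _single_coefficient(spec: PointGroupSpec) -> float:
    # Normalized so that on involutions the surrogate equals the full
    # objective for order-2 groups (C2, Cs, Ci); 1/2 otherwise.
    return 0.25 if spec.group_order <= 2 else 0.5


def symmetry_objective(
    mol: Molecule,
    perm: Permutation,
    op: SymmetryOperation,
    mode: str = "full",
) -> float:
    """Evaluate the CSM numerator for a fixed permutation and operation.

    ``mode='full'``: (1/2g) sum_{i=1..g} sum_k |T^i Q_k - Q_{pi^i(k)}|^2.
    ``mode='single'``: the i=1 surrogate, c * sum_k |T Q_k - Q_{pi(k)}|^2 with
    c = 1/4 for groups of order two and 1/2 otherwise.

    The molecule is re-centered internally.
    """
    if len(perm) != mol.n_atoms:
        raise ValueError("permutation size does not match atom count")
    q = mol.centered_coords()
    return _objective_coords(q, perm, op, mode)


def _objective_coords(
    q: np.ndarray, perm: Permutation, op: SymmetryOperation, mode: str
) -> float:
    g = op.spec.group_order
    if mode == "single":
        diff = q @ op.matrix.T - q[perm.array]
        return _single_coefficient(op.spec) * float(np.sum(diff * diff))
    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    for i in range(1, g + 1):
        ti = op.power(i)
        diff = q @ ti.T - q[perm.power(i)]
        total += float(np.sum(diff * diff))
    return total / (2.0 * g)


def nearest_symmetric_structure(
    mol: Molecule, perm: Permutation, op: SymmetryOperation
) -> np.ndarray:
    """Orbit-average closed form of the nearest T-invariant structure.

    P_k = (1/g) sum_{i=0..g-1} T^{-i} Q_{pi^i(k)}, in the centered frame.
    For a cycle-valid permutation the result satisfies T P_k = P_{pi(k)} and
    sum |Q_k - P_k|^2 equals the full objective.  For other permutations the
    same formula is returned without the invariance guarantee.
    """
    q = mol.centered_coords()
    g = op.spec.group_order
    acc = np.zeros_like(q)
    for i in range(g):
        ti_inv = op.power(i).T  # orthogonal: inverse = transpose
        acc += q[perm.power(i)] @ ti_inv.T
    return acc / g


# ---------------------------------------------------------------------------
# optimal axis


def _quadratic_terms(
    q: np.ndarray, perm: Permutation, spec: PointGroupSpec, objective: str
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (C, b) so the axis-dependent part of -M is m^T C m + b . m.

    For a rotation by angle a about unit axis m the cross term
    sum_k P_k . T Q_k expands as  cos(a) * const + sin(a) * m.B +
    (1 -/+ cos a) * m^T C0 m  with B = sum Q_k x P_k and C0 the symmetric
    part of sum Q_k P_k^T (sign '-' proper, '+' improper).  Maximizing the
    assembled quadratic over the unit sphere minimizes the objective.
    """
    g = spec.group_order
    powers = [1] if objective == "single" else list(range(1, g))
    C = np.zeros((3, 3))
    b = np.zeros(3)
    for i in powers:
        a = spec.angle * i
        improper_i = (not spec.proper) and (i % 2 == 1)
        p = q[perm.power(i)]
        c1 = -(1.0 + math.cos(a)) if improper_i else (1.0 - math.cos(a))
        if abs(c1) > 1e-15:
            c0 = 0.5 * (q.T @ p + p.T @ q)
            C += c1 * c0
        s = math.sin(a)
        if abs(s) > 1e-15:
            b += s * np.cross(q, p).sum(axis=0)
    return C, b


def _argmax_on_sphere(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Maximize m^T C m + b . m over unit vectors m.

    Analytic stationary-point solve via the secular equation in the
    eigenbasis of C, with the hard (degenerate) case handled and a guarded
    numeric polish on every candidate.
    """
    w, v = np.linalg.eigh(C)
    beta = v.T @ b
    scale = max(np.max(np.abs(w)), np.linalg.norm(b), 1e-30)
    candidates = [v[:, 2], -v[:, 2], v[:, 0], -v[:, 0], v[:, 1], -v[:, 1]]
    if np.linalg.norm(b) > 1e-13 * scale:
        candidates.append(b / np.linalg.norm(b))

        def norm2(lam: float) -> float:
            return float(np.sum((beta / (2.0 * (lam - w))) ** 2))

        wmax = w[-1]
        lo = wmax + 1e-12 * scale
        try:
            if norm2(lo) >= 1.0:
                hi = wmax + scale
                while norm2(hi) > 1.0:
                    hi *= 2.0
                    if hi > wmax + 1e12 * scale:
                        break
                lam = brentq(lambda t: norm2(t) - 1.0, lo, hi, xtol=1e-14 * scale)
                m = v @ (beta / (2.0 * (lam - w)))
                candidates.append(m / np.linalg.norm(m))
            else:
                # hard case: b nearly orthogonal to the top eigenspace
                mperp = np.where(np.abs(w - wmax) > 1e-12 * scale,
                                 beta / (2.0 * (wmax - w + 1e-300)), 0.0)
                r2 = float(np.sum(mperp ** 2))
                if r2 < 1.0:
                    t = math.sqrt(1.0 - r2)
                    for sign in (1.0, -1.0):
                        comp = mperp.copy()
                        comp[2] += sign * t / 1.0
                        m = v @ comp
                        nm = np.linalg.norm(m)
                        if nm > 0:
                            candidates.append(m / nm)
        except ValueError:
            pass

    def value(m: np.ndarray) -> float:
        return float(m @ C @ m + b @ m)

    def neg(x: np.ndarray) -> float:
        nx = np.linalg.norm(x)
        if nx < 1e-12:
            return 0.0
        m = x / nx
        return -value(m)

    best, best_val = None, -np.inf
    for m0 in candidates:
        res = minimize(neg, m0, method="BFGS",
                       options={"gtol": 1e-14 * scale, "maxiter": 200})
        m = res.x / np.linalg.norm(res.x)
        val = value(m)
        if val > best_val:
            best, best_val = m, val
    return best


def canonical_axis(axis: np.ndarray) -> np.ndarray:
    """Flip sign so the first component larger than 1e-8 in magnitude is positive."""
    for comp in axis:
        if abs(comp) > 1e-8:
            return axis if comp > 0 else -axis
    return axis


def optimal_axis(
    mol: Molecule,
    perm: Permutation,
    spec: PointGroupSpec,
    objective: str = "single",
) -> np.ndarray:
    """Axis minimizing the symmetry objective at a fixed permutation.

    ``objective='single'`` minimizes the one-operation surrogate (the step
    used inside permutation-direction iterations); ``objective='full'``
    minimizes the cycle-averaged objective.  The inversion group has no axis
    and returns the (0, 0, 1) convention.
    """
    if spec == CI:
        return np.array([0.0, 0.0, 1.0])
    q = mol.centered_coords()
    if float(np.sum(q * q)) <= 1e-300:
        raise ValueError("degenerate geometry: no axis is defined")
    C, b = _quadratic_terms(q, perm, spec, objective)
    return canonical_axis(_argmax_on_sphere(C, b))


# ---------------------------------------------------------------------------
# start directions


def fibonacci_lattice(M: int) -> DirectionSet:
    """The Fibonacci lattice of M near-uniform unit vectors.

    u_k = (x, r cos t, r sin t) with t = pi (sqrt5 + 1) k, x = 1 - 2k/(M-1),
    r = sqrt(1 - x^2), for k = 0..M-1.
    """
    if M < 2:
        raise ValueError("lattice size must be at least 2")
    k = np.arange(M, dtype=float)
    theta = math.pi * (math.sqrt(5.0) + 1.0) * k
    x = 1.0 - 2.0 * k / (M - 1)
    r = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    vecs = np.column_stack([x, r * np.cos(theta), r * np.sin(theta)])
    vecs /= np.linalg.norm(vecs, axis=1)[:, None]
    return DirectionSet(vecs, "fibonacci")


def _fit_directions(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit line direction and plane normal of a point cloud (SVD)."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[0], vt[2]


def _drop_outliers(points: np.ndarray, kind: str) -> np.ndarray:
    """Iteratively drop the centroid with the largest fit residual.

    A point is dropped while its residual exceeds twice the median residual,
    capped at 20% of the centroids.
    """
    pts = points.copy()
    max_drop = int(0.2 * len(points))
    for _ in range(max_drop):
        if len(pts) < 4:
            break
        line, normal = _fit_directions(pts)
        c = pts - pts.mean(axis=0)
        if kind == "line":
            res = np.linalg.norm(c - np.outer(c @ line, line), axis=1)
        else:
            res = np.abs(c @ normal)
        med = np.median(res)
        worst = int(np.argmax(res))
        if med <= 0 or res[worst] <= 2.0 * med:
            break
        pts = np.delete(pts, worst, axis=0)
    return pts


def _perpendicular_pair(v: np.ndarray) -> list[np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u1 = np.cross(v, helper)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(v, u1)
    return [u1, u2 / np.linalg.norm(u2)]


def initial_direction_guesses(
    mol: Molecule, partition: EquivalencePartition
) -> DirectionSet:
    """Educated start directions from equivalence-class centroids.

    Fits the best line and best plane through the class centroids (after
    outlier removal) and emits the line direction, the plane normal, and two
    perpendicular complements of each, deduplicated up to sign.  With fewer
    than two distinct centroids the coordinate axes are returned.
    """
    q = mol.centered_coords()
    cents = np.array([q[idx].mean(axis=0) for idx in partition.members()])
    distinct = np.unique(np.round(cents, 8), axis=0)
    out: list[np.ndarray] = []
    if len(distinct) < 2:
        out = [np.eye(3)[i] for i in range(3)]
    else:
        for kind in ("line", "plane"):
            pts = _drop_outliers(cents, kind)
            line, normal = _fit_directions(pts)
            primary = line if kind == "line" else normal
            nrm = np.linalg.norm(primary)
            if nrm < 1e-12:
                continue
            primary = primary / nrm
            out.append(primary)
            out.extend(_perpendicular_pair(primary))
    dedup: list[np.ndarray] = []
    for vec in out:
        vec = canonical_axis(vec)
        if not any(np.linalg.norm(vec - u) < 1e-8 for u in dedup):
            dedup.append(vec)
    return DirectionSet(np.array(dedup), "educated_guess")
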