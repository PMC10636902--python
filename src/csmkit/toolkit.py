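"""User-facing dispatch, chirality measure, diagnostics and result records.

``compute_csm`` selects an engine following the package guidelines: exact
enumeration whenever the structure-preserving permutation space is small
enough to scan, the Hungarian iteration otherwise.  ``compute_ccm`` returns
the continuous chirality measure, the minimum CSM over achiral groups
(default C_s and C_i; extensible to S4, S6, ...).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import approx_search, exact_search
from .molstruct import Molecule, bond_preservation, equivalence_classes, \
    infer_bonds, select_atoms, write_xyz
from .symcore import CI, CS, CSMResult, Permutation, PointGroupSpec, parse_group

__all__ = [
    "RunConfig",
    "prepare_molecule",
    "compute_csm",
    "compute_ccm",
    "preservation_percentage",
    "result_record",
    "write_result",
]

logger = logging.getLogger("csmkit")

# auto-dispatch: exact is attempted below this atom count, and adopted when
# the enumeration finishes inside the node cap
_EXACT_ATOM_LIMIT = 300
_EXACT_NODE_CAP = 1_000_000


@dataclasses.dataclass
class RunConfig:
    """Knobs shared by the CLI and the library entry points."""

    group: str = "chirality"
    algorithm: str = "auto"  # auto | exact | greedy | hungarian | sp | fibonacci
    n_dirs: int = 100
    time_limit: float = 300.0
    drop_hydrogens: bool = False
    bond_tolerance: float = 0.4
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.n_dirs < 1 or self.time_limit <= 0 or self.bond_tolerance < 0:
            raise ValueError("numeric configuration fields must be positive")
        if self.algorithm not in (
                "auto", "exact", "greedy", "hungarian", "sp", "fibonacci"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def prepare_molecule(mol: Molecule, cfg: RunConfig) -> Molecule:
    """Apply atom selection and bond perception according to the config."""
    if cfg.drop_hydrogens:
        mol = select_atoms(mol, drop_hydrogens=True)
    if not mol.bonds:
        mol = infer_bonds(mol, tolerance=cfg.bond_tolerance)
    return mol


def _run_engine(mol: Molecule, spec: PointGroupSpec, cfg: RunConfig) -> CSMResult:
    algo = cfg.algorithm
    if algo == "auto":
        if mol.n_atoms <= _EXACT_ATOM_LIMIT:
            try:
                res = exact_search.exact_csm(mol, spec, node_cap=_EXACT_NODE_CAP)
                logger.info("auto dispatch: exact engine (%s)", spec)
                return res
            except exact_search.EnumerationCapExceeded:
                logger.info(
                    "auto dispatch: enumeration over cap, falling back to "
                    "hungarian (%s)", spec)
        algo = "hungarian"
    if algo == "exact":
        return exact_search.exact_csm(mol, spec)
    if algo in ("greedy", "hungarian"):
        partition = equivalence_classes(mol)
        from .symcore import initial_direction_guesses
        starts = initial_direction_guesses(mol, partition).vectors
        if spec == CI:
            starts = starts[:1]
        results = [
            approx_search.permutation_direction_iterate(
                mol, spec, v, assigner=algo, partition=partition)
            for v in starts
        ]
        best = approx_search._best_result(results)
        best.algorithm = algo
        return best
    if algo == "sp":
        return approx_search.approx_structure_preserving(
            mol, spec, time_limit=cfg.time_limit)
    if algo == "fibonacci":
        return approx_search.fibonacci_multistart(
            mol, spec, n_dirs=cfg.n_dirs, assigner="hungarian")
    raise ValueError(f"unknown algorithm {algo!r}")


def compute_csm(mol: Molecule, cfg: RunConfig,
                group: Optional[PointGroupSpec] = None) -> CSMResult:
    """Compute the CSM of a prepared molecule for the configured group."""
    if group is None:
        if cfg.group == "chirality":
            return compute_ccm(mol, cfg)
        group = parse_group(cfg.group)
    res = _run_engine(mol, group, cfg)
    logger.info("S(%s) = %.6f via %s (%d iterations, preservation %s)",
                group, res.S, res.algorithm, res.iterations, res.preservation)
    return res


def compute_ccm(
    mol: Molecule,
    cfg: RunConfig,
    groups: Optional[Sequence[PointGroupSpec]] = None,
) -> CSMResult:
    """Continuous chirality measure: the minimum CSM over achiral groups.

    Defaults to {C_s, C_i}; chirality most often stems from missing
    reflection symmetry, so S(C_s) usually achieves the minimum.  Pass
    additional improper groups (S4, S6, ...) to extend the scan.
    """
    if groups is None:
        groups = (CS, CI)
    for g in groups:
        if g.proper:
            raise ValueError(f"{g} is not an achiral (improper) group")
    results = [_run_engine(mol, g, cfg) for g in groups]
    best = min(range(len(results)), key=lambda k: (results[k].S, k))
    res = results[best]
    res.algorithm = f"ccm[{res.algorithm}]"
    return res


def preservation_percentage(mol: Molecule, perm: Permutation) -> Optional[float]:
    """Percentage of bonds mapped onto bonds; None for bond-free molecules."""
    return bond_preservation(mol, perm.mapping)


def result_record(result: CSMResult) -> dict:
    """JSON-serializable record of a CSM result (permutation 1-based)."""
    return {
        "S": result.S,
        "group": str(result.group),
        "axis": [float(v) for v in result.axis],
        "permutation_1based": [int(v) + 1 for v in result.permutation.mapping],
        "M": result.M_full if result.M_full is not None else result.M_hat,
        "M_full": result.M_full,
        "M_hat": result.M_hat,
        "D": result.D,
        "preservation_percent": result.preservation,
        "algorithm": result.algorithm,
        "iterations": result.iterations,
        "converged": result.converged,
        "cycle_valid": result.cycle_valid,
        "complete": result.complete,
    }


def write_result(
    result: CSMResult,
    json_path: Optional[str | Path] = None,
    nearest_xyz_path: Optional[str | Path] = None,
    elements: Optional[Sequence[str]] = None,
) -> dict:
    """Serialize a result record to JSON and the nearest structure to XYZ."""
    record = result_record(result)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(record, indent=2) + "\n")
    if nearest_xyz_path is not None:
        els = tuple(elements) if elements is not None \
            else ("X",) * len(result.nearest)
        nearest = Molecule(els, np.asarray(result.nearest),
                           name=f"nearest {result.group} structure") \
            if elements is not None else None
        if nearest is None:
            lines = [str(len(result.nearest)), f"nearest {result.group} structure"]
            for (x, y, z) in result.nearest:
                lines.append(f"X {x:.10f} {y:.10f} {z:.10f}")
            Path(nearest_xyz_path).write_text("\n".join(lines) + "\n")
        else:
            write_xyz(nearest, nearest_xyz_path)
    return record
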