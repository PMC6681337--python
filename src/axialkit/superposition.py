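"""Least-squares rigid-body superposition (Kabsch) and RMSD.

This is the engine behind chain comparison, homolog grafting and
screw-symmetry inference. The fit minimises the RMSD between two paired
coordinate sets over proper rotations and translations; the reflection
branch of the SVD solution is corrected by the determinant sign so the
result is always a physical rotation. No outlier rejection or iterative
trimming is performed: the reported RMSD is the plain one over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_model import RigidTransform, SubunitModel

__all__ = [
    "SuperpositionResult",
    "pair_by_residue_number",
    "kabsch",
    "superpose_chains",
    "rmsd",
]


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd_A: float
    n_pairs: int
    pairing: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.rmsd_A < 0:
            raise ValueError("rmsd must be non-negative")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain root-mean-square deviation between paired coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pair_by_residue_number(
    a: SubunitModel,
    b: SubunitModel,
    atom_name: str = "CA",
    residue_range: tuple[int, int] | None = None,
):
    """Pair residues of two chains by shared author residue number.

    Returns ``(pairing, unpaired_a, unpaired_b)`` where pairing is the
    ascending list of residue numbers present (with the named atom) in both
    chains, optionally restricted to an inclusive range.
    """
    ca = a.atom_coords(atom_name)
    cb = b.atom_coords(atom_name)
    nums_a, nums_b = set(ca), set(cb)
    if residue_range is not None:
        lo, hi = residue_range
        nums_a = {n for n in nums_a if lo <= n <= hi}
        nums_b = {n for n in nums_b if lo <= n <= hi}
    shared = sorted(nums_a & nums_b)
    if not shared:
        raise ValueError(
            f"no shared residues with atom {atom_name!r} between chains "
            f"{a.chain_id!r} and {b.chain_id!r}"
        )
    pairing = [(n, n) for n in shared]
    unpaired_a = sorted(nums_a - nums_b)
    unpaired_b = sorted(nums_b - nums_a)
    return pairing, unpaired_a, unpaired_b


def kabsch(a_coords: np.ndarray, b_coords: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping ``b`` onto ``a``.

    Solves min over (R, t) of RMSD(a, R b + t) via SVD of the covariance
    matrix. Requires at least 3 non-collinear pairs; degenerate (collinear
    or coincident) inputs raise rather than returning an ill-defined axis.
    """
    a = np.asarray(a_coords, float).reshape(-1, 3)
    b = np.asarray(b_coords, float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"paired sets differ in size: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if _is_collinear(a0) or _is_collinear(b0):
        raise ValueError("degenerate (collinear) coordinates: rotation not determined")

    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = ca - rot @ cb
    transform = RigidTransform(_reorthonormalize(rot), t)
    fitted = transform.apply(b)
    return SuperpositionResult(transform=transform, rmsd_A=rmsd(a, fitted), n_pairs=n)


def _reorthonormalize(rot: np.ndarray) -> np.ndarray:
    # polish round-off so RigidTransform's 1e-9 orthonormality check holds
    u, _, vt = np.linalg.svd(rot)
    out = u @ vt
    if np.linalg.det(out) < 0:
        out = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return out


def _is_collinear(centered: np.ndarray, tol: float = 1e-10) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def superpose_chains(
    a: SubunitModel,
    b: SubunitModel,
    atom_name: str = "CA",
    residue_range: tuple[int, int] | None = None,
) -> SuperpositionResult:
    """Superpose chain ``b`` onto chain ``a`` over shared residue numbers."""
    pairing, _, _ = pair_by_residue_number(a, b, atom_name, residue_range)
    ca = a.atom_coords(atom_name)
    cb = b.atom_coords(atom_name)
    pa = np.array([ca[n] for n, _ in pairing])
    pb = np.array([cb[m] for _, m in pairing])
    result = kabsch(pa, pb)
    result.pairing = pairing
    return result
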