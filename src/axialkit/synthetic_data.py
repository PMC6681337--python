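"""Synthetic toy subunits and assemblies with known ground truth.

Real axial-structure subunits have an inner coiled-coil (D0), an extended
arm (the l-stretch) that reaches across protofilaments, and outer globular
domains (D1, D2). The toy subunit built here mimics that architecture with
a Cα-only trace in the working frame (helix axis = z):

* D0: two antiparallel ideal-helix Cα traces (1.5 A rise and 100 deg twist
  per residue) close to the axis — segments D0N and D0C;
* L_STRETCH: a taut arm of Cα pseudo-atoms running from just above the
  subunit's own D1 body to the D1 centroid of a *designed* lattice
  neighbour (e.g. offset -5), so the contact network of the built assembly
  is known by construction;
* D1: a seeded random globular cluster at a configurable radius.

Everything is deterministic for a fixed seed, which makes these toys usable
as exact oracles for the lattice, contact and grafting stages. They are
geometric stand-ins, not physical protein models: no sidechains, no
backbone geometry, no excluded volume beyond what the placement implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .helical_lattice import (
    Assembly,
    ROD_SYMMETRY,
    ScrewSymmetry,
    build_assembly,
    transform_for_index,
)
from .structure_model import Atom, Residue, SubunitModel

__all__ = ["ToySubunitSpec", "make_toy_subunit", "make_noisy_assembly"]

#: arm anchor displacement above the own-D1 centroid (A); keeps the arms of
#: +-5 and +-6 neighbours from touching each other's anchor regions. For
#: near-protofilament arm directions (|offset| ~ 11) the +-offset arms run
#: almost parallel to the axis and overlap by construction, so the designed
#: fingerprint is only guaranteed exact for cross-protofilament offsets.
_ARM_ANCHOR_LIFT = 14.0
#: Cα-Cα spacing along the taut arm (A)
_ARM_SPACING = 3.5
#: number of pseudo-atoms in the D1 ball
_D1_N_POINTS = 20
#: z of the D1 centroid in the subunit frame
_D1_CENTER_Z = 10.0


@dataclass(frozen=True)
class ToySubunitSpec:
    """Design parameters of the toy subunit.

    ``arm_direction`` is the lattice offset whose D1 centroid the arm tip
    must land on (the rod's l-stretch runs toward the -5 neighbour);
    ``arm_length_A`` must be at least the anchor-to-target distance under
    ``symmetry`` and 0 disables the arm entirely.
    """

    d0_helix_length: int = 10
    arm_length_A: float = 40.0
    arm_direction: int = -5
    d1_radius_A: float = 3.0
    radial_position_A: float = 25.0
    seed: int = 0
    symmetry: ScrewSymmetry = ROD_SYMMETRY

    def __post_init__(self) -> None:
        if self.d0_helix_length < 2:
            raise ValueError("d0_helix_length must be >= 2")
        if self.arm_length_A < 0:
            raise ValueError("arm_length_A must be >= 0")
        if self.d1_radius_A <= 0 or self.radial_position_A <= 0:
            raise ValueError("radii must be positive")
        if self.arm_length_A > 0 and self.arm_direction == 0:
            raise ValueError("arm_direction must be a non-zero lattice offset")


def _ideal_helix(n: int, base: np.ndarray, direction: float) -> np.ndarray:
    """Ideal α-helix Cα trace: 2.3 A helix radius, 1.5 A rise and 100 deg
    twist per residue, around a vertical axis through ``base``; direction
    +1 runs up, -1 runs down."""
    i = np.arange(n)
    phi = np.radians(100.0 * i)
    z = base[2] + direction * 1.5 * i
    return np.column_stack(
        [base[0] + 2.3 * np.cos(phi), base[1] + 2.3 * np.sin(phi), z]
    )


def _ca_residue(number: int, coord: np.ndarray) -> Residue:
    return Residue(number=number, name="ALA", atoms=[Atom("CA", "C", coord)])


def make_toy_subunit(spec: ToySubunitSpec) -> SubunitModel:
    """Build the reference toy subunit in the working frame.

    Raises if the arm is too short to reach the designed neighbour's D1
    centroid; the error names the required minimum length.
    """
    rng = np.random.default_rng(spec.seed)

    d1_center = np.array([spec.radial_position_A, 0.0, _D1_CENTER_Z])
    # seeded uniform points in a ball around the D1 centre
    pts = rng.normal(size=(_D1_N_POINTS, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= spec.d1_radius_A * rng.uniform(0, 1, size=(_D1_N_POINTS, 1)) ** (1 / 3)
    d1_coords = d1_center + pts

    arm_coords = np.empty((0, 3))
    if spec.arm_length_A > 0:
        anchor = d1_center + np.array([0.0, 0.0, _ARM_ANCHOR_LIFT])
        target = transform_for_index(spec.symmetry, spec.arm_direction).apply(d1_center)
        required = float(np.linalg.norm(target - anchor))
        if spec.arm_length_A < required:
            raise ValueError(
                f"arm too short to reach offset {spec.arm_direction}: needs at "
                f"least {required:.2f} A, got {spec.arm_length_A:.2f} A"
            )
        n_arm = max(2, math.ceil(required / _ARM_SPACING) + 1)
        frac = np.linspace(0.0, 1.0, n_arm)[:, None]
        arm_coords = anchor + frac * (target - anchor)

    L = spec.d0_helix_length
    d0n = _ideal_helix(L, np.array([4.5, 0.0, 0.0]), +1)
    d0c = _ideal_helix(L, np.array([7.5, 0.0, 1.5 * (L - 1)]), -1)

    residues: list[Residue] = []
    segments: dict[str, list[tuple[int, int]]] = {}
    num = 1

    def add_block(name: str, coords: np.ndarray) -> None:
        nonlocal num
        if len(coords) == 0:
            return
        start = num
        for c in coords:
            residues.append(_ca_residue(num, c))
            num += 1
        segments[name] = [(start, num - 1)]

    add_block("D0N", d0n)
    add_block("L_STRETCH", arm_coords)
    add_block("D1", d1_coords)
    add_block("D0C", d0c)
    return SubunitModel(chain_id="A", residues=residues, segments=segments)


def make_noisy_assembly(
    subunit: SubunitModel,
    sym: ScrewSymmetry,
    n: int,
    sigma_A: float,
    seed: int = 0,
) -> Assembly:
    """Helical assembly of ``n`` copies with i.i.d. Gaussian coordinate noise.

    sigma 0 reproduces :func:`build_assembly` exactly; the noise is applied
    per atom after placement, so symmetry inference degrades gracefully with
    sigma (used for the parameter-recovery tests).
    """
    if sigma_A < 0:
        raise ValueError("sigma must be >= 0")
    assembly = build_assembly(subunit, sym, (0, n - 1))
    if sigma_A == 0:
        return assembly
    rng = np.random.default_rng(seed)
    for idx in assembly.indices:
        model, t = assembly.subunits[idx]
        for res in model.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0.0, sigma_A, size=3)
        assembly.subunits[idx] = (model, t)
    return assembly
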