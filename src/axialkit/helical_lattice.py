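"""Screw-symmetry algebra for axial flagellar assemblies.

A helical assembly is generated by a single screw operator: a rotation of
``twist_deg`` about the helix axis combined with a translation of ``rise_A``
along it. The working frame puts the helix axis on +z with the distal end
toward +z; positive twist is a right-handed screw about +z. Under the
distal-rod symmetry (twist 64.75 deg, rise 4.13 A per subunit) eleven
subunits complete two turns of the 1-start helix and the lattice closes
into 11 near-axial protofilaments; the hook (64.78 deg / 4.12 A) shares the
same lattice.

Lattice positions are plain integers n along the 1-start helix, 0 being the
reference subunit and negative n proximal, so the "-5 subunit" of the
neighbour notation is index n-5. The n-start interaction families (5-start,
6-start, 11-start/protofilament) correspond to index offsets +-5, +-6, +-11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_model import CHAIN_ID_ALPHABET, RigidTransform, SubunitModel
from .superposition import kabsch

__all__ = [
    "ScrewSymmetry",
    "ROD_SYMMETRY",
    "HOOK_SYMMETRY",
    "Assembly",
    "generator_transform",
    "transform_for_index",
    "build_assembly",
    "subunits_per_turns",
    "protofilament_count",
    "start_families",
    "infer_symmetry",
    "wrap_angle",
]


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    w = math.fmod(deg, 360.0)
    if w > 180.0:
        w -= 360.0
    elif w <= -180.0:
        w += 360.0
    return w


@dataclass(frozen=True)
class ScrewSymmetry:
    """Twist (deg) and rise (A) per subunit along the 1-start helix."""

    twist_deg: float
    rise_A: float
    #: +1: positive twist is a right-handed screw about +z (default);
    #: -1 flips the sense for structures with the opposite hand.
    handedness: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_deg < 360.0:
            raise ValueError(f"twist must be in (0, 360) deg, got {self.twist_deg}")
        if self.rise_A <= 0:
            raise ValueError(f"rise must be positive, got {self.rise_A}")
        if self.handedness not in (1, -1):
            raise ValueError("handedness must be +1 or -1")

    @property
    def signed_twist_deg(self) -> float:
        return self.handedness * self.twist_deg


#: distal-rod 1-start screw symmetry
ROD_SYMMETRY = ScrewSymmetry(twist_deg=64.75, rise_A=4.13)
#: hook 1-start screw symmetry
HOOK_SYMMETRY = ScrewSymmetry(twist_deg=64.78, rise_A=4.12)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generator_transform(sym: ScrewSymmetry) -> RigidTransform:
    """The screw operator taking lattice index n to n+1."""
    return RigidTransform(_rot_z(sym.signed_twist_deg), np.array([0.0, 0.0, sym.rise_A]))


def transform_for_index(sym: ScrewSymmetry, n: int) -> RigidTransform:
    """The n-fold power of the generator.

    Because the rotation axis and translation are both along z they commute,
    so the power has the closed form rotation n*twist, translation n*rise;
    this keeps T(n) exact for negative n as well.
    """
    return RigidTransform(
        _rot_z(n * sym.signed_twist_deg), np.array([0.0, 0.0, n * sym.rise_A])
    )


@dataclass
class Assembly:
    """Subunit copies placed on the 1-start lattice.

    ``subunits`` maps the integer lattice index to the placed model and the
    transform that produced it from the reference coordinates.
    """

    symmetry: ScrewSymmetry
    subunits: dict[int, tuple[SubunitModel, RigidTransform]] = field(default_factory=dict)

    @property
    def indices(self) -> list[int]:
        return sorted(self.subunits)

    def __len__(self) -> int:
        return len(self.subunits)

    def model(self, n: int) -> SubunitModel:
        return self.subunits[n][0]

    def models(self) -> list[SubunitModel]:
        return [self.subunits[n][0] for n in self.indices]


def _chain_id_for(position: int) -> str:
    if position < len(CHAIN_ID_ALPHABET):
        return CHAIN_ID_ALPHABET[position]
    # beyond the PDB alphabet: two-character ids (mmCIF only)
    base = len(CHAIN_ID_ALPHABET)
    return CHAIN_ID_ALPHABET[position // base - 1] + CHAIN_ID_ALPHABET[position % base]


def build_assembly(
    subunit: SubunitModel, sym: ScrewSymmetry, index_range: tuple[int, int]
) -> Assembly:
    """Replicate a reference subunit over an inclusive lattice index range.

    The subunit must already sit in the working frame (helix axis = z).
    Chain ids are assigned deterministically in index order: A, B, ... Z,
    a..z, 0..9, then two-character ids.
    """
    n_min, n_max = index_range
    if n_max < n_min:
        raise ValueError(f"empty index range [{n_min}, {n_max}]")
    subunits: dict[int, tuple[SubunitModel, RigidTransform]] = {}
    for pos, n in enumerate(range(n_min, n_max + 1)):
        t = transform_for_index(sym, n)
        subunits[n] = (subunit.transformed(t, chain_id=_chain_id_for(pos)), t)
    return Assembly(symmetry=sym, subunits=subunits)


def subunits_per_turns(sym: ScrewSymmetry, turns: float) -> int:
    """Number of subunits spanning the given number of 1-start turns.

    Uses the field's counting convention of rounding to the nearest integer
    (11 subunits in two turns, 22 in four, at twist 64.75 deg).
    """
    if turns < 0:
        raise ValueError("turns must be non-negative")
    return round(turns * 360.0 / sym.twist_deg)


def protofilament_count(sym: ScrewSymmetry, n_max: int = 30) -> tuple[int, float]:
    """Lattice offset whose cumulative rotation is most nearly axial.

    Scans n = 2..n_max and returns the n minimising |wrap(n * twist)|
    together with the signed residual rotation in degrees (ties broken
    toward smaller n). For the rod lattice this is 11, the protofilament
    direction.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    best_n, best_res = None, None
    for n in range(2, n_max + 1):
        res = wrap_angle(n * sym.signed_twist_deg)
        if best_res is None or abs(res) < abs(best_res) - 1e-12:
            best_n, best_res = n, res
    return best_n, best_res


def start_families(sym: ScrewSymmetry, offsets: list[int]):
    """Net wrapped rotation and rise for each lattice offset.

    Returns a list of dicts (offset, net_rotation_deg wrapped to
    (-180, 180], net_rise_A, family label). Offsets +-5, +-6 and +-11 carry
    the 5-start / 6-start / protofilament labels of the axial lattice.
    """
    labels = {5: "5-start", 6: "6-start", 11: "protofilament (11-start)"}
    rows = []
    for k in offsets:
        if k == 0:
            raise ValueError("offset 0 is the reference subunit itself")
        rows.append(
            {
                "offset": k,
                "net_rotation_deg": wrap_angle(k * sym.signed_twist_deg),
                "net_rise_A": k * sym.rise_A,
                "family": labels.get(abs(k), f"{abs(k)}-start"),
            }
        )
    return rows


def infer_symmetry(coord_sets: list[np.ndarray], handedness_hint: int = 1):
    """Recover (twist, rise) from subunit coordinate sets in index order.

    Fits the least-squares rigid transform between each consecutive pair of
    subunits (atom correspondence assumed identical), averages the step
    transforms into a single mean screw operator, and extracts the screw
    angle about its axis and the translation along it. Returns
    ``(ScrewSymmetry, residuals)`` where residual i is the RMSD between
    subunit i+1 and the mean operator applied to subunit i — near zero for
    a true helical assembly in order, large if the subunit order is
    scrambled or the symmetry is broken. (The per-step *fit* RMSD would not
    flag a scrambled order: identical rigid copies superpose exactly in any
    order.)

    The mean axis is oriented so the rise is positive (distal = +z
    convention); the twist sign is then read in that frame.
    """
    from scipy.spatial.transform import Rotation

    if len(coord_sets) < 2:
        raise ValueError("need at least 2 subunits to infer symmetry")
    sets = [np.asarray(c, float) for c in coord_sets]
    sizes = {c.shape for c in sets}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent atom counts across subunits: {sorted(sizes)}")

    steps = [kabsch(b, a).transform for a, b in zip(sets, sets[1:])]
    mean_rot = Rotation.from_matrix([t.rotation for t in steps]).mean().as_matrix()
    mean_t = RigidTransform(
        mean_rot, np.mean([t.translation for t in steps], axis=0)
    )
    from .superposition import rmsd as _rmsd

    residuals = [ _rmsd(b, mean_t.apply(a)) for a, b in zip(sets, sets[1:]) ]
    angle_deg, _axis, axial_rise = _screw_parameters(mean_t)
    twist = float(angle_deg)
    rise = float(axial_rise)
    if twist < 0:
        # express with the opposite handedness flag, positive twist magnitude
        sym = ScrewSymmetry(twist_deg=-twist, rise_A=rise, handedness=-1)
    else:
        sym = ScrewSymmetry(twist_deg=twist, rise_A=rise, handedness=1)
    return sym, residuals


def _screw_parameters(t: RigidTransform) -> tuple[float, np.ndarray, float]:
    """Angle (deg, signed), axis (unit, rise-positive) and axial translation
    of a rigid motion interpreted as a screw."""
    rot = t.rotation
    # rotation angle from the trace; axis from the antisymmetric part
    cos_a = max(-1.0, min(1.0, (np.trace(rot) - 1.0) / 2.0))
    angle = math.acos(cos_a)
    if angle < 1e-12:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        w = np.array(
            [rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]]
        )
        norm = np.linalg.norm(w)
        if norm > 1e-9:
            axis = w / norm
        else:  # angle ~ pi: axis from symmetric part
            vals, vecs = np.linalg.eigh(rot)
            axis = vecs[:, np.argmax(vals)]
    axial = float(np.dot(t.translation, axis))
    if axial < 0:  # orient axis so the rise is positive
        axis, axial, angle = -axis, -axial, -angle
    return math.degrees(angle), axis, axial
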