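"""Coordinate data model and PDB/mmCIF readers and writers.

The pipeline works on light-weight per-chain subunit models: plain atoms
with author residue numbering (1-based, inclusive ranges, gaps allowed) and
optional segment annotations (D0N, L_STRETCH, D1, D2, D0C) given as
residue-number ranges. Parsing and serialisation of the standard formats is
delegated to gemmi; this module owns the in-memory representation that the
lattice, superposition, grafting and contact stages operate on.

Conventions fixed here:

* alternate locations: the lexicographically smallest altloc id is kept;
* hydrogens are dropped on read (all downstream analysis is heavy-atom);
* waters are kept and identified by residue name HOH/WAT;
* residue numbering is author numbering and is never renumbered on I/O.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

__all__ = [
    "Atom",
    "Residue",
    "SubunitModel",
    "RigidTransform",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "count_contents",
    "CHAIN_ID_ALPHABET",
]

#: chain-id alphabet of the PDB dialect (single-character ids)
CHAIN_ID_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits

WATER_NAMES = frozenset({"HOH", "WAT"})

#: the 20 standard amino acids plus selenomethionine (polymer in practice)
STANDARD_AA = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE""".split()
)


class StructureFormatError(ValueError):
    """Raised for unparseable files, unknown dialects or dialect limits."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")

    def moved(self, transform: "RigidTransform") -> "Atom":
        return replace(self, coord=transform.apply(self.coord))


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_water: bool = False

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"residue {self.name} {self.number}: duplicate atom names {dup}")

    @property
    def is_protein(self) -> bool:
        return self.name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms]).reshape(-1, 3)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t, the carrier for screw-symmetry
    operators and superposition results."""

    rotation: np.ndarray
    translation: np.ndarray

    _TOL = 1e-9

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > self._TOL:
            raise ValueError(f"rotation not orthonormal (deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class SubunitModel:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: segment name -> list of inclusive (first, last) author-number ranges
    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate_segments()

    def _validate_segments(self) -> None:
        covered: list[tuple[int, int, str]] = []
        for name, ranges in self.segments.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"segment {name}: range {lo}-{hi} is reversed")
                covered.append((lo, hi, name))
        covered.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(covered, covered[1:]):
            if lo2 <= hi1:
                raise ValueError(f"segments {n1} and {n2} overlap ({lo1}-{hi1} vs {lo2}-{hi2})")
        if covered and self.residues:
            lo, hi = self.residue_span()
            if covered[0][0] < lo or covered[-1][1] > hi:
                raise ValueError("segment ranges extend beyond the residue span")

    # -- residue access ----------------------------------------------------

    def residue_span(self) -> tuple[int, int]:
        nums = [r.number for r in self.residues]
        return min(nums), max(nums)

    def residue(self, number: int) -> Residue | None:
        for r in self.residues:
            if r.number == number:
                return r
        return None

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def segment_of(self, residue_number: int) -> str | None:
        for name, ranges in self.segments.items():
            if any(lo <= residue_number <= hi for lo, hi in ranges):
                return name
        return None

    # -- coordinates -------------------------------------------------------

    def coords(self) -> np.ndarray:
        """All atom coordinates in residue/atom order, shape (n, 3)."""
        parts = [r.coords() for r in self.residues if r.atoms]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)

    def atom_coords(self, atom_name: str = "CA") -> dict[int, np.ndarray]:
        """Residue number -> coordinate of the named atom (skips residues
        lacking it)."""
        out: dict[int, np.ndarray] = {}
        for r in self.residues:
            a = r.atom(atom_name)
            if a is not None:
                out[r.number] = a.coord
        return out

    def transformed(self, transform: RigidTransform, chain_id: str | None = None) -> "SubunitModel":
        residues = [
            replace(r, atoms=[a.moved(transform) for a in r.atoms]) for r in self.residues
        ]
        return SubunitModel(
            chain_id=chain_id if chain_id is not None else self.chain_id,
            residues=residues,
            segments={k: list(v) for k, v in self.segments.items()},
        )

    def with_segments(self, segments: dict[str, list[tuple[int, int]]]) -> "SubunitModel":
        return SubunitModel(self.chain_id, self.residues, segments)


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------


def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    lower = str(path).lower()
    if lower.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto"):
    """Read a PDB or mmCIF file into one :class:`SubunitModel` per chain.

    Returns ``(models, metadata)`` where metadata carries the unit cell and
    space group when the header provides them. Only the first model of
    multi-model files is used; hydrogens are dropped and for alternate
    locations the lexicographically smallest altloc id is kept.
    """
    fmt = _detect_format(path, format)
    if fmt not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")

    models: list[SubunitModel] = []
    for chain in st[0]:
        residues: list[Residue] = []
        for res in chain:
            atoms: list[Atom] = []
            seen: dict[str, str] = {}  # atom name -> kept altloc
            for at in res:
                if at.is_hydrogen():
                    continue
                alt = at.altloc or ""
                if at.name in seen:
                    if alt and alt < seen[at.name]:
                        # replace with lexicographically smaller altloc
                        idx = [a.name for a in atoms].index(at.name)
                        atoms[idx] = _convert_atom(at, res)
                        seen[at.name] = alt
                    continue
                seen[at.name] = alt
                atoms.append(_convert_atom(at, res))
            if atoms:
                residues.append(
                    Residue(
                        number=res.seqid.num,
                        name=res.name,
                        atoms=atoms,
                        insertion_code=(res.seqid.icode or "").strip(),
                        is_water=res.name in WATER_NAMES,
                    )
                )
        if residues:
            models.append(SubunitModel(chain_id=chain.name, residues=residues))

    metadata: dict = {}
    cell = st.cell
    if cell is not None and cell.a > 1.0:
        metadata["cell"] = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = st.spacegroup_hm
    if sg:
        metadata["space_group"] = sg
    return models, metadata


def _convert_atom(at, res) -> Atom:
    return Atom(
        name=at.name,
        element=at.element.name or "X",
        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
        occupancy=at.occ,
        is_hetero=res.het_flag == "H",
    )


def write_structure(models: list[SubunitModel], path, format: str = "pdb") -> None:
    """Write subunit models (one chain each) to PDB or mmCIF.

    The PDB dialect has a 62-character chain-id alphabet; larger assemblies
    must go to mmCIF, and multi-character chain ids are rejected for PDB.
    """
    if format not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown format {format!r}")
    if format == "pdb":
        if len(models) > len(CHAIN_ID_ALPHABET):
            raise StructureFormatError(
                f"{len(models)} chains exceed the PDB chain-id alphabet "
                f"({len(CHAIN_ID_ALPHABET)}); write mmCIF instead"
            )
        bad = [m.chain_id for m in models if len(m.chain_id) != 1]
        if bad:
            raise StructureFormatError(
                f"chain ids {bad} are not single characters; write mmCIF instead"
            )
    ids = [m.chain_id for m in models]
    if len(ids) != len(set(ids)):
        raise StructureFormatError("duplicate chain ids")

    st = gemmi.Structure()
    st.name = "axialkit"
    model = gemmi.Model("1")
    for sub in models:
        chain = gemmi.Chain(sub.chain_id)
        for r in sub.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
            res.het_flag = "H" if r.is_water else "A"
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coord)
                at.occ = a.occupancy
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def count_contents(models: list[SubunitModel]) -> dict[str, int]:
    """Polymer residue, water and heavy protein atom counts across chains."""
    protein_residues = 0
    waters = 0
    protein_atoms = 0
    for m in models:
        for r in m.residues:
            if r.is_water or r.name in WATER_NAMES:
                waters += 1
            elif r.is_protein:
                protein_residues += 1
                protein_atoms += sum(1 for a in r.atoms if a.element != "H")
    return {
        "protein_residues": protein_residues,
        "waters": waters,
        "protein_atoms": protein_atoms,
    }
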