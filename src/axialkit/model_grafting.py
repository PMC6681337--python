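"""Chimeric subunit construction by domain-superposition grafting.

A full-length axial-protein model can be assembled from homolog pieces: the
donor structure (e.g. a homolog whose D0 coiled-coil and l-stretch arm are
resolved) is superposed onto the acceptor (e.g. a crystallised core
fragment) by least-squares fitting of a shared domain, and the donor's
missing segments are spliced into the acceptor in that fitted placement.
Residues are then relabeled to the target protein's sequence; "sidechain
replacement" is implemented as relabeling plus truncation of the sidechain
to the atom set shared between the old and the new residue type (backbone
always kept) — a deterministic operation, with rotamer rebuilding left to
downstream refinement tools.

Splice junctions are reported, never geometrically regularised, and regions
without experimental support are handled as explicit deletion masks (the
numbering gap is preserved), never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .structure_model import Residue, SubunitModel
from .superposition import superpose_chains

__all__ = [
    "GraftPlan",
    "GraftReport",
    "graft",
    "relabel_to_target",
    "apply_deletion_mask",
    "RESIDUE_HEAVY_ATOMS",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: heavy (non-hydrogen) atom names of the 20 standard amino acids
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": BACKBONE_ATOMS,
    "ALA": BACKBONE_ATOMS + ("CB",),
    "SER": BACKBONE_ATOMS + ("CB", "OG"),
    "CYS": BACKBONE_ATOMS + ("CB", "SG"),
    "VAL": BACKBONE_ATOMS + ("CB", "CG1", "CG2"),
    "THR": BACKBONE_ATOMS + ("CB", "OG1", "CG2"),
    "ILE": BACKBONE_ATOMS + ("CB", "CG1", "CG2", "CD1"),
    "LEU": BACKBONE_ATOMS + ("CB", "CG", "CD1", "CD2"),
    "PRO": BACKBONE_ATOMS + ("CB", "CG", "CD"),
    "MET": BACKBONE_ATOMS + ("CB", "CG", "SD", "CE"),
    "PHE": BACKBONE_ATOMS + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": BACKBONE_ATOMS + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": BACKBONE_ATOMS
    + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": BACKBONE_ATOMS + ("CB", "CG", "OD1", "OD2"),
    "GLU": BACKBONE_ATOMS + ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": BACKBONE_ATOMS + ("CB", "CG", "OD1", "ND2"),
    "GLN": BACKBONE_ATOMS + ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": BACKBONE_ATOMS + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": BACKBONE_ATOMS + ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": BACKBONE_ATOMS + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass
class GraftPlan:
    """Recipe for one graft: which shared segment to superpose on, which
    donor segments to transfer, and how donor residue numbers map to the
    target numbering (``relabel_alignment``: donor number -> target number;
    identity when omitted)."""

    align_segment: str
    graft_segments: list[str]
    relabel_alignment: dict[int, int] | None = None
    fit_atom_name: str = "CA"


@dataclass
class GraftReport:
    align_rmsd_A: float
    n_fit_pairs: int
    grafted_residues: list[int] = field(default_factory=list)
    junctions: list[tuple[int, int]] = field(default_factory=list)


def _segment_residues(model: SubunitModel, segment: str) -> list[Residue]:
    if segment not in model.segments:
        raise ValueError(
            f"segment {segment!r} not annotated on chain {model.chain_id!r} "
            f"(has {sorted(model.segments)})"
        )
    return [r for r in model.residues if model.segment_of(r.number) == segment]


def _restrict(model: SubunitModel, segment: str) -> SubunitModel:
    return SubunitModel(model.chain_id, _segment_residues(model, segment))


def graft(
    acceptor: SubunitModel, donor: SubunitModel, plan: GraftPlan
) -> tuple[SubunitModel, GraftReport]:
    """Splice donor segments into the acceptor after align-segment fitting.

    The donor is rigidly moved by the superposition of its align segment
    onto the acceptor's; the residues of each graft segment are then copied
    (relabeled per the plan) into the acceptor. Acceptor coordinates are
    untouched — the chimera's non-grafted residues are bit-identical to the
    input. Residue-number collisions between grafted and retained residues
    are an error listing the colliding numbers.
    """
    fit = superpose_chains(
        _restrict(acceptor, plan.align_segment),
        _restrict(donor, plan.align_segment),
        atom_name=plan.fit_atom_name,
    )
    moved = donor.transformed(fit.transform)

    mapping = plan.relabel_alignment
    grafted: list[Residue] = []
    for segment in plan.graft_segments:
        for res in _segment_residues(moved, segment):
            new_number = mapping.get(res.number) if mapping else res.number
            if mapping and new_number is None:
                continue  # donor residue not aligned to the target: dropped
            grafted.append(replace(res, number=new_number))

    kept_numbers = set(acceptor.residue_numbers())
    collisions = sorted({r.number for r in grafted} & kept_numbers)
    if collisions:
        raise ValueError(f"graft collides with acceptor residues {collisions}")

    residues = sorted(acceptor.residues + grafted, key=lambda r: r.number)
    grafted_numbers = sorted(r.number for r in grafted)

    junctions = []
    grafted_set = set(grafted_numbers)
    for a, b in zip(residues, residues[1:]):
        if (a.number in grafted_set) != (b.number in grafted_set):
            junctions.append((a.number, b.number))

    segments = {k: list(v) for k, v in acceptor.segments.items()}
    for segment in plan.graft_segments:
        nums = [
            (mapping.get(n, n) if mapping else n)
            for lo, hi in donor.segments[segment]
            for n in range(lo, hi + 1)
            if not mapping or n in mapping
        ]
        if nums:
            segments[segment] = _to_ranges(sorted(nums))

    chimera = SubunitModel(acceptor.chain_id, residues, segments)
    report = GraftReport(
        align_rmsd_A=fit.rmsd_A,
        n_fit_pairs=fit.n_pairs,
        grafted_residues=grafted_numbers,
        junctions=junctions,
    )
    return chimera, report


def _to_ranges(sorted_numbers: list[int]) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    start = prev = sorted_numbers[0]
    for n in sorted_numbers[1:]:
        if n != prev + 1:
            ranges.append((start, prev))
            start = n
        prev = n
    ranges.append((start, prev))
    return ranges


def relabel_to_target(
    model: SubunitModel,
    alignment: dict[int, int],
    target_seq: str,
    target_start: int = 1,
) -> SubunitModel:
    """Rename residues to the target sequence, truncating sidechains.

    ``alignment`` maps model residue numbers to target residue numbers
    (1-based positions offset by ``target_start``). Each mapped residue takes
    the target residue's name and keeps only the atoms present in both the
    old and the new residue type (backbone always kept). Unaligned residues
    are dropped and reported via a warning.
    """
    missing = [r.number for r in model.residues if r.number not in alignment]
    out: list[Residue] = []
    for res in model.residues:
        tgt = alignment.get(res.number)
        if tgt is None:
            continue
        pos = tgt - target_start
        if not 0 <= pos < len(target_seq):
            raise ValueError(f"target number {tgt} outside the target sequence")
        new_name = AA1_TO_3.get(target_seq[pos].upper())
        if new_name is None:
            raise ValueError(f"unknown target residue letter {target_seq[pos]!r}")
        allowed = set(RESIDUE_HEAVY_ATOMS[new_name]) & (
            set(RESIDUE_HEAVY_ATOMS.get(res.name, ())) | set(BACKBONE_ATOMS)
        )
        atoms = [a for a in res.atoms if a.name in allowed or a.name in BACKBONE_ATOMS]
        out.append(replace(res, number=tgt, name=new_name, atoms=atoms))
    if missing:
        warnings.warn(f"{len(missing)} unaligned residues dropped: {missing}")
    segments = {}
    for name, rngs in model.segments.items():
        nums = sorted(
            alignment[n]
            for lo, hi in rngs
            for n in range(lo, hi + 1)
            if n in alignment
        )
        if nums:
            segments[name] = _to_ranges(nums)
    return SubunitModel(model.chain_id, out, segments)


def apply_deletion_mask(
    model: SubunitModel, ranges: list[tuple[int, int]]
) -> SubunitModel:
    """Remove residues in the inclusive ranges, preserving the numbering gap.

    Used for regions without experimental support (e.g. a disordered
    l-stretch tip): they are excised, never interpolated. An empty
    intersection is a warned no-op.
    """
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"reversed range {lo}-{hi}")

    def masked(n: int) -> bool:
        return any(lo <= n <= hi for lo, hi in ranges)

    kept = [r for r in model.residues if not masked(r.number)]
    removed = len(model.residues) - len(kept)
    if ranges and removed == 0:
        warnings.warn("deletion mask does not intersect the model; no-op")
    if not kept:
        warnings.warn("deletion mask removed every residue")
    segments = {}
    for name, rngs in model.segments.items():
        new_nums = [
            n for lo, hi in rngs for n in range(lo, hi + 1) if not masked(n)
        ]
        if new_nums:
            segments[name] = _to_ranges(new_nums)
    return SubunitModel(model.chain_id, kept, segments)
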