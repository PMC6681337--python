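"""Pairwise sequence comparison for axial-protein homologs.

Two alignment routes are provided. ``global_align`` is a classic
Needleman–Wunsch global alignment with BLOSUM62 and affine gap penalties
(open 10, extend 0.5 — EMBOSS-needle-style defaults), the convention under
which the rod protein FlgG and the hook protein FlgE show ~39% sequence
identity. ``structure_based_alignment`` instead derives residue
correspondences from a rigid superposition: residues are paired when their
Cα atoms are mutual nearest neighbours within a distance cutoff, with
crossing pairs resolved in favour of the shorter distance so the pairing is
monotone and one-to-one.

Identity convention (stated in every report): identical aligned pairs
divided by the number of aligned columns excluding terminal overhangs but
including internal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_model import SubunitModel
from .superposition import SuperpositionResult

__all__ = ["PairwiseAlignment", "global_align", "structure_based_alignment"]

IDENTITY_CONVENTION = (
    "identical pairs / aligned columns (terminal overhangs excluded, "
    "internal gaps included)"
)

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class PairwiseAlignment:
    """Aligned position pairs (0-based; None marks a gap) plus summary
    fractions. ``columns`` spans the region between the first and last
    matched columns, i.e. terminal overhangs are excluded."""

    pairs: list[tuple[int | None, int | None]]
    identity_fraction: float
    similarity_fraction: float
    score: float
    convention: str = IDENTITY_CONVENTION

    def __post_init__(self) -> None:
        if not 0 <= self.identity_fraction <= self.similarity_fraction <= 1:
            raise ValueError("need 0 <= identity <= similarity <= 1")
        last_a = last_b = -1
        for pa, pb in self.pairs:
            if pa is not None:
                if pa <= last_a:
                    raise ValueError("positions in a must be strictly increasing")
                last_a = pa
            if pb is not None:
                if pb <= last_b:
                    raise ValueError("positions in b must be strictly increasing")
                last_b = pb

    @property
    def matched_pairs(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.pairs if a is not None and b is not None]


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    m = substitution_matrices.load(matrix)
    aligner.substitution_matrix = m
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gaps.

    Sequences are upper-cased; X is tolerated. Identity and similarity
    fractions follow :data:`IDENTITY_CONVENTION`; a similar pair is one with
    a positive substitution score.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for name, s in (("a", seq_a), ("b", seq_b)):
        bad = set(s) - VALID_AA
        if bad:
            raise ValueError(f"sequence {name} has invalid letters {sorted(bad)}")

    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]  # deterministic first optimum
    m = aligner.substitution_matrix

    pairs = _columns(aln)
    matched_cols = [i for i, (a, b) in enumerate(pairs) if a is not None and b is not None]
    if matched_cols:
        first, last = matched_cols[0], matched_cols[-1]
        window = pairs[first : last + 1]
    else:
        window = []
    n_cols = len(window)
    ident = sum(
        1 for a, b in window if a is not None and b is not None and seq_a[a] == seq_b[b]
    )
    simil = sum(
        1
        for a, b in window
        if a is not None and b is not None and _score(m, seq_a[a], seq_b[b]) > 0
    )
    return PairwiseAlignment(
        pairs=pairs,
        identity_fraction=ident / n_cols if n_cols else 0.0,
        similarity_fraction=simil / n_cols if n_cols else 0.0,
        score=float(aln.score),
    )


def _score(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        return 0.0  # X or other letters missing from the matrix


def _columns(aln) -> list[tuple[int | None, int | None]]:
    """Column-wise (pos_a, pos_b) pairs from a Bio.Align alignment."""
    pairs: list[tuple[int | None, int | None]] = []
    ia = ib = 0
    sa, sb = str(aln[0]), str(aln[1])
    for ca, cb in zip(sa, sb):
        pa = pb = None
        if ca != "-":
            pa, ia = ia, ia + 1
        if cb != "-":
            pb, ib = ib, ib + 1
        pairs.append((pa, pb))
    return pairs


def structure_based_alignment(
    superposition: SuperpositionResult,
    a: SubunitModel,
    b: SubunitModel,
    dist_cutoff_A: float = 3.0,
    atom_name: str = "CA",
) -> PairwiseAlignment:
    """Residue pairing induced by a rigid superposition of two models.

    After moving model ``b`` by the superposition transform, residues are
    paired when their Cα atoms are mutual nearest neighbours within the
    cutoff. Crossing (non-monotone) candidates are resolved by keeping the
    shorter-distance pair. Positions in the returned alignment are indices
    into each model's residue list; matched-only columns are reported (an
    empty pairing is returned, with a warning, when nothing falls under the
    cutoff).
    """
    import warnings

    ca = a.atom_coords(atom_name)
    cb = b.atom_coords(atom_name)
    nums_a, nums_b = sorted(ca), sorted(cb)
    if not nums_a or not nums_b:
        raise ValueError(f"no {atom_name} atoms to pair")
    xa = np.array([ca[n] for n in nums_a])
    xb = superposition.transform.apply(np.array([cb[n] for n in nums_b]))

    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    nn_a = d.argmin(axis=1)
    nn_b = d.argmin(axis=0)
    candidates = [
        (i, int(nn_a[i]), d[i, nn_a[i]])
        for i in range(len(nums_a))
        if nn_b[nn_a[i]] == i and d[i, nn_a[i]] <= dist_cutoff_A
    ]
    # resolve crossings: accept pairs shortest-first, keep only monotone ones
    kept: list[tuple[int, int]] = []
    for i, j, _dist in sorted(candidates, key=lambda c: c[2]):
        if all((i < ki) == (j < kj) for ki, kj in kept):
            kept.append((i, j))
    kept.sort()
    if not kept:
        warnings.warn(f"no residue pairs within {dist_cutoff_A} A")
        return PairwiseAlignment([], 0.0, 0.0, 0.0)

    pairs: list[tuple[int | None, int | None]] = list(kept)
    n = len(kept)
    ident = sum(
        1
        for i, j in kept
        if a.residue(nums_a[i]).name == b.residue(nums_b[j]).name
    )
    frac = ident / n
    # every kept pair is a structural equivalence, so similarity is 1 here
    return PairwiseAlignment(
        pairs=pairs, identity_fraction=frac, similarity_fraction=1.0, score=float(n)
    )
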