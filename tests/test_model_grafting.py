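import numpy as np
import pytest

from axialkit import (
    GraftPlan,
    ToySubunitSpec,
    apply_deletion_mask,
    graft,
    make_toy_subunit,
    relabel_to_target,
)
from axialkit.model_grafting import BACKBONE_ATOMS, RESIDUE_HEAVY_ATOMS
from axialkit.structure_model import Atom, Residue, RigidTransform, SubunitModel


def residue_with_atoms(number, name):
    atoms = [Atom(a, a[0], [number + i * 0.1, 0, 0]) for i, a in
             enumerate(RESIDUE_HEAVY_ATOMS[name])]
    return Residue(number, name, atoms)


@pytest.fixture
def donor(toy_subunit):
    return toy_subunit


@pytest.fixture
def armless_acceptor(donor):
    """The same toy subunit with its arm deleted — the graft ground truth is
    the donor itself."""
    return apply_deletion_mask(donor, donor.segments["L_STRETCH"])


class TestGraft:
    def test_grafting_back_the_arm_reconstructs_the_donor(self, donor, armless_acceptor):
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        chimera, report = graft(armless_acceptor, donor, plan)
        assert chimera.residue_numbers() == donor.residue_numbers()
        np.testing.assert_allclose(chimera.coords(), donor.coords(), atol=1e-9)
        assert report.align_rmsd_A == pytest.approx(0.0, abs=1e-9)
        lo, hi = donor.segments["L_STRETCH"][0]
        assert report.grafted_residues == list(range(lo, hi + 1))

    def test_graft_from_displaced_donor_lands_at_true_geometry(
        self, donor, armless_acceptor, rng
    ):
        """Moving the donor rigidly must not change the chimera: the align-
        segment superposition undoes the motion exactly."""
        from scipy.spatial.transform import Rotation

        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        moved_donor = donor.transformed(t)
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        chimera, _ = graft(armless_acceptor, moved_donor, plan)
        np.testing.assert_allclose(chimera.coords(), donor.coords(), atol=1e-8)

    def test_acceptor_coordinates_outside_graft_bit_identical(self, donor, armless_acceptor):
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        chimera, _ = graft(armless_acceptor, donor, plan)
        for res in armless_acceptor.residues:
            out = chimera.residue(res.number)
            for a_in, a_out in zip(res.atoms, out.atoms):
                assert np.array_equal(a_in.coord, a_out.coord)  # bitwise

    def test_grafted_segment_keeps_donor_internal_geometry(self, donor, armless_acceptor, rng):
        from scipy.spatial.transform import Rotation

        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        chimera, _ = graft(armless_acceptor, donor.transformed(t), plan)
        lo, hi = donor.segments["L_STRETCH"][0]
        arm = lambda m: np.array(
            [m.residue(n).atom("CA").coord for n in range(lo, hi + 1)]
        )
        d_true = np.linalg.norm(arm(donor)[:, None] - arm(donor)[None], axis=2)
        d_graft = np.linalg.norm(arm(chimera)[:, None] - arm(chimera)[None], axis=2)
        np.testing.assert_allclose(d_graft, d_true, atol=1e-6)

    def test_graft_then_delete_returns_acceptor_exactly(self, donor, armless_acceptor):
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        chimera, _ = graft(armless_acceptor, donor, plan)
        back = apply_deletion_mask(chimera, donor.segments["L_STRETCH"])
        assert back.residue_numbers() == armless_acceptor.residue_numbers()
        np.testing.assert_array_equal(back.coords(), armless_acceptor.coords())

    def test_residue_number_collision_is_an_error_listing_numbers(self, donor):
        plan = GraftPlan(align_segment="D1", graft_segments=["L_STRETCH"])
        with pytest.raises(ValueError, match="collides"):
            graft(donor, donor, plan)  # acceptor still owns the arm numbers

    def test_missing_segment_is_an_error(self, armless_acceptor, donor):
        plan = GraftPlan(align_segment="D9", graft_segments=["L_STRETCH"])
        with pytest.raises(ValueError, match="D9"):
            graft(armless_acceptor, donor, plan)


class TestRelabel:
    def test_identity_relabeling_keeps_model_unchanged(self):
        model = SubunitModel("A", [residue_with_atoms(1, "TRP"), residue_with_atoms(2, "SER")])
        out = relabel_to_target(model, {1: 1, 2: 2}, "WS")
        assert [r.name for r in out.residues] == ["TRP", "SER"]
        np.testing.assert_array_equal(out.coords(), model.coords())

    def test_ala_to_gly_drops_cb(self):
        model = SubunitModel("A", [residue_with_atoms(1, "ALA")])
        out = relabel_to_target(model, {1: 1}, "G")
        assert [a.name for a in out.residues[0].atoms] == list(BACKBONE_ATOMS)

    def test_trp_to_ser_keeps_backbone_plus_cb(self):
        # shared atoms of TRP and SER = backbone plus CB (OG is SER-only)
        model = SubunitModel("A", [residue_with_atoms(1, "TRP")])
        out = relabel_to_target(model, {1: 1}, "S")
        assert sorted(a.name for a in out.residues[0].atoms) == sorted(
            BACKBONE_ATOMS + ("CB",)
        )
        assert out.residues[0].name == "SER"

    def test_unaligned_residues_dropped_with_warning(self):
        model = SubunitModel("A", [residue_with_atoms(1, "ALA"), residue_with_atoms(2, "GLY")])
        with pytest.warns(UserWarning, match="unaligned"):
            out = relabel_to_target(model, {1: 1}, "A")
        assert out.residue_numbers() == [1]

    def test_target_position_out_of_range_is_an_error(self):
        model = SubunitModel("A", [residue_with_atoms(1, "ALA")])
        with pytest.raises(ValueError, match="outside"):
            relabel_to_target(model, {1: 5}, "AG")


class TestDeletionMask:
    def test_mask_53_64_removes_exactly_12_residues(self):
        residues = [
            Residue(n, "ALA", [Atom("CA", "C", [n, 0, 0])]) for n in range(47, 261)
        ]
        model = SubunitModel("A", residues)
        out = apply_deletion_mask(model, [(53, 64)])
        assert len(model.residues) - len(out.residues) == 12
        # numbering of the survivors untouched: the gap is preserved
        assert out.residue(52) is not None and out.residue(65) is not None
        assert all(out.residue(n) is None for n in range(53, 65))

    def test_empty_mask_is_identity(self, toy_subunit):
        out = apply_deletion_mask(toy_subunit, [])
        assert out.residue_numbers() == toy_subunit.residue_numbers()

    def test_mask_covering_everything_warns_and_empties(self, toy_subunit):
        lo, hi = toy_subunit.residue_span()
        with pytest.warns(UserWarning, match="every residue"):
            out = apply_deletion_mask(toy_subunit, [(lo, hi)])
        assert out.residues == []

    def test_non_intersecting_mask_warns_noop(self, toy_subunit):
        with pytest.warns(UserWarning, match="no-op"):
            out = apply_deletion_mask(toy_subunit, [(10_000, 10_005)])
        assert out.residue_numbers() == toy_subunit.residue_numbers()
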