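import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axialkit import (
    HOOK_SYMMETRY,
    ROD_SYMMETRY,
    ScrewSymmetry,
    build_assembly,
    generator_transform,
    infer_symmetry,
    make_toy_subunit,
    protofilament_count,
    start_families,
    subunits_per_turns,
    transform_for_index,
    ToySubunitSpec,
)
from axialkit.helical_lattice import wrap_angle


class TestGeneratorTransform:
    def test_near_identity_rotation_preserves_rise(self):
        t = generator_transform(ScrewSymmetry(360.0 - 1e-9, 2.5))
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-8)
        assert t.translation[2] == 2.5

    def test_eleven_steps_accumulate_printed_twist_and_rise(self):
        # 11 x 64.75 deg = 712.25 deg (wraps to -7.75), 11 x 4.13 A = 45.43 A
        t11 = transform_for_index(ROD_SYMMETRY, 11)
        assert wrap_angle(11 * ROD_SYMMETRY.twist_deg) == pytest.approx(-7.75)
        assert t11.translation[2] == pytest.approx(45.43)
        angle = np.degrees(np.arctan2(t11.rotation[1, 0], t11.rotation[0, 0]))
        assert angle == pytest.approx(-7.75, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(-20, 20), st.integers(-20, 20))
    def test_group_property_composition_matches_index_addition(self, n, m):
        tn = transform_for_index(ROD_SYMMETRY, n)
        tm = transform_for_index(ROD_SYMMETRY, m)
        tnm = transform_for_index(ROD_SYMMETRY, n + m)
        comp = tn.compose(tm)
        np.testing.assert_allclose(comp.rotation, tnm.rotation, atol=1e-9)
        np.testing.assert_allclose(comp.translation, tnm.translation, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        for twist, rise in [(0.0, 4.0), (360.0, 4.0), (-5.0, 4.0), (60.0, 0.0)]:
            with pytest.raises(ValueError):
                ScrewSymmetry(twist, rise)


class TestLatticeCounting:
    def test_rod_subunits_per_two_and_four_turns(self):
        assert subunits_per_turns(ROD_SYMMETRY, 2) == 11
        assert subunits_per_turns(ROD_SYMMETRY, 4) == 22
        assert subunits_per_turns(ROD_SYMMETRY, 0) == 0

    def test_protofilament_count_rod_and_hook(self):
        n, residual = protofilament_count(ROD_SYMMETRY)
        assert n == 11
        assert residual == pytest.approx(-7.75)
        assert protofilament_count(HOOK_SYMMETRY)[0] == 11

    def test_protofilament_count_exact_eleven_start(self):
        n, residual = protofilament_count(ScrewSymmetry(720.0 / 11.0, 4.13))
        assert n == 11
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_start_families_arithmetic_and_antisymmetry(self):
        rows = start_families(ROD_SYMMETRY, [5, -5, 6, 11])
        by_offset = {r["offset"]: r for r in rows}
        assert by_offset[5]["net_rotation_deg"] == pytest.approx(-36.25)
        assert by_offset[5]["net_rise_A"] == pytest.approx(20.65)
        assert by_offset[5]["family"] == "5-start"
        assert by_offset[-5]["net_rotation_deg"] == pytest.approx(36.25)
        assert by_offset[-5]["net_rise_A"] == pytest.approx(-20.65)
        assert by_offset[6]["family"] == "6-start"
        assert by_offset[11]["family"].startswith("protofilament")
        with pytest.raises(ValueError):
            start_families(ROD_SYMMETRY, [0])

    def test_exact_lattice_offset_11_wraps_to_zero(self):
        rows = start_families(ScrewSymmetry(720.0 / 11.0, 4.0), [11])
        assert rows[0]["net_rotation_deg"] == pytest.approx(0.0, abs=1e-9)


class TestBuildAssembly:
    def test_single_index_range_is_identity(self, toy_subunit):
        asm = build_assembly(toy_subunit, ROD_SYMMETRY, (0, 0))
        assert len(asm) == 1
        np.testing.assert_array_equal(asm.model(0).coords(), toy_subunit.coords())

    def test_rod_segment_has_22_subunits_over_four_turns(self, toy_subunit):
        asm = build_assembly(toy_subunit, ROD_SYMMETRY, (-21, 0))
        assert len(asm) == subunits_per_turns(ROD_SYMMETRY, 4) == 22

    def test_empty_range_rejected(self, toy_subunit):
        with pytest.raises(ValueError, match="empty"):
            build_assembly(toy_subunit, ROD_SYMMETRY, (3, 2))

    def test_all_subunits_share_internal_geometry(self, toy_subunit):
        asm = build_assembly(toy_subunit, ROD_SYMMETRY, (-3, 3))
        ref = toy_subunit.coords()
        dref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        for n in asm.indices:
            c = asm.model(n).coords()
            d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
            np.testing.assert_allclose(d, dref, atol=1e-6)


class TestInferSymmetry:
    def test_noiseless_rod_assembly_recovers_parameters_exactly(self, rod_assembly):
        coords = [rod_assembly.model(n).coords() for n in rod_assembly.indices]
        sym, residuals = infer_symmetry(coords)
        assert sym.signed_twist_deg == pytest.approx(64.75, abs=1e-9)
        assert sym.rise_A == pytest.approx(4.13, abs=1e-9)
        assert max(residuals) < 1e-9

    def test_recovery_round_trip_over_random_parameters(self, toy_subunit, rng):
        for _ in range(10):
            twist = rng.uniform(30.0, 120.0)
            rise = rng.uniform(2.0, 8.0)
            sym = ScrewSymmetry(twist, rise)
            asm = build_assembly(toy_subunit, sym, (0, 9))
            inferred, _ = infer_symmetry([asm.model(n).coords() for n in asm.indices])
            assert inferred.signed_twist_deg == pytest.approx(twist, rel=1e-9)
            assert inferred.rise_A == pytest.approx(rise, rel=1e-9)

    def test_left_handed_symmetry_recovered_with_handedness_flag(self, toy_subunit):
        sym = ScrewSymmetry(64.75, 4.13, handedness=-1)
        asm = build_assembly(toy_subunit, sym, (0, 5))
        inferred, _ = infer_symmetry([asm.model(n).coords() for n in asm.indices])
        assert inferred.signed_twist_deg == pytest.approx(-64.75, abs=1e-9)

    def test_noisy_assembly_recovers_within_stated_tolerance(self, toy_subunit):
        from axialkit import make_noisy_assembly

        asm = make_noisy_assembly(toy_subunit, ROD_SYMMETRY, 22, sigma_A=0.2, seed=7)
        sym, _ = infer_symmetry([asm.model(n).coords() for n in asm.indices])
        assert sym.signed_twist_deg == pytest.approx(64.75, abs=0.1)
        assert sym.rise_A == pytest.approx(4.13, abs=0.05)

    def test_shuffled_subunit_order_flags_large_residual(self, rod_assembly, rng):
        coords = [rod_assembly.model(n).coords() for n in rod_assembly.indices]
        shuffled = [coords[i] for i in rng.permutation(len(coords))]
        _, residuals = infer_symmetry(shuffled)
        assert max(residuals) > 1.0  # far above the noiseless ~1e-14

    def test_input_validation(self, toy_subunit):
        c = toy_subunit.coords()
        with pytest.raises(ValueError, match="at least 2"):
            infer_symmetry([c])
        with pytest.raises(ValueError, match="atom counts"):
            infer_symmetry([c, c[:-1]])
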