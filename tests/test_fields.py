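"""Grid construction and CoMFA/CoMSIA field values against analytic and
brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gridqsar import fields
from gridqsar.fields import GridSpec, ProbeSpec


class TestMakeGrid:
    def test_point_count_with_margin(self, toy_molecule):
        m = toy_molecule([[0, 0, 0], [4, 0, 0]])
        grid = fields.make_grid([m], spacing=2.0, margin=4.0)
        assert grid.dims[0] == 7  # x from -4 to 8 by 2
        assert grid.origin[0] == pytest.approx(-4.0)

    def test_degenerate_single_atom_zero_margin(self, toy_molecule):
        m = toy_molecule([[1.0, 2.0, 3.0]])
        grid = fields.make_grid([m], spacing=2.0, margin=0.0)
        assert grid.dims == (1, 1, 1)

    def test_lattice_covers_all_atoms(self, toy_molecule):
        rng = np.random.default_rng(0)
        m = toy_molecule(rng.uniform(-7, 7, (20, 3)))
        grid = fields.make_grid([m], spacing=1.7, margin=3.0)
        lo = np.asarray(grid.origin)
        hi = lo + grid.spacing * (np.asarray(grid.dims) - 1)
        assert np.all(m.coords >= lo - 1e-9) and np.all(m.coords <= hi + 1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fields.make_grid([], spacing=2.0, margin=4.0)


class TestComsiaValues:
    def test_probe_on_atom_gives_minus_one(self, toy_molecule):
        m = toy_molecule([[0, 0, 0]], s=[1.0], e=[1.0], h=[1.0], d=[1.0], a=[1.0])
        vals = fields.comsia_values(m, np.array([[0.0, 0.0, 0.0]]))
        for key in "SEHDA":
            assert vals[key][0] == pytest.approx(-1.0, abs=1e-12)

    def test_analytic_value_at_known_distance(self, toy_molecule):
        # alpha * r^2 = 0.3 * 10/3 = 1, so the index is -e^-1
        m = toy_molecule([[0, 0, 0]], s=[1.0])
        r = np.sqrt(10.0 / 3.0)
        vals = fields.comsia_values(m, np.array([[r, 0.0, 0.0]]))
        assert vals["S"][0] == pytest.approx(-np.exp(-1.0), abs=1e-12)

    def test_matches_brute_force_double_loop(self, toy_molecule):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-2, 2, (3, 3))
        props = {k: rng.uniform(-1, 2, 3) for k in "SEHDA"}
        m = toy_molecule(coords, **{k.lower(): v for k, v in props.items()})
        pts = rng.uniform(-4, 4, (50, 3))
        vals = fields.comsia_values(m, pts)
        for key in "SEHDA":
            expected = np.array(
                [
                    -sum(
                        props[key][i] * np.exp(-0.3 * np.sum((p - coords[i]) ** 2))
                        for i in range(3)
                    )
                    for p in pts
                ]
            )
            np.testing.assert_allclose(vals[key], expected, atol=1e-12)

    def test_magnitude_decreases_with_distance(self, toy_molecule):
        m = toy_molecule([[0, 0, 0]], s=[2.0])
        d = np.linspace(0, 6, 30)
        pts = np.column_stack([d, np.zeros_like(d), np.zeros_like(d)])
        mags = np.abs(fields.comsia_values(m, pts)["S"])
        assert np.all(np.diff(mags) < 0)


class TestComfaValues:
    def test_zero_charges_give_zero_electrostatics(self, toy_molecule):
        m = toy_molecule([[0, 0, 0], [2, 0, 0]], charges=[0.0, 0.0])
        _, elec, _ = fields.comfa_values(m, np.random.default_rng(1).uniform(-3, 3, (20, 3)))
        np.testing.assert_array_equal(elec, 0.0)

    def test_steric_zero_at_sigma(self, toy_molecule):
        probe = ProbeSpec()
        m = toy_molecule([[0, 0, 0]])
        rmin = fields.VDW_PARAMS["X"][0] + probe.radius
        sigma = rmin * 2 ** (-1 / 6)
        steric, _, _ = fields.comfa_values(m, np.array([[sigma, 0.0, 0.0]]), probe)
        assert steric[0] == pytest.approx(0.0, abs=1e-9)

    def test_probe_at_atom_center_clamps_to_truncation(self, toy_molecule):
        m = toy_molecule([[0, 0, 0]])
        steric, _, excluded = fields.comfa_values(m, np.array([[0.0, 0.0, 0.0]]))
        assert steric[0] == 30.0
        assert excluded[0]

    def test_clamp_bounds_hold_everywhere(self, toy_molecule):
        rng = np.random.default_rng(2)
        m = toy_molecule(rng.uniform(-2, 2, (5, 3)), charges=rng.uniform(-1, 1, 5))
        pts = rng.uniform(-3, 3, (200, 3))
        steric, elec, _ = fields.comfa_values(m, pts)
        assert steric.max() <= 30.0
        assert np.abs(elec).max() <= 30.0

    def test_coulomb_with_distance_dependent_dielectric(self, toy_molecule):
        m = toy_molecule([[0, 0, 0]], charges=[0.25])
        r = 3.0
        _, elec, _ = fields.comfa_values(m, np.array([[r, 0.0, 0.0]]))
        assert elec[0] == pytest.approx(fields.COULOMB_CONSTANT * 0.25 / r**2, rel=1e-12)


class TestAssembleBlocks:
    def test_row_count_and_order(self, toy_molecule):
        mols = [toy_molecule([[i * 0.5, 0, 0]], cid=10 - i) for i in range(5)]
        grid = fields.make_grid(mols, spacing=2.0, margin=2.0)
        block = fields.assemble_block(mols, grid, field_kind="comsia_S")
        assert block.matrix.shape[0] == 5
        assert block.compound_ids == sorted(m.compound_id for m in mols)

    def test_duplicate_molecules_give_identical_rows(self, toy_molecule):
        a = toy_molecule([[0, 0, 0], [1, 1, 0]], cid=1)
        b = toy_molecule([[0, 0, 0], [1, 1, 0]], cid=2)
        grid = fields.make_grid([a, b], spacing=2.0, margin=3.0)
        block = fields.assemble_block([a, b], grid, field_kind="comsia_S")
        np.testing.assert_array_equal(block.matrix[0], block.matrix[1])

    def test_joint_rigid_transform_invariance(self, toy_molecule):
        rng = np.random.default_rng(9)
        coords = rng.uniform(-2, 2, (4, 3))
        m = toy_molecule(coords, s=rng.uniform(1, 3, 4), charges=rng.uniform(-0.5, 0.5, 4))
        pts = rng.uniform(-4, 4, (100, 3))
        R = Rotation.random(random_state=4).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        moved = m.transformed(R, t)
        pts_moved = pts @ R.T + t

        base = fields.comsia_values(m, pts)["S"]
        trans = fields.comsia_values(moved, pts_moved)["S"]
        np.testing.assert_allclose(trans, base, atol=1e-9)

        s0, e0, _ = fields.comfa_values(m, pts)
        s1, e1, _ = fields.comfa_values(moved, pts_moved)
        np.testing.assert_allclose(s1, s0, atol=1e-9)
        np.testing.assert_allclose(e1, e0, atol=1e-9)

    def test_excluded_electrostatics_replaced_by_column_mean(self, toy_molecule):
        # molecule 1 engulfs the origin; molecules 2 and 3 are remote dipoles
        a = toy_molecule([[0, 0, 0]], charges=[0.3], cid=1)
        b = toy_molecule([[4, 0, 0]], charges=[0.3], cid=2)
        c = toy_molecule([[0, 4, 0]], charges=[-0.3], cid=3)
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=2.0, dims=(1, 1, 1))
        blocks = fields.assemble_comfa_blocks([a, b, c], grid)
        elec = blocks["comfa_electrostatic"].matrix[:, 0]
        raw = fields.assemble_comfa_blocks([a, b, c], grid, electrostatic_exclusion="raw")
        # the excluded first row equals the mean of the two non-excluded rows
        assert elec[0] == pytest.approx((elec[1] + elec[2]) / 2)
        assert raw["comfa_electrostatic"].matrix[0, 0] == 30.0  # clamped raw

    def test_unknown_field_kind(self, toy_molecule):
        m = toy_molecule([[0, 0, 0]])
        grid = fields.make_grid([m], margin=2.0)
        with pytest.raises(ValueError, match="field kind"):
            fields.assemble_block([m], grid, field_kind="nope")
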