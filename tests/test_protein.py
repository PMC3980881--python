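"""Variable enumeration, chain geometry, reduced energy, planted landscape, dRMSD."""
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cmqa.landscapes import PlantedLandscape, planted_landscape
from cmqa.protein import (
    CHI_COUNTS,
    INTERNAL_GEOMETRY,
    ChainGeometry,
    EnergyParams,
    build_coordinates,
    compute_energy,
    dihedral_deg,
    drmsd,
    enumerate_variables,
    measure_torsions,
    read_fasta,
    read_pdb_coords,
    write_pdb,
)


class TestEnumerateVariables:
    def test_met_enkephalin_dimension(self):
        # 2 backbone angles per residue plus 3+0+0+2+4 side-chain torsions
        inst = enumerate_variables("YGGFM", ("phi", "psi", "chi"))
        assert inst.m == 19

    def test_free_ends_drop_terminal_angles(self):
        assert enumerate_variables("G", ("phi", "psi"), ends="free").m == 0
        inst = enumerate_variables("GG", ("phi", "psi", "omega"), ends="free")
        assert inst.m == 3
        assert [(v.residue, v.kind) for v in inst.variables] == [
            (0, "psi"), (0, "omega"), (1, "phi"),
        ]

    def test_charged_ends_keep_terminal_angles(self):
        assert enumerate_variables("G", ("phi", "psi"), ends="charged").m == 2

    def test_enumeration_is_stable(self):
        a = enumerate_variables("YGGFM")
        b = enumerate_variables("YGGFM")
        assert a.variables == b.variables

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            enumerate_variables("GGXG")

    def test_unknown_angle_kind_rejected(self):
        with pytest.raises(ValueError, match="angle kinds"):
            enumerate_variables("GG", ("phi", "theta"))


@pytest.fixture(scope="module")
def ygg_geom():
    inst = enumerate_variables("YGGFM")
    conf = np.random.default_rng(11).uniform(-179.0, 179.0, inst.m)
    return inst, conf, build_coordinates(inst, conf)


class TestGeometry:
    def test_bonded_distances_match_table(self, ygg_geom):
        _, _, geom = ygg_geom
        for a, b in geom.bonds:
            na, nb = geom.atom_names[a], geom.atom_names[b]
            ca = "SC" if na.startswith("SC") else na
            cb = "SC" if nb.startswith("SC") else nb
            expect = (
                INTERNAL_GEOMETRY.get((ca, cb))
                or INTERNAL_GEOMETRY.get((cb, ca))
            )
            r = np.linalg.norm(geom.coords[a] - geom.coords[b])
            assert r == pytest.approx(expect, abs=1e-6), (na, nb)

    def test_torsion_round_trip(self, ygg_geom):
        _, conf, geom = ygg_geom
        measured = measure_torsions(geom)
        assert np.abs(measured - conf).max() < 1e-6

    def test_terminal_chi_is_local(self):
        inst = enumerate_variables("YGGFM")
        rng = np.random.default_rng(3)
        conf = rng.uniform(-179, 179, inst.m)
        other = conf.copy()
        other[-1] += 40.0  # last chi of the final Met
        ga = build_coordinates(inst, conf)
        gb = build_coordinates(inst, other)
        backbone = [i for i, n in enumerate(ga.atom_names) if n in ("N", "CA", "C", "O", "OXT")]
        np.testing.assert_allclose(ga.coords[backbone], gb.coords[backbone], atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        inst = enumerate_variables("GG", ("phi", "psi"), ends="free")
        with pytest.raises(ValueError):
            build_coordinates(inst, np.zeros(inst.m + 1))

    def test_dihedral_sign_convention(self):
        # +90 degree torsion: the fourth atom sits on the +z side
        p = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [3.0, 0.0, 1.0]])
        measured = dihedral_deg(*p)
        assert measured == pytest.approx(-90.0) or measured == pytest.approx(90.0)
        # antiperiplanar is 180 under the convention used throughout
        p[3] = [3.0, -1.0, 0.0]
        assert abs(dihedral_deg(*p)) == pytest.approx(180.0)


def _pair_geometry(r):
    return ChainGeometry(
        coords=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        atom_names=["CB", "CB"],
        res_index=[0, 0],
        bonds=[],
        torsion_quads=[],
        torsion_kinds=[],
        torsion_values=np.array([]),
    )


class TestEnergy:
    def test_components_sum_to_total(self, ygg_geom):
        _, _, geom = ygg_geom
        e = compute_energy(geom)
        assert e.total == e.lj + e.electrostatic + e.torsion + e.hbond

    def test_lj_minimum_closed_form(self):
        params = EnergyParams.default()
        eps, rmin = params.lj["CB"]["eps"], params.lj["CB"]["rmin"]
        A, B = eps * rmin**12, 2 * eps * rmin**6
        r_star = (2 * A / B) ** (1 / 6)
        e = compute_energy(_pair_geometry(r_star), params)
        assert e.lj == pytest.approx(-(B**2) / (4 * A), rel=1e-12)
        assert e.electrostatic == 0.0 and e.hbond == 0.0 and e.torsion == 0.0

    def test_rigid_motion_invariance(self, ygg_geom):
        _, _, geom = ygg_geom
        e0 = compute_energy(geom).total
        rng = np.random.default_rng(5)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=10.0, size=3)
            moved = ChainGeometry(
                coords=geom.coords @ rot.T + shift,
                atom_names=geom.atom_names,
                res_index=geom.res_index,
                bonds=geom.bonds,
                torsion_quads=geom.torsion_quads,
                torsion_kinds=geom.torsion_kinds,
                torsion_values=geom.torsion_values,
            )
            assert compute_energy(moved).total == pytest.approx(e0, abs=1e-9)

    def test_coincident_atoms_penalized_finite(self):
        e = compute_energy(_pair_geometry(1e-9))
        assert np.isfinite(e.total) and e.total >= 1e6


class TestPlantedLandscape:
    def test_optimum_is_exactly_zero(self, planted19):
        assert planted19.energy(planted19.sigma_star) == 0.0

    def test_positive_away_from_optimum(self, planted19):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            s = rng.uniform(-180, 180, planted19.m)
            assert planted19.energy(s) > 0.0

    def test_trap_free_profile_is_unimodal(self):
        ls = planted_landscape(3, n_traps=0, rng=np.random.default_rng(1))
        grid = np.linspace(-179.9, 180.0, 3600)
        for i in range(ls.m):
            v = ls._coordinate_profile(i, grid)
            # single interior minimum: derivative changes sign exactly once
            sign_changes = np.sum(np.diff(np.sign(np.diff(v))) > 0)
            assert sign_changes == 1

    def test_descent_spot_check(self, planted19):
        assert planted19.descent_check(n_random=2000, seed=2)

    def test_deterministic_from_seed(self):
        a = planted_landscape(6, n_traps=2, rng=np.random.default_rng(9))
        b = planted_landscape(6, n_traps=2, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.sigma_star, b.sigma_star)
        np.testing.assert_array_equal(a.trap_shifts_deg, b.trap_shifts_deg)

    def test_invalid_traps_rejected(self):
        with pytest.raises(ValueError):
            planted_landscape(2, n_traps=5, rng=np.random.default_rng(0))


class TestDrmsd:
    def test_identity_and_rigid_invariance(self, ygg_geom):
        _, _, geom = ygg_geom
        ca = geom.select("CA")
        assert drmsd(ca, ca) == 0.0
        rng = np.random.default_rng(23)
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = ca @ rot.T + rng.normal(size=3)
            assert drmsd(ca, moved) < 1e-9
        # reflection too: pairwise distances are chirality-blind
        assert drmsd(ca, -ca) < 1e-9

    def test_three_atom_worked_value(self):
        a = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
        x = -11.0 / 6.0
        b = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [x, math.sqrt(16 - x * x), 0.0]])
        # pair distances (3, 4, 5) vs (3, 4, 6)
        assert drmsd(a, b) == pytest.approx(math.sqrt(1.0 / 3.0), abs=1e-12)

    def test_mismatched_structures_rejected(self):
        with pytest.raises(ValueError):
            drmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestFileFormats:
    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "seq.fasta"
        p.write_text(">pep1\nYGGFM\n>pep2\nAAA\n")
        assert read_fasta(p) == ("pep1", "YGGFM")
        assert read_fasta(p, record="pep2") == ("pep2", "AAA")

    def test_pdb_round_trip_preserves_ca(self, tmp_path, ygg_geom):
        inst, _, geom = ygg_geom
        p = tmp_path / "best.pdb"
        write_pdb(geom, inst.sequence, p)
        ca = read_pdb_coords(p, "CA")
        # PDB coordinates carry three decimals
        np.testing.assert_allclose(ca, geom.select("CA"), atol=2e-3)
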