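"""Structure/sequence statistics: parsing, ASA, core packing, RMSD, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemrrm import structcore as sc
from tandemrrm.errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    InputError,
)
from tandemrrm.synthetic_data import gen_toy_structure

from conftest import two_residue_model


# ---------------------------------------------------------------- parsing
class TestReadStructure:
    def test_identity_parse(self, tiny_pdb):
        m = sc.read_structure(tiny_pdb)
        assert m.n_atoms == 3
        np.testing.assert_allclose(m.coords[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(m.coords[2], [3.0, 3.4, 3.0])
        assert m.atomname == ["N", "CA", "CB"]
        assert m.resname == ["ALA"] * 3

    def test_altloc_a_kept(self, altloc_pdb):
        m = sc.read_structure(altloc_pdb)
        assert m.n_atoms == 2
        ca = m.coords[m.atomname.index("CA")]
        np.testing.assert_allclose(ca, [2.5, 2.0, 3.0])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            sc.read_structure(tmp_path / "nope.pdb")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(EmptyInputError):
            sc.read_structure(p)

    def test_pdb_round_trip(self, tmp_path, helix_model):
        out = tmp_path / "helix.pdb"
        sc.write_pdb(helix_model, out)
        back = sc.read_structure(out)
        np.testing.assert_allclose(back.coords, helix_model.coords, atol=1e-3)


# ---------------------------------------------------------------- ASA
class TestResidueASA:
    def test_far_apart_residues_equal(self):
        m = two_residue_model(100.0)
        t = sc.compute_residue_asa(m, n_points=500)
        assert t.asa[1] == pytest.approx(t.asa[2], rel=1e-9)

    def test_point_density_convergence(self):
        # a single isolated residue: doubling the sampling changes ASA < 1%
        m = two_residue_model(100.0)
        lo = sc.compute_residue_asa(m, n_points=960).asa[1]
        hi = sc.compute_residue_asa(m, n_points=1920).asa[1]
        assert abs(lo - hi) / hi < 0.01
        # and matches the analytic area of two fused spheres within 1%
        r = 1.70 + 1.4
        d = 2.0
        cap = 2.0 * np.pi * r * (r - d / 2.0)      # buried cap per sphere
        analytic = 2.0 * (4.0 * np.pi * r**2 - cap)
        assert hi == pytest.approx(analytic, rel=0.01)

    def test_buried_atom_zero(self):
        # central atom caged by 14 tight neighbours contributes nothing
        shells = [
            [2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0],
            [0, 0, 2.0], [0, 0, -2.0],
            [1.2, 1.2, 1.2], [-1.2, 1.2, 1.2], [1.2, -1.2, 1.2],
            [1.2, 1.2, -1.2], [-1.2, -1.2, 1.2], [-1.2, 1.2, -1.2],
            [1.2, -1.2, -1.2], [-1.2, -1.2, -1.2],
        ]
        n = 1 + len(shells)
        m = sc.StructureModel(
            chain=["A"] * n,
            resnum=[1] + [2] * len(shells),
            resname=["ALA"] * n,
            atomname=["CA"] * n,
            element=["C"] * n,
            coords=[[0.0, 0.0, 0.0]] + shells,
        )
        t = sc.compute_residue_asa(m, n_points=960)
        assert t.asa[1] == 0.0

    def test_rigid_motion_invariance(self, helix_model):
        # translation is exact (the sampling grid translates with each atom);
        # rotation is invariant only up to the anisotropy of the finite
        # sphere sampling, which shrinks with the point count
        from scipy.spatial.transform import Rotation

        def moved_copy(coords):
            return sc.StructureModel(
                chain=list(helix_model.chain),
                resnum=helix_model.resnum.copy(),
                resname=list(helix_model.resname),
                atomname=list(helix_model.atomname),
                element=list(helix_model.element),
                coords=coords,
            )

        t0 = sc.compute_residue_asa(helix_model, n_points=960)
        shifted = moved_copy(helix_model.coords + np.array([5.0, -3.0, 12.0]))
        t_shift = sc.compute_residue_asa(shifted, n_points=960)
        for r in t0.asa:
            assert t_shift.asa[r] == pytest.approx(t0.asa[r], rel=1e-9)

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        t_rot = sc.compute_residue_asa(
            moved_copy(helix_model.coords @ rot.T), n_points=960
        )
        for r in t0.asa:
            assert t_rot.asa[r] == pytest.approx(t0.asa[r], rel=0.02)

    def test_cross_check_against_biotite(self, helix_model):
        biotite_struc = pytest.importorskip("biotite.structure")
        n = helix_model.n_atoms
        arr = biotite_struc.AtomArray(n)
        arr.coord = helix_model.coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = helix_model.resnum
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii="Single"
        )
        mine = sc.compute_residue_asa(helix_model, n_points=960)
        got = np.array([mine.asa[r] for r in helix_model.resnum])
        np.testing.assert_allclose(got, ref, rtol=1e-4)

    def test_parameter_validation(self, helix_model):
        with pytest.raises(ConfigurationError):
            sc.compute_residue_asa(helix_model, n_points=10)
        with pytest.raises(ConfigurationError):
            sc.compute_residue_asa(helix_model, probe_radius=0.0)


# ---------------------------------------------------------------- core selection
class TestCoreSelection:
    @pytest.fixture
    def table(self):
        return sc.ASATable(
            asa={1: 5.0, 2: 1.0, 3: 1.0, 4: 9.0, 5: 0.5}, probe_radius=1.4,
            n_points=960,
        )

    def test_lowest_asa_with_tie_rule(self, table):
        dom = sc.DomainDefinition("d", 1, 5)
        got = sc.select_core_residues(table, dom, k=3)
        assert got.residues == [2, 3, 5]     # tie 2/3 broken by lower number

    def test_degenerate_bounds(self, table):
        dom = sc.DomainDefinition("d", 1, 5)
        with pytest.raises(ConfigurationError):
            sc.select_core_residues(table, dom, k=0)
        assert sc.select_core_residues(table, dom, k=5).residues == [1, 2, 3, 4, 5]

    def test_deterministic(self, table):
        dom = sc.DomainDefinition("d", 1, 5)
        a = sc.select_core_residues(table, dom, k=3)
        b = sc.select_core_residues(table, dom, k=3)
        assert a.residues == b.residues


# ---------------------------------------------------------------- packing
class TestPacking:
    def test_two_body_exact(self):
        m = two_residue_model(3.0)
        res = sc.core_packing_distance(m, sc.CoreSet([1, 2]))
        assert res.per_residue == {1: pytest.approx(3.0), 2: pytest.approx(3.0)}
        assert res.mean == pytest.approx(3.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n_res, per = 6, 3
        coords, resnum, names = [], [], []
        centers = rng.normal(scale=6.0, size=(n_res, 3))
        for r in range(n_res):
            for a in range(per):
                coords.append(centers[r] + rng.normal(scale=1.0, size=3))
                resnum.append(r + 1)
                names.append(["CB", "CG", "CD"][a])
        m = sc.StructureModel(
            chain=["A"] * len(coords), resnum=resnum,
            resname=["LYS"] * len(coords), atomname=names,
            element=["C"] * len(coords), coords=np.array(coords),
        )
        core = sc.CoreSet(list(range(1, n_res + 1)))
        res = sc.core_packing_distance(m, core)
        xyz = np.array(coords)
        rn = np.array(resnum)
        for r in core.residues:
            a = xyz[rn == r]
            b = xyz[rn != r]
            brute = np.min(
                np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
            )
            assert res.per_residue[r] == pytest.approx(brute)

    def test_relabeling_and_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        m = two_residue_model(3.7)
        base = sc.core_packing_distance(m, sc.CoreSet([1, 2])).mean
        swapped = sc.core_packing_distance(m, sc.CoreSet([2, 1])).mean
        assert swapped == pytest.approx(base)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        m2 = sc.StructureModel(
            chain=list(m.chain), resnum=m.resnum.copy(),
            resname=list(m.resname), atomname=list(m.atomname),
            element=list(m.element), coords=m.coords @ rot.T + 3.0,
        )
        assert sc.core_packing_distance(m2, sc.CoreSet([1, 2])).mean == (
            pytest.approx(base)
        )

    def test_surrogate_policies(self):
        # glycine-like residue: no side-chain atom; CA surrogate vs exclusion
        m = sc.StructureModel(
            chain=["A"] * 5,
            resnum=[1, 1, 2, 3, 3],
            resname=["ALA", "ALA", "GLY", "ALA", "ALA"],
            atomname=["CA", "CB", "CA", "CA", "CB"],
            element=["C"] * 5,
            coords=[[-2, 0, 0], [0, 0, 0], [3, 0, 0], [8, 0, 0], [6, 0, 0]],
        )
        with_sur = sc.core_packing_distance(m, sc.CoreSet([1, 2, 3]))
        assert with_sur.per_residue[2] == pytest.approx(3.0)
        with pytest.warns(UserWarning):
            without = sc.core_packing_distance(
                m, sc.CoreSet([1, 2, 3]), gly_policy="exclude"
            )
        assert 2 in without.excluded
        assert without.per_residue[1] == pytest.approx(6.0)

    def test_too_small_core(self):
        m = two_residue_model(3.0)
        with pytest.raises(InputError):
            sc.core_packing_distance(m, sc.CoreSet([1]))


# ---------------------------------------------------------------- superposition
class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        _, _, rmsd = sc.superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        b = a @ rot.T + np.array([3.0, -1.0, 8.0])
        _, _, rmsd = sc.superpose_kabsch(a, b)
        assert rmsd <= 1e-9

    def test_against_quaternion_reference(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, _, mine = sc.superpose_kabsch(a, b)
            a0 = a - a.mean(axis=0)
            b0 = b - b.mean(axis=0)
            rot_ref = Rotation.align_vectors(a0, b0)[0].as_matrix()
            ref = np.sqrt(np.mean(np.sum((a0 - b0 @ rot_ref.T) ** 2, axis=1)))
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        _, _, r_ab = sc.superpose_kabsch(a, b)
        _, _, r_ba = sc.superpose_kabsch(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-10)
        assert r_ab >= 0

    def test_size_mismatch(self):
        with pytest.raises(InputError):
            sc.superpose_kabsch(np.zeros((4, 3)), np.zeros((5, 3)))


class TestDomainRMSD:
    def test_self_is_zero(self, helix_model):
        dom = sc.DomainDefinition("d", 1, 12)
        assert sc.domain_rmsd(helix_model, dom, dom) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_displacement(self):
        # two identical helices in one chain, the second rigidly offset:
        # after superposition the RMSD returns to zero
        a = gen_toy_structure("helix", 10)
        coords = np.vstack([a.coords, a.coords + np.array([50.0, 0.0, 0.0])])
        m = sc.StructureModel(
            chain=["A"] * 20, resnum=np.arange(1, 21),
            resname=["ALA"] * 20, atomname=["CA"] * 20,
            element=["C"] * 20, coords=coords,
        )
        rmsd = sc.domain_rmsd(
            m, sc.DomainDefinition("h1", 1, 10), sc.DomainDefinition("h2", 11, 20)
        )
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        # a known per-atom internal distortion d on half the atoms gives
        # rmsd = d·sqrt(fraction) once mean-centred contributions cancel
        perturbed = coords.copy()
        perturbed[15] += np.array([0.0, 0.0, 2.0])
        m2 = sc.StructureModel(
            chain=["A"] * 20, resnum=np.arange(1, 21),
            resname=["ALA"] * 20, atomname=["CA"] * 20,
            element=["C"] * 20, coords=perturbed,
        )
        r2 = sc.domain_rmsd(
            m2, sc.DomainDefinition("h1", 1, 10), sc.DomainDefinition("h2", 11, 20)
        )
        assert r2 > 0.3


# ---------------------------------------------------------------- alignment
def _nw_oracle(a: str, b: str, sub, gap: float):
    """Full-matrix Needleman-Wunsch with linear gaps, free terminal gaps."""
    n, m = len(a), len(b)
    big = -1e18
    f = np.full((n + 1, m + 1), big)
    f[0, :] = 0.0           # free leading gaps
    f[:, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            f[i, j] = max(
                f[i - 1, j - 1] + sub[a[i - 1], b[j - 1]],
                f[i - 1, j] + gap,
                f[i, j - 1] + gap,
            )
    # free trailing gaps: best over the last row/column
    return max(f[n, :].max(), f[:, m].max())


class TestAlignment:
    def test_self_alignment(self):
        s = sc.align_sequences("MKVLITAD", "MKVLITAD")
        assert s.percent_identity == 100.0
        assert s.percent_positives == 100.0
        assert s.aligned_length == 8

    def test_identity_le_positives(self):
        s = sc.align_sequences("MKVLITADWE", "MRVLISADFE")
        assert s.identity_count <= s.positive_count <= s.aligned_length
        assert s.percent_identity == pytest.approx(
            100.0 * s.identity_count / s.aligned_length
        )

    def test_score_matches_dp_oracle(self):
        from Bio.Align import substitution_matrices

        sub = substitution_matrices.load("BLOSUM62")
        toys = [
            ("MKVLITAD", "MKVLGTAD"),
            ("WWKLHEAD", "WKLHEADS"),
            ("ACDEFGHI", "IHGFEDCA"),
            ("PPPPGGGG", "PPGG"),
        ]
        for a, b in toys:
            # linear gap penalty -10 exercised by setting extend == open
            got = sc.align_sequences(a, b, gap_open=-10.0, gap_extend=-10.0)
            assert got.score == pytest.approx(_nw_oracle(a, b, sub, -10.0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            sc.align_sequences("", "MKV")

    @settings(max_examples=25, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12),
    )
    def test_counts_are_consistent(self, a, b):
        s = sc.align_sequences(a, b)
        assert 0 <= s.identity_count <= s.positive_count <= s.aligned_length
        assert len(s.aligned_pairs) <= s.aligned_length
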