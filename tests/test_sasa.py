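"""Shrake-Rupley engine, residue aggregation and RSA normalisation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from afdisorder import sasa
from afdisorder.errors import ConfigurationError, InputError
from .conftest import sasa_dense_oracle

CARBON = 1.7
PROBE = 1.4


def sphere_area(r):
    return 4.0 * np.pi * r * r


class TestShrakeRupley:
    def test_single_sphere_closed_form(self):
        out = sasa.shrake_rupley(np.zeros((1, 3)), np.array([CARBON]),
                                 probe_radius=PROBE, n_points=960)
        assert out[0] == pytest.approx(sphere_area(CARBON + PROBE), rel=0.01)

    def test_distant_pair_no_occlusion(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        out = sasa.shrake_rupley(coords, np.array([CARBON, CARBON]),
                                 probe_radius=PROBE, n_points=960)
        assert out[0] == out[1] == pytest.approx(sphere_area(CARBON + PROBE))

    def test_caged_atom_fully_buried(self):
        # 26 overlapping atoms on the cube directions at 2 A: every sample
        # point of the central atom falls inside a neighbour's expanded sphere
        dirs = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                         for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)],
                        dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], 2.0 * dirs])
        radii = np.full(len(coords), CARBON)
        out = sasa.shrake_rupley(coords, radii, probe_radius=PROBE,
                                 n_points=960)
        assert out[0] == 0.0

    def test_two_sphere_cap_convergence(self):
        # two equal spheres at distance d: each loses a cap of height
        # h = R - d/2, area 2 pi R h -- exact reference for the quadrature
        R, d = CARBON + PROBE, 3.0
        exact = sphere_area(R) - 2 * np.pi * R * (R - d / 2)
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([CARBON, CARBON])
        errs = []
        n = 60
        while n <= 3840:
            out = sasa.shrake_rupley(coords, radii, probe_radius=PROBE,
                                     n_points=n)
            errs.append(abs(out[0] - exact))
            n *= 2
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.01 * exact
        # quadrature error shrinks with n on average; individual doublings
        # wiggle because lattice points shift relative to the occlusion cap
        half = len(errs) // 2
        assert np.mean(errs[half:]) < np.mean(errs[:half])

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            n_atoms = rng.integers(2, 6)
            coords = rng.uniform(0, 4.0, size=(n_atoms, 3))
            radii = rng.uniform(1.2, 2.0, size=n_atoms)
            ours = sasa.shrake_rupley(coords, radii, probe_radius=PROBE,
                                      n_points=960)
            oracle = sasa_dense_oracle(coords, radii, probe=PROBE,
                                       n=100_000, seed=1)
            scale = sphere_area(radii.max() + PROBE)
            np.testing.assert_allclose(ours, oracle, atol=0.02 * scale)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 8, size=(20, 3))
        radii = rng.uniform(1.4, 1.9, size=20)
        base = sasa.shrake_rupley(coords, radii, n_points=240)
        shifted = sasa.shrake_rupley(coords + np.array([123.0, -45.0, 6.7]),
                                     radii, n_points=240)
        np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-9)

    def test_rotation_within_quadrature_tolerance(self):
        # the sample lattice is fixed in the lab frame, so rotating the body
        # perturbs per-atom SASA at the quadrature scale, not to 1e-9
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 8, size=(15, 3))
        radii = np.full(15, CARBON)
        rot = Rotation.from_euler("xyz", [31, -57, 101], degrees=True)
        base = sasa.shrake_rupley(coords, radii, n_points=960)
        rotated = sasa.shrake_rupley(rot.apply(coords), radii, n_points=960)
        np.testing.assert_allclose(rotated, base,
                                   atol=0.02 * sphere_area(CARBON + PROBE))

    def test_occlusion_monotonicity(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = np.full(8, CARBON)
        base = sasa.shrake_rupley(coords, radii, n_points=480)
        for _ in range(5):
            extra = rng.uniform(0, 6, size=(1, 3))
            more = sasa.shrake_rupley(np.vstack([coords, extra]),
                                      np.append(radii, CARBON), n_points=480)
            assert np.all(more[:8] <= base + 1e-9)

    @pytest.mark.parametrize("bad", [
        {"coords": np.array([[np.nan, 0, 0]]), "radii": np.array([1.7])},
        {"coords": np.array([[np.inf, 0, 0]]), "radii": np.array([1.7])},
    ])
    def test_nonfinite_coordinates_rejected(self, bad):
        with pytest.raises(InputError):
            sasa.shrake_rupley(bad["coords"], bad["radii"])

    def test_n_points_must_be_at_least_two(self):
        with pytest.raises(ConfigurationError):
            sasa.shrake_rupley(np.zeros((1, 3)), np.array([1.7]), n_points=1)

    def test_cross_check_against_biopython(self, tmp_path, suite):
        # independent engine on the same radii: Biopython's Shrake-Rupley
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from afdisorder.synthetic_structures import write_model

        target = suite[1]  # a tailed model: exposed and buried residues
        path = tmp_path / "model.pdb"
        write_model(target.spec, path)
        structure = PDBParser(QUIET=True).get_structure("m", str(path))
        ShrakeRupley(probe_radius=PROBE, n_points=960,
                     radii_dict=dict(sasa.DEFAULT_RADII)).compute(
            structure, level="R")
        theirs = np.array([res.sasa for res in structure.get_residues()])

        model = target.model
        coords, radii, res_idx = [], [], []
        rs = sasa.RadiiSet()
        for ch in model.chains:
            for k, res in enumerate(ch.residues):
                for atom in res.atoms:
                    coords.append(atom.coord)
                    radii.append(rs.radius(atom.element))
                    res_idx.append(k)
        atom_sasa = sasa.shrake_rupley(np.array(coords), np.array(radii),
                                       probe_radius=PROBE, n_points=960)
        ours = sasa.residue_asa(atom_sasa, np.array(res_idx))
        assert ours.shape == theirs.shape
        np.testing.assert_allclose(ours, theirs,
                                   atol=0.02 * sphere_area(CARBON + PROBE))


class TestResidueAsa:
    def test_sums_atoms(self):
        out = sasa.residue_asa(np.array([10.0, 5.5, 2.0]),
                               np.array([0, 0, 1]))
        assert out.tolist() == [15.5, 2.0]

    def test_buried_residue_zero(self):
        out = sasa.residue_asa(np.array([0.0, 0.0]), np.array([0, 0]))
        assert out.tolist() == [0.0]

    def test_hydrogens_excluded(self):
        out = sasa.residue_asa(np.array([10.0, 99.0]), np.array([0, 0]),
                               elements=np.array(["C", "H"]))
        assert out.tolist() == [10.0]

    def test_conservation_over_residues(self):
        rng = np.random.default_rng(3)
        atom_sasa = rng.uniform(0, 30, 50)
        idx = rng.integers(0, 7, 50)
        assert sasa.residue_asa(atom_sasa, idx).sum() == pytest.approx(
            atom_sasa.sum())


@pytest.fixture(scope="module")
def table():
    return sasa.MaxAsaTable.from_dialect("sander")


class TestRelativeAccessibility:
    @pytest.mark.parametrize("dialect", ["sander", "wilke", "miller"])
    def test_tables_complete_and_positive(self, dialect):
        table = sasa.MaxAsaTable.from_dialect(dialect)
        assert set("ACDEFGHIKLMNPQRSTVWY") <= set(table.values)
        assert all(v > 0 for v in table.values.values())

    def test_unknown_dialect(self):
        with pytest.raises(ConfigurationError):
            sasa.MaxAsaTable.from_dialect("nope")

    @pytest.mark.parametrize("asa,expected", [
        (0.0, 0.0),
        (None, 1.0),      # asa equal to the maximum
        ("over", 1.0),    # 20% above the maximum: clamped
    ])
    def test_normalisation_and_clamp(self, table, asa, expected):
        max_g = table.max_asa("G")
        value = {None: max_g, "over": 1.2 * max_g}.get(asa, asa)
        assert sasa.relative_accessibility(value, "G", table) == pytest.approx(
            expected)

    def test_unknown_residue_uses_glycine_maximum(self, table):
        assert table.max_asa("X") == table.max_asa("G")

    def test_nonpositive_table_rejected(self):
        values = {aa: 100.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        values["G"] = 0.0
        with pytest.raises(ConfigurationError):
            sasa.MaxAsaTable(values)


DSSP_SNIPPET = """\
==== Secondary Structure Definition by the program DSSP ====  (synthetic)
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O
    1    1 A M              0   0  185      0, 0.0     2,-0.3     0, 0.0
    2    2 A K  H  >        0   0   96      1,-0.2     4,-2.4     2,-0.2
    3        !*             0   0    0      0, 0.0     0, 0.0     0, 0.0
    4    3 A V  H  3        0   0    7      1,-0.3     3,-0.6     0, 0.0
"""


def test_read_dssp_acc(tmp_path):
    """Parse a tiny synthetic DSSP snippet (ACC column only)."""
    path = tmp_path / "model.dssp"
    path.write_text(DSSP_SNIPPET)
    rows = sasa.read_dssp_acc(path)
    assert rows == [("A", 1, "M", 185.0), ("A", 2, "K", 96.0),
                    ("A", 3, "V", 7.0)]


def test_read_dssp_rejects_non_dssp(tmp_path):
    path = tmp_path / "x.txt"
    path.write_text("not dssp\n")
    with pytest.raises(InputError):
        sasa.read_dssp_acc(path)
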