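"""Alignment-tensor SVD fitting, prediction, PDB extraction and R-factor."""

import numpy as np
import pytest

from twosite import rdc
from twosite.synthetic import gen_rdc_set


def random_unit_vectors(n, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return rdc.BondVectorSet({f"r{i}": v[i] for i in range(n)})


def random_tensor(seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3)) * scale
    s = (a + a.T) / 2.0
    s -= np.eye(3) * np.trace(s) / 3.0
    return rdc.AlignmentTensor.from_matrix(s)


class TestCouplingArithmetic:
    @pytest.mark.parametrize(
        "ja, ji, expected", [(-93.0, -93.0, 0.0), (-85.2, -93.0, 7.8), (-93.0, -85.2, -7.8)]
    )
    def test_difference_of_splittings(self, ja, ji, expected):
        assert rdc.rdc_from_couplings(ja, ji) == pytest.approx(expected)


class TestAxialTensor:
    def test_closed_form_angular_dependence(self):
        """Axially symmetric tensor: D = 2*Da along z, -Da in the xy-plane."""
        tensor = rdc.AlignmentTensor.axially_symmetric(da_hz=8.0)
        vectors = rdc.BondVectorSet(
            {"z": (0, 0, 1), "x": (1, 0, 0), "d": (np.sqrt(0.5), 0, np.sqrt(0.5))}
        )
        d = rdc.predict_rdc(tensor, vectors)
        assert d["z"] == pytest.approx(16.0)
        assert d["x"] == pytest.approx(-8.0)
        assert d["d"] == pytest.approx(8.0 * (3 * 0.5 - 1))

    def test_derived_quantities(self):
        tensor = rdc.AlignmentTensor.axially_symmetric(da_hz=8.0, rhombicity=0.3)
        assert tensor.da_hz == pytest.approx(8.0)
        assert tensor.rhombicity == pytest.approx(0.3)


class TestSVDFit:
    def test_exact_recovery_of_generating_tensor(self):
        truth = random_tensor(seed=1)
        vectors = random_unit_vectors(25, seed=2)
        data = gen_rdc_set(truth, vectors)
        fit = rdc.svd_fit(data, vectors)
        np.testing.assert_allclose(fit.tensor.matrix, truth.matrix, atol=1e-8)
        assert fit.r_factor < 1e-8

    def test_traceless_eigenvalues(self):
        vectors = random_unit_vectors(20, seed=3)
        fit = rdc.svd_fit(gen_rdc_set(random_tensor(4), vectors, 0.5, seed=5), vectors)
        evals = np.linalg.eigvalsh(fit.tensor.matrix)
        assert abs(evals.sum()) < 1e-10
        assert abs(fit.tensor.rhombicity) <= 2.0 / 3.0 + 1e-12

    def test_noise_level_sets_r_factor(self):
        """sigma = 0.1 * rms(D) leaves an R-factor of roughly 0.07."""
        truth = random_tensor(seed=6)
        vectors = random_unit_vectors(40, seed=7)
        clean = np.array(list(rdc.predict_rdc(truth, vectors).values()))
        sigma = 0.1 * np.sqrt(np.mean(clean**2))
        rfs = []
        for seed in range(50):
            fit = rdc.svd_fit(gen_rdc_set(truth, vectors, sigma, seed=seed), vectors)
            rfs.append(fit.r_factor)
        assert np.mean(rfs) == pytest.approx(0.07, abs=0.03)

    def test_rotation_invariance(self):
        """Rigidly rotating all bond vectors rotates the tensor, not the fit quality."""
        from scipy.spatial.transform import Rotation

        truth = random_tensor(seed=8)
        vectors = random_unit_vectors(25, seed=9)
        data = gen_rdc_set(truth, vectors)
        rot = Rotation.from_euler("zyz", [31.0, 57.0, -12.0], degrees=True).as_matrix()
        rotated = rdc.BondVectorSet({k: rot @ v for k, v in vectors.vectors.items()})
        fit_rot = rdc.svd_fit(data, rotated)
        assert fit_rot.r_factor < 1e-8
        np.testing.assert_allclose(
            np.linalg.eigvalsh(fit_rot.tensor.matrix),
            np.linalg.eigvalsh(truth.matrix),
            atol=1e-8,
        )

    def test_least_squares_optimality(self):
        """No randomly perturbed tensor scores a lower R-factor on the same data."""
        truth = random_tensor(seed=10)
        vectors = random_unit_vectors(30, seed=11)
        data = gen_rdc_set(truth, vectors, noise_sd=1.0, seed=12)
        fit = rdc.svd_fit(data, vectors)
        d_obs = np.array([data.d_obs[r] for r in fit.residues_used])
        rng = np.random.default_rng(13)
        for _ in range(20):
            other = rdc.AlignmentTensor(fit.tensor.saupe + rng.normal(0, 0.5, 5))
            d_alt = rdc.predict_rdc(other, vectors)
            alt = rdc.r_factor(d_obs, np.array([d_alt[r] for r in fit.residues_used]))
            assert alt >= fit.r_factor - 1e-12

    def test_too_few_or_degenerate_vectors_rejected(self):
        truth = random_tensor(seed=14)
        small = random_unit_vectors(4, seed=15)
        with pytest.raises(ValueError):
            rdc.svd_fit(gen_rdc_set(truth, small), small)
        collinear = rdc.BondVectorSet({f"r{i}": (0.0, 0.0, 1.0) for i in range(6)})
        with pytest.raises(ValueError):
            rdc.svd_fit(rdc.RDCSet({f"r{i}": 5.0 for i in range(6)}), collinear)


class TestRFactor:
    def test_perfect_agreement(self):
        assert rdc.r_factor([5.0, -3.0], [5.0, -3.0]) == 0.0

    def test_uninformative_prediction(self):
        assert rdc.r_factor([5.0, -3.0, 8.0], [0.0, 0.0, 0.0]) == pytest.approx(
            1.0 / np.sqrt(2.0)
        )

    def test_scale_invariance(self):
        obs, calc = np.array([5.0, -3.0, 8.0]), np.array([4.0, -2.0, 9.0])
        assert rdc.r_factor(3.7 * obs, 3.7 * calc) == pytest.approx(
            rdc.r_factor(obs, calc), rel=1e-12
        )

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            rdc.r_factor([0.0, 0.0], [1.0, 2.0])


class TestPDBExtraction:
    PDB_TEMPLATE = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H
ATOM      3  CA  ALA A   1       0.500   1.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00  0.00           N
ATOM      5  H   GLY A   2       3.000   1.000   0.000  1.00  0.00           H
ATOM      6  CA  GLY A   2       3.500   0.500   1.000  1.00  0.00           C
ATOM      7  N   PRO A   3       6.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  PRO A   3       6.500   1.000   0.000  1.00  0.00           C
ATOM      9  N   SER A   4       9.000   0.000   0.000  1.00  0.00           N
ATOM     10  H   SER A   4       9.000   0.000   2.000  1.00  0.00           H
ENDMDL
END
"""

    @pytest.fixture
    def pdb_file(self, tmp_path):
        path = tmp_path / "synthetic_axis_aligned.pdb"
        path.write_text(self.PDB_TEMPLATE)
        return path

    def test_axis_aligned_unit_vectors(self, pdb_file):
        vecs = rdc.extract_nh_vectors(pdb_file, chain="A")
        np.testing.assert_allclose(vecs.vectors["A:1"], (1, 0, 0), atol=1e-12)
        np.testing.assert_allclose(vecs.vectors["A:2"], (0, 1, 0), atol=1e-12)
        np.testing.assert_allclose(vecs.vectors["A:4"], (0, 0, 1), atol=1e-12)

    def test_proline_skipped(self, pdb_file):
        vecs = rdc.extract_nh_vectors(pdb_file, chain="A")
        assert "A:3" not in vecs.vectors

    def test_norms_are_unity(self, pdb_file):
        vecs = rdc.extract_nh_vectors(pdb_file)
        for v in vecs.vectors.values():
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-6)

    def test_missing_chain_rejected(self, pdb_file):
        with pytest.raises(ValueError):
            rdc.extract_nh_vectors(pdb_file, chain="Q")
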