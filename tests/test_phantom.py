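"""Phantom construction, rotation ground truth, DWI forward model, noise, I/O."""
import numpy as np
import pytest

import alps_reorient.phantom as ph
from alps_reorient.acquisition import AcquisitionSpec, GradientTable, generate_gradient_table
from alps_reorient.dwi_io import read_dataset, write_dataset


@pytest.fixture(scope="module")
def phantom(small_acq=None):
    return ph.build_tensor_phantom(ph.PhantomSpec(), AcquisitionSpec(grid_shape=(32, 32, 16)))


class TestBuildTensorPhantom:
    def test_projection_region_dzz_exact(self, phantom):
        proj = np.isin(phantom.labels, [ph.PROJ_L, ph.PROJ_R])
        assert proj.any()
        assert np.all(phantom.tensors[proj][:, 2, 2] == 1.40e-3)

    def test_all_tensors_spd(self, phantom):
        evals = np.linalg.eigvalsh(phantom.tensors.reshape(-1, 3, 3))
        assert evals.min() > 0

    def test_left_right_mirror_symmetry(self, phantom):
        # flip along x and swap L/R labels -> identical map
        swap = {ph.PROJ_L: ph.PROJ_R, ph.PROJ_R: ph.PROJ_L,
                ph.ASSOC_L: ph.ASSOC_R, ph.ASSOC_R: ph.ASSOC_L}
        flipped = phantom.labels[::-1, :, :].copy()
        relabeled = flipped.copy()
        for a, b in swap.items():
            relabeled[flipped == a] = b
        np.testing.assert_array_equal(relabeled, phantom.labels)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            ph.build_tensor_phantom(ph.PhantomSpec(), AcquisitionSpec(grid_shape=(16, 16, 8)))


class TestRotatePhantom:
    def test_identity_is_bitwise_noop(self, phantom):
        out = ph.rotate_phantom(phantom, ph.RotationSpec((0.0, 0.0, 0.0)))
        np.testing.assert_array_equal(out.tensors, phantom.tensors)
        np.testing.assert_array_equal(out.labels, phantom.labels)

    def test_90deg_z_permutes_diagonal(self, phantom):
        out = ph.rotate_phantom(phantom, ph.RotationSpec((0.0, 0.0, 90.0)))
        # a diag(a,b,c) tensor becomes diag(b,a,c) wherever tissue rotated
        proj = np.isin(out.labels, [ph.PROJ_L, ph.PROJ_R])
        t = out.tensors[proj]
        np.testing.assert_allclose(t[:, 0, 0], 0.40e-3, atol=1e-18)
        np.testing.assert_allclose(t[:, 1, 1], 0.55e-3, atol=1e-18)
        np.testing.assert_allclose(t[:, 2, 2], 1.40e-3, atol=1e-18)

    def test_15deg_x_closed_form_dyy(self, phantom):
        # direct matrix arithmetic R D R^T for the projection tensor
        out = ph.rotate_phantom(phantom, ph.RotationSpec((15.0, 0.0, 0.0)))
        c, s = np.cos(np.deg2rad(15)), np.sin(np.deg2rad(15))
        expected = c**2 * 0.40e-3 + s**2 * 1.40e-3
        assert expected == pytest.approx(0.467e-3, abs=1e-6)
        proj = np.isin(out.labels, [ph.PROJ_L, ph.PROJ_R])
        np.testing.assert_allclose(out.tensors[proj][:, 1, 1], expected, atol=1e-18)

    def test_eigenvalue_multiset_preserved(self, phantom):
        out = ph.rotate_phantom(phantom, ph.RotationSpec((12.0, -7.0, 23.0), (1.0, -2.0, 0.5)))
        for lab, D in phantom.region_tensors.items():
            voxels = out.labels == lab
            if not voxels.any():
                continue
            got = np.sort(np.linalg.eigvalsh(out.tensors[voxels][0]))
            np.testing.assert_allclose(got, np.sort(np.linalg.eigvalsh(D)), atol=1e-18)

    def test_out_of_grid_preimage_becomes_background(self, phantom):
        out = ph.rotate_phantom(phantom, ph.RotationSpec((0, 0, 0), translation=(200.0, 0, 0)))
        assert np.all(out.labels == ph.BACKGROUND)


class TestSimulateDwi:
    def test_isotropic_closed_form(self):
        gtab = generate_gradient_table(8, 1, 1000.0, seed=1)
        d = 0.8e-3
        tensors = np.tile(d * np.eye(3), (2, 2, 2, 1, 1))
        field = ph.TensorPhantom(tensors, np.zeros((2, 2, 2), np.int8), np.eye(4), {})
        dwi = ph.simulate_dwi(field, gtab, s0=1000.0)
        assert np.all(dwi.signal[..., 0] == 1000.0)  # b = 0
        np.testing.assert_allclose(dwi.signal[..., 1:], 1000.0 * np.exp(-1000.0 * d), rtol=1e-12)

    def test_single_axis_tensor_closed_form(self):
        gtab = GradientTable(np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([0.0, 1000.0]))
        D = np.zeros((1, 1, 1, 3, 3))
        D[..., 0, 0] = 1e-3
        field = ph.TensorPhantom(D, np.zeros((1, 1, 1), np.int8), np.eye(4), {})
        dwi = ph.simulate_dwi(field, gtab, s0=1000.0)
        assert dwi.signal[0, 0, 0, 1] == pytest.approx(1000.0 / np.e, rel=1e-12)

    def test_negative_eigenvalue_rejected_with_voxel(self):
        gtab = generate_gradient_table(8, 1, 1000.0, seed=1)
        D = np.tile(0.8e-3 * np.eye(3), (2, 2, 2, 1, 1))
        D[1, 0, 1] = np.diag([1e-3, -1e-4, 1e-3])
        field = ph.TensorPhantom(D, np.zeros((2, 2, 2), np.int8), np.eye(4), {})
        with pytest.raises(ValueError, match=r"\(1, 0, 1\)"):
            ph.simulate_dwi(field, gtab, s0=1000.0)

    def test_log_signal_linear_in_b(self):
        # same direction at several b values: ln S must fall on a line
        g = np.array([0.6, 0.64, 0.48])
        g /= np.linalg.norm(g)
        bvals = np.array([0.0, 250.0, 500.0, 1000.0])
        gtab = GradientTable(np.vstack([np.zeros(3), g, g, g]), bvals)
        D = np.tile(np.diag([1.4e-3, 0.5e-3, 0.3e-3]), (1, 1, 1, 1, 1))
        dwi = ph.simulate_dwi(ph.TensorPhantom(D, np.zeros((1, 1, 1), np.int8), np.eye(4), {}), gtab, 100.0)
        lnS = np.log(dwi.signal[0, 0, 0])
        slopes = np.diff(lnS[1:]) / np.diff(bvals[1:])
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)
        assert np.all(dwi.signal > 0) and np.all(dwi.signal <= 100.0)


class TestRicianNoise:
    def _flat_dwi(self, value=0.0, n=100000):
        gtab = GradientTable(np.zeros((1, 3)), np.zeros(1))
        sig = np.full((n, 1, 1, 1), value, dtype=float)
        return ph.DwiDataset(sig, gtab, np.eye(4))

    def test_infinite_snr_is_identity(self, small_template):
        dwi = ph.simulate_dwi(small_template.phantom, small_template.gradient_table, 1000.0)
        out = ph.add_rician_noise(dwi, np.inf, seed=0)
        np.testing.assert_array_equal(out.signal, dwi.signal)

    def test_seed_determinism(self):
        dwi = self._flat_dwi(100.0, n=64)
        a = ph.add_rician_noise(dwi, 30.0, seed=9, s0=100.0)
        b = ph.add_rician_noise(dwi, 30.0, seed=9, s0=100.0)
        np.testing.assert_array_equal(a.signal, b.signal)
        c = ph.add_rician_noise(dwi, 30.0, seed=10, s0=100.0)
        assert not np.array_equal(a.signal, c.signal)

    def test_zero_signal_gives_rayleigh_mean(self):
        # S=0, sigma=1: magnitude is Rayleigh with mean sigma*sqrt(pi/2)
        dwi = self._flat_dwi(0.0)
        out = ph.add_rician_noise(dwi, snr=1.0, seed=3, s0=1.0)
        assert out.signal.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_invalid_snr_rejected(self):
        dwi = self._flat_dwi(1.0, n=2)
        with pytest.raises(ValueError, match="snr"):
            ph.add_rician_noise(dwi, 0.0, seed=0)


class TestDatasetIo:
    def test_round_trip(self, tmp_path, small_template):
        dwi = ph.simulate_dwi(small_template.phantom, small_template.gradient_table, 1000.0)
        write_dataset(dwi, tmp_path)
        back = read_dataset(tmp_path / "dwi.nii.gz")
        np.testing.assert_allclose(back.signal, dwi.signal, rtol=1e-6)  # float32 storage
        np.testing.assert_allclose(back.gradient_table.bvecs, dwi.gradient_table.bvecs, atol=1e-9)
        np.testing.assert_allclose(back.affine, dwi.affine, atol=1e-5)

    def test_volume_count_mismatch_rejected(self, tmp_path, small_template):
        dwi = ph.simulate_dwi(small_template.phantom, small_template.gradient_table, 1000.0)
        paths = write_dataset(dwi, tmp_path)
        truncated = dwi.gradient_table
        np.savetxt(paths["bvals"], truncated.bvals[None, :-1], fmt="%.6g")
        np.savetxt(paths["bvecs"], truncated.bvecs[:-1].T, fmt="%.10g")
        with pytest.raises(ValueError, match="volumes"):
            read_dataset(paths["dwi"])


class TestSubjectVariation:
    def test_perivascular_scale_only_touches_fiber_dxx(self):
        rng = np.random.default_rng(0)
        spec = ph.subject_phantom_spec(ph.PhantomSpec(), 0.1, rng)
        base = ph.PhantomSpec()
        s = spec.perivascular_scale
        assert s != 1.0
        for lab in (ph.PROJ_L, ph.ASSOC_R):
            np.testing.assert_allclose(
                spec.region_tensors[lab][0, 0], base.region_tensors[lab][0, 0] * s
            )
            np.testing.assert_allclose(
                np.diag(spec.region_tensors[lab])[1:], np.diag(base.region_tensors[lab])[1:]
            )
        np.testing.assert_allclose(spec.region_tensors[ph.CSF], base.region_tensors[ph.CSF])

    def test_zero_sd_is_identity(self):
        rng = np.random.default_rng(0)
        spec = ph.subject_phantom_spec(ph.PhantomSpec(), 0.0, rng)
        assert spec.perivascular_scale == 1.0
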