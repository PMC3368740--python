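"""DWI I/O, tensor fitting and resampling tests.

The fitting oracle is the forward signal model S_i = S0 exp(-b g^T D g):
signals synthesized from a known tensor must fit back to it exactly in
the noise-free case.
"""

import numpy as np
import pytest

from ccdtiseg.dti_io import (
    GradientTable,
    ScalarVolume,
    TensorVolume,
    fit_tensors,
    read_dwi,
    read_tensor_nifti,
    resample_isotropic,
    write_tensor_nifti,
)
from ccdtiseg.tensor_features import principal_direction


def make_gradient_table(n_dirs=25, rng_seed=0):
    """b=0 volume + n_dirs unit directions spread over the sphere."""
    rng = np.random.default_rng(rng_seed)
    dirs = rng.normal(size=(n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_dirs, 1000.0)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def forward_signals(D, gtab, s0=1000.0):
    sig = np.empty(len(gtab))
    for i, (b, g) in enumerate(zip(gtab.bvals, gtab.bvecs)):
        sig[i] = s0 * np.exp(-b * g @ D @ g)
    return sig


class TestGradientTable:
    def test_validates_counts_and_norms(self):
        gtab = make_gradient_table()
        assert len(gtab) == 26
        assert gtab.b0_mask.sum() == 1

    def test_rejects_missing_b0(self):
        with pytest.raises(ValueError, match="b=0"):
            GradientTable(bvals=[1000.0, 1000.0], bvecs=[[1, 0, 0], [0, 1, 0]])

    def test_rejects_count_mismatch(self):
        with pytest.raises(ValueError, match="row counts"):
            GradientTable(bvals=[0.0, 1000.0, 1000.0], bvecs=[[0, 0, 0], [1, 0, 0]])

    def test_rejects_non_unit_direction(self):
        with pytest.raises(ValueError, match="unit norm"):
            GradientTable(bvals=[0.0, 1000.0], bvecs=[[0, 0, 0], [2, 0, 0]])


class TestReadDwi(object):
    def _write(self, tmp_path, n_vols, n_rows, with_b0=True):
        import nibabel as nib

        data = np.ones((4, 4, 4, n_vols), dtype=np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "dwi.nii.gz"))
        bvals = np.full(n_rows, 1000.0)
        if with_b0:
            bvals[0] = 0.0
        rng = np.random.default_rng(1)
        bvecs = rng.normal(size=(n_rows, 3))
        bvecs /= np.linalg.norm(bvecs, axis=1, keepdims=True)
        if with_b0:
            bvecs[0] = 0.0
        np.savetxt(tmp_path / "f.bval", bvals[None])
        np.savetxt(tmp_path / "f.bvec", bvecs.T)
        return tmp_path / "dwi.nii.gz", tmp_path / "f.bval", tmp_path / "f.bvec"

    def test_roundtrip(self, tmp_path):
        dwi, bv, bc = self._write(tmp_path, 26, 26)
        data, gtab, vs = read_dwi(dwi, bv, bc)
        assert data.shape == (4, 4, 4, 26)
        assert len(gtab) == 26

    def test_row_count_mismatch(self, tmp_path):
        dwi, bv, bc = self._write(tmp_path, 26, 25)
        with pytest.raises(ValueError, match="25 rows"):
            read_dwi(dwi, bv, bc)

    def test_missing_b0(self, tmp_path):
        dwi, bv, bc = self._write(tmp_path, 26, 26, with_b0=False)
        with pytest.raises(ValueError, match="b=0"):
            read_dwi(dwi, bv, bc)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dwi(tmp_path / "absent.nii.gz", "x", "y")


class TestFitTensors:
    def test_recovers_known_tensor(self):
        gtab = make_gradient_table()
        D = np.array(
            [
                [1.5e-3, 2e-4, 1e-4],
                [2e-4, 0.6e-3, 5e-5],
                [1e-4, 5e-5, 0.4e-3],
            ]
        )
        dwi = np.tile(forward_signals(D, gtab), (3, 3, 3, 1))
        tv = fit_tensors(dwi, gtab)
        assert np.allclose(tv.tensors, D, atol=1e-8)

    def test_isotropic_signals_give_fa_zero(self):
        gtab = make_gradient_table()
        D = 0.8e-3 * np.eye(3)
        dwi = np.tile(forward_signals(D, gtab), (2, 2, 2, 1))
        tv = fit_tensors(dwi, gtab)
        w = np.linalg.eigvalsh(tv.tensors[0, 0, 0])
        assert np.ptp(w) < 1e-8

    def test_pdd_of_fitted_prolate_tensor(self):
        gtab = make_gradient_table()
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        dwi = np.tile(forward_signals(D, gtab), (2, 2, 2, 1))
        tv = fit_tensors(dwi, gtab)
        p = principal_direction(tv.tensors[0, 0, 0])
        assert np.arccos(np.clip(abs(p[0]), 0, 1)) < 1e-6

    def test_requires_six_directions(self):
        gtab = make_gradient_table(n_dirs=5)
        with pytest.raises(ValueError, match=">= 6"):
            fit_tensors(np.ones((2, 2, 2, 6)), gtab)

    def test_zero_s0_voxels_get_zero_tensor(self):
        gtab = make_gradient_table()
        D = np.diag([1.0e-3, 0.5e-3, 0.5e-3])
        dwi = np.tile(forward_signals(D, gtab), (2, 2, 2, 1))
        dwi[0, 0, 0] = 0.0
        tv = fit_tensors(dwi, gtab)
        assert np.allclose(tv.tensors[0, 0, 0], 0.0)
        assert not np.allclose(tv.tensors[1, 1, 1], 0.0)

    def test_negative_eigenvalues_clamped(self):
        gtab = make_gradient_table()
        rng = np.random.default_rng(5)
        dwi = rng.uniform(100, 1000, size=(3, 3, 3, 26))
        tv = fit_tensors(dwi, gtab)
        w = np.linalg.eigvalsh(tv.tensors)
        assert w.min() >= -1e-15


class TestResample:
    def test_identity_when_at_target(self):
        tv = TensorVolume(
            tensors=np.tile(np.eye(3) * 1e-3, (4, 4, 4, 1, 1)),
            voxel_size=[1.9, 1.9, 1.9],
        )
        assert resample_isotropic(tv, 1.9) is tv

    def test_anisotropic_to_iso_shape(self):
        # clinical in-plane 0.98 mm / 2.5 mm slices onto the 1.9 mm grid
        vol = ScalarVolume(
            values=np.zeros((256, 256, 20)), voxel_size=[0.98, 0.98, 2.5]
        )
        out = resample_isotropic(vol, 1.9)
        assert out.shape[0] == int((255 * 0.98) // 1.9) + 1 == 132
        assert np.allclose(out.voxel_size, 1.9)

    def test_constant_volume_stays_constant(self):
        vol = ScalarVolume(values=np.full((10, 10, 10), 7.0), voxel_size=[1, 1, 2])
        out = resample_isotropic(vol, 1.5)
        assert np.allclose(out.values, 7.0)

    def test_range_preserved_componentwise(self):
        rng = np.random.default_rng(2)
        comps = rng.normal(size=(6, 6, 6, 3, 3)) * 1e-3
        comps = 0.5 * (comps + np.swapaxes(comps, 3, 4))
        tv = TensorVolume(tensors=comps, voxel_size=[1, 1, 1])
        out = resample_isotropic(tv, 0.7)
        for i in range(3):
            for j in range(3):
                assert out.tensors[..., i, j].max() <= comps[..., i, j].max() + 1e-12
                assert out.tensors[..., i, j].min() >= comps[..., i, j].min() - 1e-12

    def test_rejects_nonpositive_target(self):
        vol = ScalarVolume(values=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


def test_tensor_nifti_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    t = rng.normal(size=(5, 6, 7, 3, 3)) * 1e-3
    t = 0.5 * (t + np.swapaxes(t, 3, 4))
    tv = TensorVolume(tensors=t, voxel_size=[1.9, 1.9, 1.9])
    write_tensor_nifti(tv, tmp_path / "t.nii.gz")
    back = read_tensor_nifti(tmp_path / "t.nii.gz")
    assert np.allclose(back.tensors, tv.tensors, atol=1e-9)  # float32 storage
    assert np.allclose(back.voxel_size, 1.9)
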