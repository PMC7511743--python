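"""Lesion-stack handling, incidence masking, voxel fits, FDR, NIfTI I/O."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from wmhmap import br_glm, voxelwise
from wmhmap._design import build_design


def _tiny_stack(rng, n=40, dims=(5, 4, 3)):
    data = (rng.random((n,) + dims) < 0.3).astype(np.uint8)
    return voxelwise.LesionStack(data=data,
                                 brain_mask=np.ones(dims, dtype=bool),
                                 affine=np.eye(4))


class TestStackBasics:
    def test_load_counts(self, rng):
        assert voxelwise.compute_wmh_load(np.zeros((4, 4, 4))) == 0
        vol = np.zeros((10, 10, 10))
        vol[2:7, 2:7, 2:7] = 1
        assert voxelwise.compute_wmh_load(vol) == 125
        rand = (rng.random((6, 6, 6)) < 0.4).astype(int)
        assert voxelwise.compute_wmh_load(rand) == int(rand.ravel().sum())
        with pytest.raises(ValueError, match="binary"):
            voxelwise.compute_wmh_load(np.full((2, 2, 2), 0.7))

    def test_incidence_threshold(self, rng):
        dims = (3, 3, 3)
        data = np.zeros((10,) + dims, dtype=np.uint8)
        data[:3, 0, 0, 0] = 1   # 3 subjects -> excluded at min_count=4
        data[:4, 1, 0, 0] = 1   # 4 subjects -> included
        stack = voxelwise.LesionStack(data=data,
                                      brain_mask=np.ones(dims, bool),
                                      affine=np.eye(4))
        mask = voxelwise.build_incidence_mask(stack, min_count=4)
        assert not mask[0, 0, 0] and mask[1, 0, 0]
        assert voxelwise.build_incidence_mask(stack, min_count=5).sum() == 0
        # monotone decreasing in min_count; never includes zero-lesion voxels
        prev = None
        for mc in (1, 2, 3, 4, 5):
            cur = voxelwise.build_incidence_mask(stack, min_count=mc)
            assert not np.any(cur & (data.sum(axis=0) == 0))
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur
        with pytest.raises(ValueError):
            voxelwise.build_incidence_mask(stack, min_count=0)

    def test_empty_stack_incidence(self):
        dims = (2, 2, 2)
        stack = voxelwise.LesionStack(data=np.zeros((5,) + dims, np.uint8),
                                      brain_mask=np.ones(dims, bool),
                                      affine=np.eye(4))
        assert voxelwise.build_incidence_mask(stack).sum() == 0

    def test_empirical_probability(self):
        dims = (2, 2, 1)
        a = np.zeros(dims); a[0, 0, 0] = 1
        b = np.zeros(dims); b[1, 1, 0] = 1
        stack = voxelwise.LesionStack(
            data=np.stack([a, b]).astype(np.uint8),
            brain_mask=np.ones(dims, bool), affine=np.eye(4))
        prob = voxelwise.empirical_probability_map(stack)
        assert prob[0, 0, 0] == 0.5 and prob[1, 1, 0] == 0.5
        one = voxelwise.LesionStack(data=a[None].astype(np.uint8),
                                    brain_mask=np.ones(dims, bool),
                                    affine=np.eye(4))
        assert np.array_equal(voxelwise.empirical_probability_map(one), a)
        quarter = voxelwise.LesionStack(
            data=np.stack([a, a, b, b]).astype(np.uint8),
            brain_mask=np.ones(dims, bool), affine=np.eye(4))
        sq = voxelwise.empirical_probability_map(quarter, sqrt_transform=True)
        assert sq[0, 0, 0] == pytest.approx(np.sqrt(0.5))


class TestNiftiIO:
    def test_read_stack_roundtrip_and_errors(self, tmp_path, rng):
        dims = (4, 4, 3)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        paths = []
        for i in range(3):
            vol = (rng.random(dims) < 0.4).astype(np.uint8)
            p = tmp_path / f"sub{i}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), p)
            paths.append(p)
        maskp = tmp_path / "brain.nii.gz"
        nib.save(nib.Nifti1Image(np.ones(dims, dtype=np.uint8), affine), maskp)
        stack = voxelwise.read_lesion_stack(paths, maskp)
        assert stack.n_subjects == 3 and stack.grid_dims == dims

        bad_dim = tmp_path / "bad_dim.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((5, 4, 3), np.uint8), affine), bad_dim)
        with pytest.raises(ValueError, match="bad_dim"):
            voxelwise.read_lesion_stack(paths + [bad_dim], maskp)

        nonbin = tmp_path / "nonbin.nii.gz"
        nib.save(nib.Nifti1Image(np.full(dims, 0.7, np.float32), affine), nonbin)
        with pytest.raises(ValueError, match="non-binary"):
            voxelwise.read_lesion_stack(paths + [nonbin], maskp)

        bad_aff = tmp_path / "bad_aff.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros(dims, np.uint8), np.eye(4)), bad_aff)
        with pytest.raises(ValueError, match="affine"):
            voxelwise.read_lesion_stack(paths + [bad_aff], maskp)

    def test_write_stat_map_roundtrip(self, tmp_path, rng):
        dims = (4, 3, 2)
        vol = rng.standard_normal(dims)
        mask = rng.random(dims) < 0.6
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-90, -126, -72]
        path = tmp_path / "stat.nii.gz"
        voxelwise.write_stat_map(vol, mask, path, affine=affine)
        img = nib.load(path)
        back = np.asarray(img.dataobj)
        assert np.allclose(back[mask], vol[mask].astype(np.float32))
        assert np.all(np.isnan(back[~mask]))
        assert np.allclose(img.affine, affine, atol=1e-6)


class TestVoxelwiseFit:
    def test_single_voxel_matches_direct_fit(self, small_cohort):
        cfg, table, stack, truth = small_cohort
        vox = (6, 6, 3)
        mask = np.zeros(stack.grid_dims, dtype=bool)
        mask[vox] = True
        terms = ["age", "female", "head_size", "hypertension"]
        inter = [("age", "female")]
        ms = voxelwise.fit_voxelwise_model(stack, table, terms, inter,
                                           analysis_mask=mask)
        design = build_design(table, terms, inter)
        y = stack.data[(slice(None),) + vox].astype(float)
        direct = br_glm.fit_binary_glm(
            br_glm.BinaryDesign(X=design.X, y=y), estimator="BR")
        for k, name in enumerate(design.names):
            assert ms.maps[name]["estimate"][vox] == pytest.approx(
                direct.estimates[k], abs=1e-12)
            assert ms.maps[name]["se"][vox] == pytest.approx(direct.se[k],
                                                             abs=1e-12)

    def test_subject_permutation_invariance(self, rng):
        n, dims = 60, (4, 3, 2)
        table = pd.DataFrame({"x": rng.standard_normal(n)})
        data = (rng.random((n,) + dims) < 0.4).astype(np.uint8)
        stack = voxelwise.LesionStack(data=data,
                                      brain_mask=np.ones(dims, bool),
                                      affine=np.eye(4))
        ms1 = voxelwise.fit_voxelwise_model(stack, table, ["x"], min_count=4)
        perm = rng.permutation(n)
        stack2 = voxelwise.LesionStack(data=data[perm],
                                       brain_mask=np.ones(dims, bool),
                                       affine=np.eye(4))
        ms2 = voxelwise.fit_voxelwise_model(stack2, table.iloc[perm].reset_index(drop=True),
                                            ["x"], min_count=4)
        for name in ms1.coef_names:
            np.testing.assert_allclose(ms1.maps[name]["z"], ms2.maps[name]["z"],
                                       atol=1e-10, equal_nan=True)

    def test_misalignment_and_empty_mask_errors(self, rng):
        stack = _tiny_stack(rng)
        short = pd.DataFrame({"x": np.zeros(stack.n_subjects - 1)})
        with pytest.raises(ValueError, match="rows"):
            voxelwise.fit_voxelwise_model(stack, short, ["x"])
        table = pd.DataFrame({"x": rng.standard_normal(stack.n_subjects)})
        with pytest.raises(ValueError, match="empty analysis mask"):
            voxelwise.fit_voxelwise_model(stack, table, ["x"],
                                          min_count=stack.n_subjects + 1)


def _brute_force_bh(p, alpha):
    """sort, m*p(i)/i, cummin from the top, unsort; reject q <= alpha."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


class TestFdr:
    def test_examples(self):
        mask = np.ones(100, dtype=bool).reshape(10, 10, 1)
        q, sig = voxelwise.fdr_correct(np.full((10, 10, 1), 0.01), mask, 0.05)
        assert np.all(sig == 1)
        single = np.ones((1, 1, 1), dtype=bool)
        q, _ = voxelwise.fdr_correct(np.full((1, 1, 1), 0.03), single, 0.05)
        assert q[0, 0, 0] == pytest.approx(0.03)

    def test_matches_brute_force(self, rng):
        p = np.array([0.01, 0.04, 0.03, 0.05]).reshape(4, 1, 1)
        mask = np.ones((4, 1, 1), dtype=bool)
        q, sig = voxelwise.fdr_correct(p, mask, 0.05)
        bq, bsig = _brute_force_bh(p.ravel(), 0.05)
        np.testing.assert_allclose(q.ravel(), bq, atol=1e-12)
        np.testing.assert_array_equal(sig.ravel().astype(bool), bsig)
        for _ in range(25):
            m = int(rng.integers(1, 200))
            pv = rng.random(m).reshape(m, 1, 1)
            q, sig = voxelwise.fdr_correct(pv, np.ones((m, 1, 1), bool), 0.05)
            bq, bsig = _brute_force_bh(pv.ravel(), 0.05)
            np.testing.assert_allclose(q.ravel(), bq, atol=1e-12)
            np.testing.assert_array_equal(sig.ravel().astype(bool), bsig)

    def test_q_dominates_p_and_alpha_monotone(self, rng):
        pv = rng.random(500).reshape(500, 1, 1)
        mask = np.ones((500, 1, 1), bool)
        q, sig05 = voxelwise.fdr_correct(pv, mask, 0.05)
        assert np.all(q[mask] >= pv[mask] - 1e-15)
        _, sig01 = voxelwise.fdr_correct(pv, mask, 0.01)
        assert np.nansum(sig01) <= np.nansum(sig05)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            voxelwise.fdr_correct(np.ones((2, 2, 1)), np.zeros((2, 2, 1), bool))
        with pytest.raises(ValueError, match="p-values"):
            voxelwise.fdr_correct(np.full((2, 1, 1), 1.5),
                                  np.ones((2, 1, 1), bool))


class TestSummary:
    def test_published_scale_arithmetic(self):
        """4,705 significant of 40,001 analysed voxels reports as 11.8%."""
        m = 40_001
        sig = np.zeros(m)
        sig[:4_705] = 1.0
        mapset = voxelwise.VoxelMapSet(
            maps={"hypertension": {"significant": sig.reshape(m, 1, 1)}},
            coef_names=["hypertension"],
            analysis_mask=np.ones((m, 1, 1), bool),
            alpha_fdr=0.05, affine=np.eye(4))
        tab = voxelwise.summarize_significant_voxels(mapset)
        assert tab.loc[0, "count"] == 4_705
        assert tab.loc[0, "percent"] == 11.8

    def test_empty_and_brute_force_counts(self, rng):
        m = 57
        sig = (rng.random(m) < 0.3).astype(float)
        mapset = voxelwise.VoxelMapSet(
            maps={"a": {"significant": sig.reshape(m, 1, 1)},
                  "b": {"significant": np.zeros((m, 1, 1))}},
            coef_names=["a", "b"],
            analysis_mask=np.ones((m, 1, 1), bool),
            alpha_fdr=0.05, affine=np.eye(4))
        tab = voxelwise.summarize_significant_voxels(mapset).set_index("term")
        assert tab.loc["a", "count"] == int(sig.sum())
        assert tab.loc["b", "count"] == 0 and tab.loc["b", "percent"] == 0.0
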