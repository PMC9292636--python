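import numpy as np
import pytest
from scipy import ndimage

from petmrac import atlas, phantom, preprocess as pp
from petmrac.atlas import AtlasDataset, AtlasEntry


class TestSignedDistance:
    def test_single_voxel_neighbors(self):
        m = np.zeros((11, 11), bool)
        m[5, 5] = True
        sd = atlas.signed_distance(m, (1.0, 1.0))
        assert sd[5, 5] == 0.0  # boundary voxel
        assert sd[5, 6] == 1.0
        assert np.isclose(sd[6, 6], np.sqrt(2))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            atlas.signed_distance(np.zeros((5, 5), bool), (1.0, 1.0))
        with pytest.raises(ValueError):
            atlas.signed_distance(np.ones((5, 5), bool), (1.0, 1.0))

    def test_square_matches_brute_force(self):
        m = np.zeros((15, 15), bool)
        m[2:13, 2:13] = True
        spacing = (2.0, 1.5)
        sd = atlas.signed_distance(m, spacing)
        boundary = m & ~ndimage.binary_erosion(m)
        bidx = np.argwhere(boundary) * np.asarray(spacing)
        for iy in range(15):
            for ix in range(15):
                p = np.array([iy * spacing[0], ix * spacing[1]])
                d = np.sqrt(((bidx - p) ** 2).sum(axis=1)).min()
                expected = -d if m[iy, ix] else d
                assert np.isclose(sd[iy, ix], expected), (iy, ix)

    def test_anisotropic_spacing_in_mm(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        sd = atlas.signed_distance(m, (3.0, 1.0))
        assert sd[5, 4] == 3.0 and sd[4, 5] == 1.0


class TestPhaseCongruency:
    def test_constant_image_is_structureless(self):
        assert atlas.phase_congruency(np.full((64, 64), 5.0)).max() < 1e-6

    def test_step_edge_produces_ridge(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        pc = atlas.phase_congruency(img)
        edge = pc[20:44, 31:33].mean()
        flat = pc[20:44, 5:15].mean()
        assert edge > 10 * flat
        assert 0 <= pc.min() and pc.max() <= 1

    def test_affine_intensity_invariance(self, desk_phantom):
        img = desk_phantom.mr[0]
        a = atlas.phase_congruency(img)
        b = atlas.phase_congruency(2.0 * img + 10.0)
        assert np.abs(a - b).max() < 0.01


class TestVoteBoneMap:
    def _dataset(self, masks):
        entries = []
        for m in masks:
            entries.append(AtlasEntry(
                mr=np.zeros(m.shape), ct_hu=np.zeros(m.shape), bone_mask=m,
                signed_distance=np.zeros(m.shape), pcm=np.zeros(m.shape),
                valid_mask=np.ones(m.shape, bool)))
        return AtlasDataset(entries=entries, spacing=(1.0, 1.0, 1.0))

    def test_majority_vote(self):
        m1 = np.zeros((4, 4), bool); m1[1, 1] = True
        m2 = np.zeros((4, 4), bool); m2[1, 1] = True
        m3 = np.zeros((4, 4), bool)
        vote = atlas.vote_bone_map(self._dataset([m1, m2, m3]), 0.5)
        assert vote[1, 1] and vote.sum() == 1

    def test_identical_atlases_reproduce_mask(self, rng):
        m = rng.random((8, 8)) > 0.6
        vote = atlas.vote_bone_map(self._dataset([m, m, m]), 0.5)
        assert np.array_equal(vote, m)

    def test_monotone_in_threshold(self, rng):
        masks = [rng.random((10, 10)) > 0.5 for _ in range(5)]
        ds = self._dataset(masks)
        prev = None
        for thr in np.linspace(0.05, 0.95, 10):
            v = atlas.vote_bone_map(ds, thr)
            if prev is not None:
                assert np.all(v <= prev)  # non-increasing support
            prev = v

    def test_single_entry_rejected(self):
        with pytest.raises(ValueError):
            atlas.vote_bone_map(self._dataset([np.ones((3, 3), bool)]))


class TestAtlasWeights:
    def _entry(self, sd, pcm, ct=None):
        sd = np.asarray(sd, float)
        return AtlasEntry(mr=np.zeros_like(sd), ct_hu=np.asarray(
            ct if ct is not None else np.zeros_like(sd), float),
            bone_mask=np.zeros_like(sd, dtype=bool), signed_distance=sd,
            pcm=np.asarray(pcm, float), valid_mask=np.ones_like(sd, dtype=bool))

    def test_identical_atlas_dominates(self, rng):
        tgt_sd = rng.normal(size=(6, 6))
        tgt_pcm = rng.random((6, 6))
        perfect = self._entry(tgt_sd, tgt_pcm)
        other = self._entry(tgt_sd + 3.0, np.clip(tgt_pcm + 0.3, 0, 1))
        ds = AtlasDataset(entries=[perfect, other], spacing=(1, 1, 1))
        w = atlas.atlas_weights(tgt_sd, tgt_pcm, ds)
        assert np.all(w[0] >= w[1])

    def test_two_identical_atlases_split_evenly(self, rng):
        tgt_sd = rng.normal(size=(5, 5))
        tgt_pcm = rng.random((5, 5))
        e = self._entry(tgt_sd + 1.0, tgt_pcm)
        ds = AtlasDataset(entries=[e, self._entry(tgt_sd + 1.0, tgt_pcm)],
                          spacing=(1, 1, 1))
        w = atlas.atlas_weights(tgt_sd, tgt_pcm, ds)
        assert np.allclose(w, 0.5)

    def test_hand_computed_kernel_values(self):
        # 1x3 example, patch_radius 0 so the patch mean is the voxel itself
        tgt_sd = np.array([[0.0, 1.0, 2.0]])
        tgt_pcm = np.array([[0.1, 0.5, 0.9]])
        e1 = self._entry([[0.0, 3.0, 2.0]], [[0.1, 0.5, 0.5]])
        e2 = self._entry([[5.0, 1.0, 2.0]], [[0.3, 0.5, 0.9]])
        ds = AtlasDataset(entries=[e1, e2], spacing=(1, 1, 1))
        sigma_d, sigma_p = 5.0, 0.2
        w = atlas.atlas_weights(tgt_sd, tgt_pcm, ds, sigma_d=sigma_d,
                                sigma_p=sigma_p, patch_radius=0)
        kd = lambda dd: np.exp(-dd ** 2 / (2 * sigma_d ** 2))
        kp = lambda dp: np.exp(-dp ** 2 / (2 * sigma_p ** 2))
        raw1 = np.array([kd(0) * kp(0), kd(2) * kp(0), kd(0) * kp(0.4)])
        raw2 = np.array([kd(5) * kp(0.2), kd(0) * kp(0), kd(0) * kp(0)])
        assert np.allclose(w[0][0], raw1 / (raw1 + raw2), atol=1e-10)

    def test_underflow_falls_back_to_uniform(self):
        tgt_sd = np.zeros((2, 2))
        tgt_pcm = np.zeros((2, 2))
        e = self._entry(tgt_sd + 1e4, tgt_pcm)  # kernels underflow to 0
        ds = AtlasDataset(entries=[e, self._entry(tgt_sd + 1e4, tgt_pcm)],
                          spacing=(1, 1, 1))
        w = atlas.atlas_weights(tgt_sd, tgt_pcm, ds)
        assert np.allclose(w, 0.5)


class TestFusion:
    def test_convex_combination_bounds(self, rng):
        cts = [rng.normal(0, 300, (8, 8)) for _ in range(3)]
        entries = [AtlasEntry(mr=np.zeros((8, 8)), ct_hu=c,
                              bone_mask=np.zeros((8, 8), bool),
                              signed_distance=rng.normal(size=(8, 8)),
                              pcm=rng.random((8, 8)),
                              valid_mask=np.ones((8, 8), bool)) for c in cts]
        ds = AtlasDataset(entries=entries, spacing=(1, 1, 1))
        w = atlas.atlas_weights(np.zeros((8, 8)), rng.random((8, 8)), ds)
        fused = atlas.fuse_sct(ds, w)
        lo = np.min(cts, axis=0)
        hi = np.max(cts, axis=0)
        assert np.all(fused >= lo - 1e-3) and np.all(fused <= hi + 1e-3)

    def test_single_atlas_is_exact(self, rng):
        ct = rng.normal(0, 300, (6, 6))
        e = AtlasEntry(mr=np.zeros((6, 6)), ct_hu=ct,
                       bone_mask=np.zeros((6, 6), bool),
                       signed_distance=np.zeros((6, 6)), pcm=np.zeros((6, 6)),
                       valid_mask=np.ones((6, 6), bool))
        fused = atlas.fuse_sct(AtlasDataset(entries=[e], spacing=(1, 1, 1)))
        assert np.allclose(fused, ct, atol=1e-4)


@pytest.fixture(scope="module")
def library(desk_conf):
    mrs, cts = [], []
    for s in range(4):
        ph = phantom.generate_phantom(desk_conf, 30 + s)
        mrs.append(pp.normalize_unit_range(ph.mr))
        cts.append(ph.ct_hu)
    return mrs, cts


class TestAtlasSCTEndToEnd:

    def test_truncation_robustness(self, library, desk_conf):
        """The fused sCT keeps the full body even when the input MR is
        truncated — the atlas prior fills the missing anatomy."""
        mrs, cts = library
        target = phantom.generate_phantom(desk_conf, 77)
        tr = phantom.inject_truncation(target, 0.15)
        est = atlas.AtlasSCT().fit(mrs, cts, spacing=desk_conf.voxel_spacing)
        sct = est.predict(pp.normalize_unit_range(tr.mr))
        area_sct = (sct > -400).sum()
        area_true = (target.ct_hu > -400).sum()
        assert area_sct >= 0.95 * area_true

    def test_metal_replaced_with_tissue(self, library, desk_conf):
        """At the implant site the fused sCT shows population tissue (bone
        present in the map), not the MR signal void."""
        mrs, cts = library
        target = phantom.generate_phantom(desk_conf, 78)
        mt = phantom.inject_metal(target, (58.0, -32.0), 28.0, 9.0)
        est = atlas.AtlasSCT().fit(mrs, cts, spacing=desk_conf.voxel_spacing)
        sct = est.predict(pp.normalize_unit_range(mt.mr))
        implant_core = (mt.labels == phantom.LABELS["implant"]) & target.body_mask
        assert sct[implant_core].mean() > -300  # tissue-like, not air
        assert (sct > 160).sum() > 0  # bone range present in the map

    def test_atlas_order_permutation_invariant(self, library, desk_conf):
        mrs, cts = library
        target = pp.normalize_unit_range(
            phantom.generate_phantom(desk_conf, 79).mr)
        a = atlas.AtlasSCT().fit(mrs, cts, spacing=desk_conf.voxel_spacing
                                 ).predict(target)
        b = atlas.AtlasSCT().fit(mrs[::-1], cts[::-1],
                                 spacing=desk_conf.voxel_spacing).predict(target)
        assert np.allclose(a, b, atol=1e-3)

    def test_library_roundtrip(self, library, desk_conf, tmp_path):
        mrs, cts = library
        atlas.save_atlas_library(tmp_path, mrs, cts, desk_conf.voxel_spacing)
        mrs2, cts2, ids, spacing = atlas.load_atlas_library(tmp_path)
        assert len(mrs2) == len(mrs)
        assert np.allclose(mrs2[0], mrs[0], atol=1e-5)
        assert np.allclose(spacing, desk_conf.voxel_spacing)
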