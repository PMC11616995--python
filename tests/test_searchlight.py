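"""Searchlight maps: neighborhood oracles, locality, degenerate cases."""
import numpy as np
import pytest

import braillemvpa as bm
from braillemvpa.searchlight import _voxel_neighborhoods

from conftest import make_epochs


class TestNeighborhoodOracles:
    def test_sphere_matches_brute_force_scan(self):
        """Voxel neighborhoods from sphere offsets equal an exhaustive
        distance scan over a 10x10x10 grid."""
        rng = np.random.default_rng(0)
        mask = rng.random((10, 10, 10)) < 0.7
        mask[0, 0, 0] = True
        for radius in (1.0, 2.0, 3.5):
            centers, neigh = _voxel_neighborhoods(mask, radius)
            got = {tuple(c): set(n) for c, n in zip(centers, neigh)}
            coords = np.argwhere(mask)
            for c in coords[rng.choice(len(coords), 25, replace=False)]:
                d2 = ((coords - c) ** 2).sum(axis=1)
                expected = {int(np.ravel_multi_index(v, mask.shape))
                            for v in coords[d2 <= radius ** 2]}
                assert got[tuple(c)] == expected

    def test_sphere_center_included_and_radius_validated(self):
        offs = bm.sphere_offsets(4)
        assert (offs == 0).all(axis=1).any()
        assert (np.linalg.norm(offs, axis=1) <= 4).all()
        with pytest.raises(ValueError, match="radius"):
            bm.sphere_offsets(0.5)

    def test_channel_knn_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mont = {f"c{i}": rng.normal(size=3) for i in range(12)}
        neigh = bm.channel_neighborhoods(mont, k=4)
        names = list(mont)
        for i, name in enumerate(names):
            dists = sorted((np.linalg.norm(mont[name] - mont[o]), o)
                           for o in names if o != name)
            assert set(neigh[name]) == {o for _, o in dists[:4]}
            assert name not in neigh[name]
        inc = bm.channel_neighborhoods(mont, k=4, include_center=True)
        assert all(n in inc[n] for n in names)

    def test_k_validation(self):
        mont = {f"c{i}": np.array([i, 0.0, 0.0]) for i in range(4)}
        with pytest.raises(ValueError, match="smaller"):
            bm.channel_neighborhoods(mont, k=4)
        mont["c0"] = np.array([np.nan, 0.0, 0.0])
        with pytest.raises(ValueError, match="positions"):
            bm.channel_neighborhoods(mont, k=2)


class TestVolumeSearchlight:
    @staticmethod
    def _planted_volumes(g=8, seed=0, amplitude=3.0):
        spec = bm.EffectSpec(seed=seed)
        block = np.zeros((g, g, g), dtype=bool)
        block[:3, :3, :3] = True
        sets = bm.synthesize_roi_patterns(10, spec,
                                          n_features=int(block.sum()),
                                          mix={"b": 0.0},
                                          amplitude=amplitude)
        rng = np.random.default_rng(seed + 1)
        vols = rng.standard_normal((10, 16, g * g * g))
        vols[:, :, block.ravel()] = sets["b"].data
        return (vols.reshape(10, 16, g, g, g), sets["b"].conditions, block)

    def test_signal_is_localized(self):
        vols, conds, block = self._planted_volumes()
        mask = np.ones(vols.shape[2:], dtype=bool)
        maps = bm.volume_searchlight(vols, conds, mask, radius=1.5, seed=2)
        m = maps["across"].data
        assert not np.isnan(m).any()
        inside = m[block]
        far = np.zeros_like(block)
        far[5:, 5:, 5:] = True
        assert inside.mean() > 65.0
        assert abs(m[far].mean() - 50.0) < 5.0

    def test_corner_neighborhood_truncated(self):
        vols, conds, _ = self._planted_volumes(g=4)
        mask = np.ones((4, 4, 4), dtype=bool)
        maps = bm.volume_searchlight(vols, conds, mask, radius=2, seed=0)
        assert np.isfinite(maps["across"].data).all()

    def test_whole_mask_sphere_gives_constant_map(self):
        vols, conds, _ = self._planted_volumes(g=3)
        mask = np.ones((3, 3, 3), dtype=bool)
        maps = bm.volume_searchlight(vols, conds, mask, radius=10, seed=1)
        vals = maps["across"].data.ravel()
        assert np.unique(vals).size == 1

    def test_input_validation(self):
        vols, conds, _ = self._planted_volumes(g=4)
        with pytest.raises(ValueError, match="mask"):
            bm.volume_searchlight(vols, conds, np.ones((5, 5, 5), bool),
                                  radius=2)
        with pytest.raises(ValueError, match="empty"):
            bm.volume_searchlight(vols, conds, np.zeros((4, 4, 4), bool),
                                  radius=2)


class TestSensorSearchlight:
    def test_bin_arithmetic_1ms_to_10ms(self, montage8):
        ep = make_epochs(n_letters=2, reps=5, n_channels=8, sfreq=1000.0,
                         window=(-100.0, 999.0), seed=20, montage=montage8)
        maps = bm.sensor_searchlight(ep, k=3, bin_ms=10.0, seed=0)
        assert maps["across"].data.shape == (8, 110)
        assert maps["across"].bin_ms == 10.0

    def test_local_signal_stays_local(self):
        """Signal planted on one channel is visible only at that channel
        and its montage neighbors."""
        rng = np.random.default_rng(3)
        n, t = 80, 20
        data = rng.standard_normal((n, 6, t))
        mont = {f"ch{i}": np.array([float(i > 2) * 10 + i, 0.0, 0.0])
                for i in range(6)}
        # letters B/C on two hands, signal only on channel 0, letter coded
        from conftest import toy_epochs
        ep = toy_epochs(data, times=np.arange(-5, 15, dtype=float),
                        montage=mont)
        code = {"B": 4.0, "C": -4.0}
        post = ep.times >= 0
        for i in range(n):
            ep.data[i, 0, post] += code[ep.labels.loc[i, "letter"]]
        maps = bm.sensor_searchlight(ep, k=2, bin_ms=5.0, seed=1,
                                     include_center=True,
                                     schemes=("within",))
        m = maps["within"].data
        post_bins = maps["within"].bin_starts_ms >= 0
        near = m[:3][:, post_bins].mean()
        far = m[3:][:, post_bins].mean()
        assert near > 85.0
        assert abs(far - 50.0) < 10.0

    def test_k_equals_all_channels_matches_full_montage(self, planted_epochs):
        maps = bm.sensor_searchlight(planted_epochs,
                                     k=planted_epochs.n_channels - 1,
                                     bin_ms=10.0, include_center=True,
                                     seed=5, schemes=("within",))
        m = maps["within"].data
        # every channel sees the full montage: rows identical up to rare
        # boundary flips caused by feature-order floating-point noise
        diff = np.abs(m - m[0][None])
        assert (diff < 1e-9).mean() > 0.95
        assert diff.max() < 2.0

    def test_requires_montage_and_valid_k(self, planted_epochs):
        with pytest.raises(ValueError, match="smaller"):
            bm.sensor_searchlight(planted_epochs,
                                  k=planted_epochs.n_channels)
        bare = planted_epochs.copy()
        bare.montage = {}
        with pytest.raises(ValueError, match="montage"):
            bm.sensor_searchlight(bare, k=2)


class TestClusterReport:
    def test_planted_block_forms_one_cluster(self):
        data = np.full((6, 6, 6), 50.0)
        data[1:3, 1:3, 1:3] = 80.0
        data[5, 5, 5] = 90.0  # isolated supra-threshold voxel
        amap = bm.AccuracyMap(kind="volume", data=data, affine=np.eye(4))
        rep = bm.cluster_report(amap, threshold=70.0)
        assert len(rep) == 2
        assert rep[0]["n_voxels"] == 8
        assert rep[0]["peak_accuracy"] == 80.0
        assert rep[1]["peak_voxel"] == (5, 5, 5)

    def test_requires_volume_map(self):
        amap = bm.AccuracyMap(kind="sensor", data=np.zeros((2, 3)),
                              channel_names=["a", "b"],
                              bin_starts_ms=np.arange(3.0), bin_ms=10.0)
        with pytest.raises(ValueError, match="volumetric"):
            bm.cluster_report(amap)
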