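"""Tests of 3D puncta segmentation, metrics and nanodomain clustering."""

import numpy as np
import pytest

import pulsechase as pc

VOX = (0.1, 0.05, 0.05)


def brute_force_components(binary):
    """Independent 26-connected labelling by explicit flood fill."""
    binary = np.asarray(binary, bool)
    visited = np.zeros_like(binary)
    comps = []
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack, comp = [start], set()
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if (all(0 <= w[i] < binary.shape[i] for i in range(3))
                        and binary[w] and not visited[w]):
                    visited[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestSegmentPuncta:
    def test_empty_volume_gives_no_objects(self):
        vol = np.zeros((16, 16, 16))
        ps = pc.segment_puncta(vol, np.ones_like(vol, bool), VOX)
        assert ps.n_objects == 0

    def test_sphere_volumes_match_analytic_value(self, coloc_volume):
        _, vol = coloc_volume
        ps = pc.segment_puncta(vol.channel_a, vol.dendrite_mask,
                               vol.voxel_size)
        assert ps.n_objects == 10
        analytic = 4 / 3 * np.pi * 0.3 ** 3
        np.testing.assert_allclose(ps.table["volume_um3"], analytic, rtol=0.15)

    def test_split_divides_touching_blobs(self):
        z, y, x = np.meshgrid(*[(np.arange(s) + 0.5) * v
                                for s, v in zip((24, 48, 48), VOX)],
                              indexing="ij")
        blob = lambda c, s: np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2
                                     + (x - c[2]) ** 2) / (2 * s ** 2))
        vol = blob((1.2, 1.2, 0.85), 0.2) + blob((1.2, 1.2, 1.55), 0.2)
        mask = np.ones_like(vol, bool)
        merged = pc.segment_puncta(vol, mask, VOX, threshold=0.1, split=False)
        assert merged.n_objects == 1
        split = pc.segment_puncta(vol, mask, VOX, threshold=0.1, split=True)
        assert split.n_objects == 2

    def test_no_split_equals_brute_force_labelling(self):
        rng = np.random.default_rng(4)
        from scipy import ndimage as ndi
        vol = ndi.gaussian_filter(rng.uniform(0, 1, (24, 24, 24)), 1.5)
        mask = np.ones_like(vol, bool)
        thr = np.quantile(vol, 0.8)
        ps = pc.segment_puncta(vol, mask, VOX, threshold=thr, split=False,
                               min_volume=0.0)
        got = {frozenset(zip(*np.nonzero(ps.label_image == lab)))
               for lab in ps.table["label"]}
        assert got == brute_force_components(vol > thr)

    def test_min_volume_discards_specks(self):
        vol = np.zeros((16, 16, 16))
        vol[8, 8, 8] = 10.0                       # 1-voxel speck
        vol[2:6, 2:6, 2:6] = 10.0                 # 64-voxel cube
        ps = pc.segment_puncta(vol, np.ones_like(vol, bool), VOX,
                               threshold=5.0, split=False)
        assert ps.n_objects == 1
        assert ps.table["n_voxels"].iloc[0] == 64

    def test_intensity_scale_invariance_with_auto_threshold(self, coloc_volume):
        _, vol = coloc_volume
        p1 = pc.segment_puncta(vol.channel_a, vol.dendrite_mask,
                               vol.voxel_size)
        p2 = pc.segment_puncta(vol.channel_a * 13.0, vol.dendrite_mask,
                               vol.voxel_size)
        assert p1.n_objects == p2.n_objects
        np.testing.assert_array_equal(p1.label_image > 0, p2.label_image > 0)


class TestPunctaMetrics:
    def test_density_is_count_over_mask_volume(self, coloc_volume):
        _, vol = coloc_volume
        ps = pc.segment_puncta(vol.channel_a, vol.dendrite_mask,
                               vol.voxel_size)
        m = pc.puncta_metrics(ps, vol.dendrite_mask)
        assert m.puncta_density == pytest.approx(
            ps.n_objects / m.dendrite_volume_um3)
        assert m.total_surface_volume == pytest.approx(
            ps.table["volume_um3"].sum() / m.dendrite_volume_um3)

    def test_doubling_mask_volume_halves_all_metrics(self):
        vol = np.zeros((16, 32, 32))
        vol[4:8, 4:8, 4:8] = 10.0
        half = np.zeros_like(vol, bool)
        half[:8] = True
        full = np.ones_like(vol, bool)
        ps = pc.segment_puncta(vol, full, VOX, threshold=5.0)
        m_half = pc.puncta_metrics(ps, half)
        m_full = pc.puncta_metrics(ps, full)
        assert m_full.puncta_density == pytest.approx(m_half.puncta_density / 2)
        assert m_full.total_surface_volume == pytest.approx(
            m_half.total_surface_volume / 2)
        assert m_full.mean_puncta_volume == pytest.approx(
            m_half.mean_puncta_volume / 2)

    def test_zero_volume_mask_is_an_error(self):
        vol = np.zeros((8, 8, 8))
        ps = pc.segment_puncta(vol, np.ones_like(vol, bool), VOX)
        with pytest.raises(ValueError, match="zero volume"):
            pc.puncta_metrics(ps, np.zeros_like(vol, bool))

    def test_metrics_match_generator_ground_truth(self, coloc_volume):
        _, vol = coloc_volume
        ps = pc.segment_puncta(vol.channel_a, vol.dendrite_mask,
                               vol.voxel_size)
        m = pc.puncta_metrics(ps, vol.dendrite_mask)
        gt = vol.puncta_table[vol.puncta_table.channel == "A"]
        dvol = vol.dendrite_mask.sum() * np.prod(vol.voxel_size)
        assert m.puncta_density == pytest.approx(len(gt) / dvol)
        assert m.total_surface_volume == pytest.approx(
            gt["volume_um3"].sum() / dvol, rel=0.15)


class TestNanodomains:
    def _blob(self, shape, centre, sigma=0.1):
        z, y, x = np.meshgrid(*[(np.arange(s) + 0.5) * v
                                for s, v in zip(shape, VOX)], indexing="ij")
        return np.exp(-((z - centre[0]) ** 2 + (y - centre[1]) ** 2
                        + (x - centre[2]) ** 2) / (2 * sigma ** 2))

    def test_single_blob_gives_one_centre_at_blob_centre(self):
        c = (0.8, 0.8, 0.8)
        vol = self._blob((16, 32, 32), c)
        centres = pc.detect_nanodomains(vol, VOX, threshold=0.2)
        assert len(centres) == 1
        assert np.linalg.norm(centres[0] - c) <= max(VOX)

    def test_separation_controls_merging(self):
        shape = (16, 32, 32)
        far = self._blob(shape, (0.8, 0.8, 0.5)) \
            + self._blob(shape, (0.8, 0.8, 1.1))
        near = self._blob(shape, (0.8, 0.8, 0.75)) \
            + self._blob(shape, (0.8, 0.8, 0.85))
        assert len(pc.detect_nanodomains(far, VOX, threshold=0.2,
                                         min_separation=0.3)) == 2
        assert len(pc.detect_nanodomains(near, VOX, threshold=0.2,
                                         min_separation=0.3)) == 1

    def test_planted_layout_count_recovered(self, coloc_volume):
        spec, vol = coloc_volume
        centres = pc.detect_nanodomains(vol.channel_b, vol.voxel_size)
        planted = sum(len(c) for c in spec.cluster_layout) \
            + sum(1 for p in spec.puncta if p.channel == "B")
        assert len(centres) == planted


class TestCytoskeletonMask:
    def test_bright_tube_recovered_and_gaps_closed(self):
        vol = np.zeros((8, 16, 64))
        vol[3:6, 6:10, :] = 100.0
        vol[3:6, 6:10, 30:33] = 0.0       # a dark gap along the tube
        vol += np.random.default_rng(7).uniform(0, 1, vol.shape)
        mask = pc.dendrite_mask_from_cytoskeleton(vol, VOX)
        assert mask[4, 8, 10] and mask[4, 8, 50]
        assert mask[4, 8, 31]              # gap closed (0.15 μm = 3 voxels)
        assert not mask[0, 0, 0]


class TestClusterNanodomains:
    def test_all_far_apart_gives_singletons(self):
        rng = np.random.default_rng(5)
        centres = rng.uniform(0, 50, (12, 3))   # typical gap >> 0.3 μm
        prof = pc.cluster_nanodomains(centres, 0.3)
        assert prof.histogram == {1: 12}

    def test_chain_links_transitively(self):
        centres = np.array([[0, 0, 0], [0, 0, 0.25], [0, 0, 0.5]])
        prof = pc.cluster_nanodomains(centres, 0.3)
        assert prof.histogram == {3: 1}

    def test_planted_histogram_recovered(self, coloc_volume):
        spec, vol = coloc_volume
        centres = pc.detect_nanodomains(vol.channel_b, vol.voxel_size)
        prof = pc.cluster_nanodomains(centres, 0.3)
        expect = dict(vol.cluster_histogram)
        n_b = sum(1 for p in spec.puncta if p.channel == "B")
        expect[1] = expect.get(1, 0) + n_b    # co-placed B puncta are singles
        assert prof.histogram == expect

    def test_histogram_mass_balance_and_invariances(self):
        rng = np.random.default_rng(6)
        centres = rng.uniform(0, 10, (40, 3))
        prof = pc.cluster_nanodomains(centres, 0.6)
        assert sum(k * v for k, v in prof.histogram.items()) == 40
        shuffled = pc.cluster_nanodomains(centres[rng.permutation(40)], 0.6)
        assert shuffled.histogram == prof.histogram
        shifted = pc.cluster_nanodomains(centres + 7.3, 0.6)
        assert shifted.histogram == prof.histogram

    def test_single_density_uses_mask_volume(self):
        centres = np.array([[0, 0, 0], [5, 5, 5]])
        prof = pc.cluster_nanodomains(centres, 0.3, mask_volume_um3=100.0)
        assert prof.single_nanodomain_density == pytest.approx(0.02)

    def test_empty_centres(self):
        prof = pc.cluster_nanodomains(np.empty((0, 3)), 0.3)
        assert prof.histogram == {} and prof.clusters == []
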