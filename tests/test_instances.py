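"""Instance post-processing: labeling, filters, association, Feret, crops."""

import numpy as np
import pytest

from lewyseg.errors import ParameterError
from lewyseg.instances import (
    AggregateInstance,
    CropSpec,
    InstanceMask,
    associate_labels,
    extract_crop,
    extract_instances,
    filter_feret,
    label_components,
    max_feret,
    postprocess,
    remove_small,
)
from lewyseg.types import BinaryMask, RGBTile

# ---------------------------------------------------------------------------
# independent oracles


def flood_fill_label(mask):
    """BFS flood-fill labeling oracle (8-connectivity, raster order)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 1
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < mask.shape[0]
                                and 0 <= xx < mask.shape[1]
                                and mask[yy, xx]
                                and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = nxt
                                stack.append((yy, xx))
                nxt += 1
    return labels, nxt - 1


def feret_bruteforce_allpairs(coords):
    pts = np.asarray(coords, dtype=np.int64)
    if len(pts) < 2:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(int(d2.max())))


def transitive_closure_groups(coord_sets, Td):
    """Brute-force transitive closure over the pairwise min-distance graph."""
    n = len(coord_sets)
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            a = np.asarray(coord_sets[i], float)
            b = np.asarray(coord_sets[j], float)
            d = np.sqrt(((a[:, None] - b[None]) ** 2).sum(-1)).min()
            adj[i, j] = adj[j, i] = d <= Td
    groups = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {i}
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for j in np.flatnonzero(adj[k]):
                if j not in comp:
                    comp.add(int(j))
                    frontier.append(int(j))
        seen |= comp
        groups.append(frozenset(comp))
    return set(groups)


def random_blobs_mask(rng, size=64, n_blobs=4):
    mask = np.zeros((size, size), bool)
    for _ in range(n_blobs):
        r, c = rng.integers(5, size - 5, 2)
        rad = rng.integers(2, 6)
        yy, xx = np.mgrid[0:size, 0:size]
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    return mask


# ---------------------------------------------------------------------------


class TestLabelComponents:
    def test_empty_mask_has_zero_instances(self):
        inst = label_components(BinaryMask(np.zeros((8, 8), bool)))
        assert inst.n_instances == 0

    def test_two_disjoint_blobs(self):
        m = np.zeros((16, 16), bool)
        m[1:4, 1:4] = True
        m[10:13, 10:13] = True
        assert label_components(BinaryMask(m)).n_instances == 2

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(50):
            mask = rng.random((64, 64)) > 0.82
            inst = label_components(BinaryMask(mask))
            oracle_labels, oracle_n = flood_fill_label(mask)
            assert inst.n_instances == oracle_n
            # same partition: labels agree up to identical relabeling
            joint = set(zip(inst.labels.ravel(), oracle_labels.ravel()))
            assert len(joint) == oracle_n + 1  # bijection incl. background


class TestRemoveSmall:
    def test_area_boundary_is_strict(self):
        m = np.zeros((40, 40), bool)
        m[1:10, 1:12] = True   # 99 px
        m[20:30, 1:11] = True  # 100 px
        inst = label_components(BinaryMask(m))
        areas = {r.area_px for r in extract_instances(inst)}
        assert areas == {99, 100}
        kept = remove_small(inst, Ts=100)
        assert kept.n_instances == 1
        assert extract_instances(kept)[0].area_px == 100

    def test_zero_threshold_is_identity(self, rng):
        mask = rng.random((32, 32)) > 0.8
        inst = label_components(BinaryMask(mask))
        out = remove_small(inst, Ts=0)
        assert np.array_equal(out.labels, inst.labels)

    def test_survivor_count_matches_bruteforce(self, rng):
        for _ in range(20):
            mask = random_blobs_mask(rng)
            inst = label_components(BinaryMask(mask))
            Ts = int(rng.integers(1, 80))
            expected = sum(
                1 for r in extract_instances(inst) if r.area_px >= Ts
            )
            assert remove_small(inst, Ts).n_instances == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            remove_small(InstanceMask(np.zeros((4, 4), int), 0), Ts=-1)


class TestAssociateLabels:
    def _two_bars(self, gap):
        m = np.zeros((64, 64), bool)
        m[10:14, 5:25] = True
        m[10 + 3 + gap : 14 + 3 + gap, 5:25] = True  # vertical distance = gap
        return m

    def test_blobs_within_td_merge(self):
        inst = label_components(BinaryMask(self._two_bars(15)))
        assert inst.n_instances == 2
        assert associate_labels(inst, Td=20).n_instances == 1

    def test_blobs_beyond_td_stay_separate(self):
        inst = label_components(BinaryMask(self._two_bars(25)))
        assert associate_labels(inst, Td=20).n_instances == 2

    def test_distance_exactly_td_merges(self):
        inst = label_components(BinaryMask(self._two_bars(20)))
        assert associate_labels(inst, Td=20).n_instances == 1

    def test_chain_merges_transitively(self):
        m = np.zeros((80, 80), bool)
        m[10:12, 5:25] = True   # A
        m[26:28, 5:25] = True   # B: 15 px from A
        m[42:44, 5:25] = True   # C: 15 px from B, 30 px from A
        inst = label_components(BinaryMask(m))
        out = associate_labels(inst, Td=20)
        assert out.n_instances == 1

    def test_matches_transitive_closure_oracle(self, rng):
        for trial in range(50):
            mask = random_blobs_mask(rng, n_blobs=int(rng.integers(2, 6)))
            inst = label_components(BinaryMask(mask))
            coord_sets = [r.pixel_coords for r in extract_instances(inst)]
            for Td in (0, 5, 20, 50):
                merged = associate_labels(inst, Td)
                # group partition from the implementation
                impl_groups = set()
                for rec in extract_instances(merged):
                    members = frozenset(
                        int(lab - 1)
                        for lab in np.unique(
                            inst.labels[
                                rec.pixel_coords[:, 0], rec.pixel_coords[:, 1]
                            ]
                        )
                        if lab > 0
                    )
                    impl_groups.add(members)
                assert impl_groups == transitive_closure_groups(coord_sets, Td)

    def test_idempotent_and_relabel_invariant(self, rng):
        mask = random_blobs_mask(rng, n_blobs=5)
        inst = label_components(BinaryMask(mask))
        once = associate_labels(inst, Td=10)
        twice = associate_labels(once, Td=10)
        assert once.n_instances == twice.n_instances
        # permute input labels: same resulting partition
        perm = rng.permutation(inst.n_instances) + 1
        permuted = InstanceMask(
            np.where(inst.labels > 0, perm[inst.labels - 1], 0),
            inst.n_instances,
        )
        out_p = associate_labels(permuted, Td=10)
        assert out_p.n_instances == once.n_instances

    def test_negative_td_rejected(self):
        with pytest.raises(ParameterError):
            associate_labels(InstanceMask(np.zeros((4, 4), int), 0), Td=-1)


class TestMaxFeret:
    def test_single_pixel_is_zero(self):
        assert max_feret(np.array([[3, 3]])) == 0.0

    def test_horizontal_run_of_34_pixels(self):
        coords = np.array([[5, c] for c in range(10, 44)])
        assert max_feret(coords) == 33.0

    def test_matches_allpairs_oracle_on_random_blobs(self, rng):
        for _ in range(100):
            mask = random_blobs_mask(rng, size=48,
                                     n_blobs=int(rng.integers(1, 4)))
            rr, cc = np.nonzero(mask)
            if len(rr) == 0:
                continue
            coords = np.stack([rr, cc], axis=1)
            assert max_feret(coords) == feret_bruteforce_allpairs(coords)

    def test_collinear_points(self):
        coords = np.array([[i, 2 * i] for i in range(20)])
        assert max_feret(coords) == feret_bruteforce_allpairs(coords)


class TestFilterFeret:
    def test_thin_neurite_retained_compact_blob_removed(self):
        m = np.zeros((100, 100), bool)
        m[10:13, 5:65] = True  # 60x3 neurite: area 180, feret ~60
        yy, xx = np.mgrid[0:100, 0:100]
        m |= (yy - 70) ** 2 + (xx - 70) ** 2 <= 100  # disk r=10: feret 20
        inst = label_components(BinaryMask(m))
        out = filter_feret(inst, TF=33)
        assert out.n_instances == 1
        assert extract_instances(out)[0].max_feret_px >= 33

    def test_zero_threshold_is_identity(self, rng):
        mask = random_blobs_mask(rng)
        inst = label_components(BinaryMask(mask))
        out = filter_feret(inst, TF=0)
        assert np.array_equal(out.labels, inst.labels)

    def test_negative_tf_rejected(self):
        with pytest.raises(ParameterError):
            filter_feret(InstanceMask(np.zeros((4, 4), int), 0), TF=-1)


class TestPipelineOrderProperties:
    def test_association_never_increases_count_filters_only_reduce(self, rng):
        for _ in range(10):
            mask = random_blobs_mask(rng, n_blobs=6)
            inst = label_components(BinaryMask(mask))
            after_small = remove_small(inst, 30)
            assert after_small.n_instances <= inst.n_instances
            after_assoc = associate_labels(after_small, 10)
            assert after_assoc.n_instances <= after_small.n_instances
            after_feret = filter_feret(after_assoc, 10)
            assert after_feret.n_instances <= after_assoc.n_instances


class TestExtractCrop:
    def _tile(self):
        return RGBTile(np.full((256, 256, 3), 200.0))

    def _instance_at(self, r, c):
        coords = np.array([[r + dr, c + dc] for dr in range(-2, 3)
                           for dc in range(-2, 3)])
        return AggregateInstance(1, len(coords), (float(r), float(c)), 4.0,
                                 coords)

    def test_center_pixel_inside_centered_blob(self):
        tile = self._tile()
        inst = self._instance_at(128, 128)
        tile.pixels[inst.pixel_coords[:, 0], inst.pixel_coords[:, 1]] = 50.0
        crop, _ = extract_crop(tile, inst, CropSpec(size=64))
        assert crop[32, 32, 0] == 50.0

    def test_border_centroid_padded_with_white_point(self):
        tile = self._tile()
        inst = self._instance_at(10, 10)
        crop, _ = extract_crop(tile, inst, CropSpec(size=256))
        # 256/2 - 10 = 118 rows/cols of padding at the top/left
        assert np.all(crop[:118, :, :] == 255.0)
        assert np.all(crop[:, :118, :] == 255.0)
        assert crop[118, 118, 0] == 200.0

    def test_crop_dims_always_exact(self, rng):
        tile = self._tile()
        for _ in range(10):
            r, c = rng.integers(0, 256, 2)
            crop, _ = extract_crop(tile, self._instance_at(r, c),
                                   CropSpec(size=128))
            assert crop.shape == (128, 128, 3)

    def test_overlay_draws_green_contour(self):
        tile = self._tile()
        inst = self._instance_at(128, 128)
        _, over = extract_crop(tile, inst, CropSpec(size=64), overlay=True)
        assert (over == np.array([0.0, 200.0, 0.0])).all(axis=-1).any()

    def test_invalid_crop_spec_rejected(self):
        with pytest.raises(ParameterError):
            CropSpec(size=31)


def test_threshold_fixture_postprocessing_is_exact(threshold_fixture):
    """On the designed boundary fixture the surviving set equals the
    ground-truth expectation, including area=100 kept / 99 removed and
    feret=33 kept / 32 removed."""
    tile, gt = threshold_fixture
    inst = postprocess(BinaryMask(gt.labels > 0), Ts=100, Td=20, TF=33)
    surviving = set()
    for rec in extract_instances(inst):
        surviving.update(
            int(v)
            for v in np.unique(gt.labels[rec.pixel_coords[:, 0],
                                         rec.pixel_coords[:, 1]])
            if v > 0
        )
    assert surviving == gt.expected_surviving
    # pixel-exact: surviving instances cover exactly the expected objects
    expected_mask = np.isin(gt.labels, sorted(gt.expected_surviving))
    assert np.array_equal(inst.labels > 0, expected_mask)


def test_threshold_fixture_all_objects_survive_zero_thresholds(threshold_fixture):
    tile, gt = threshold_fixture
    inst = postprocess(BinaryMask(gt.labels > 0), Ts=0, Td=0, TF=0)
    assert inst.n_instances == len(gt.records)
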