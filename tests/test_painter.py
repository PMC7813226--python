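import numpy as np
import pytest

from voxseg import (
    BrushStroke,
    SelectionMask,
    TagVolume,
    Volume,
    apply_stroke,
    connected_components,
    extract_tag,
    region_grow,
    sphere_voxels,
)
from voxseg.errors import (
    EmptySelectionError,
    InvalidArgumentError,
    SeedNotInSelectionError,
)
from voxseg.painter import read_stroke_script


def footprint_mask(center, radius, dims):
    m = np.zeros(dims, bool)
    z, y, x = sphere_voxels(center, radius, dims)
    m[z, y, x] = True
    return m


class TestSphereVoxels:
    def test_radius_zero_single_voxel(self):
        m = footprint_mask((2, 2, 2), 0.0, (5, 5, 5))
        assert m.sum() == 1 and m[2, 2, 2]

    def test_radius_one_face_neighbours_only(self):
        # corners sit at distance √2 > 1 and are excluded
        m = footprint_mask((2, 2, 2), 1.0, (5, 5, 5))
        assert m.sum() == 7

    def test_large_radius_clipped_to_volume(self):
        m = footprint_mask((0, 0, 0), 10.0, (4, 4, 4))
        assert m.all()

    def test_fractional_center(self):
        z, y, x = sphere_voxels((1.5, 1.5, 1.5), 0.9, (4, 4, 4))
        assert len(z) == 8  # the surrounding 2×2×2 cube, each at distance √3/2·√3 ≈ 0.866


class TestApplyStroke:
    def test_point_stamp(self):
        tags = TagVolume.zeros((5, 5, 5))
        out = apply_stroke(tags, BrushStroke([(2, 2, 2)], 0.0, tag=3))
        assert out.data[2, 2, 2] == 3 and (out.data != 0).sum() == 1

    def test_paint_then_erase_is_identity(self):
        tags = TagVolume.zeros((6, 6, 6))
        stroke = BrushStroke([(2, 2, 1), (2, 2, 4)], 1.5, tag=5)
        painted = apply_stroke(tags, stroke)
        assert (painted.data != 0).any()
        erased = apply_stroke(
            painted, BrushStroke([(2, 2, 1), (2, 2, 4)], 1.5, tag=5, mode="erase")
        )
        assert not erased.data.any()

    def test_erase_protects_other_tags(self):
        tags = TagVolume.zeros((5, 5, 5))
        tags = apply_stroke(tags, BrushStroke([(2, 2, 2)], 1.0, tag=7))
        erased = apply_stroke(tags, BrushStroke([(2, 2, 2)], 1.0, tag=9, mode="erase"))
        np.testing.assert_array_equal(erased.data, tags.data)

    def test_swept_tube_has_no_gaps(self):
        tags = TagVolume.zeros((5, 5, 20))
        out = apply_stroke(tags, BrushStroke([(2, 2, 1), (2, 2, 18)], 1.2, tag=1))
        # every x along the stroke axis is covered
        assert all(out.data[2, 2, x] == 1 for x in range(1, 19))

    def test_restrict_confines_paint(self, rng):
        phase_b = rng.random((6, 6, 6)) < 0.5
        tags = apply_stroke(
            TagVolume.zeros((6, 6, 6)),
            BrushStroke([(3, 3, 3)], 4.0, tag=2),
            restrict=SelectionMask(phase_b),
        )
        assert (tags.data != 0).any()
        assert not (tags.data[~phase_b] != 0).any()  # tagged ⊆ phase B

    def test_voxels_outside_footprint_untouched(self, rng):
        base = TagVolume(rng.integers(0, 4, size=(6, 6, 6)).astype(np.uint8))
        out = apply_stroke(base, BrushStroke([(3, 3, 3)], 1.0, tag=9))
        touched = footprint_mask((3, 3, 3), 1.0, (6, 6, 6))
        np.testing.assert_array_equal(out.data[~touched], base.data[~touched])

    def test_tag_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BrushStroke([(1, 1, 1)], 1.0, tag=0)

    def test_stroke_script_roundtrip(self, tmp_path):
        p = tmp_path / "strokes.jsonl"
        p.write_text(
            '{"centers": [[1,1,1],[1,1,3]], "radius": 1.0, "tag": 2, "mode": "paint"}\n'
            '{"centers": [[1,1,1]], "radius": 0.5, "tag": 2, "mode": "erase"}\n'
        )
        strokes = read_stroke_script(p)
        assert len(strokes) == 2
        assert strokes[0].tag == 2 and strokes[1].mode == "erase"


def flood_fill_oracle(mask, seed, connectivity):
    """Brute-force BFS flood fill."""
    from tests.test_morphology import offsets

    seen = {tuple(seed)}
    stack = [tuple(seed)]
    while stack:
        p = stack.pop()
        for off in offsets(connectivity):
            q = tuple(c + o for c, o in zip(p, off))
            if (
                all(0 <= c < d for c, d in zip(q, mask.shape))
                and mask[q]
                and q not in seen
            ):
                seen.add(q)
                stack.append(q)
    out = np.zeros_like(mask)
    for p in seen:
        out[p] = True
    return out


class TestRegionGrow:
    def test_two_blocks_grow_one(self):
        m = np.zeros((5, 5, 8), bool)
        m[1:3, 1:3, 1:3] = True
        m[1:3, 1:3, 5:7] = True
        grown = region_grow(SelectionMask(m), (1, 1, 1), connectivity=6)
        assert grown.data[:, :, :3].sum() == 8 and not grown.data[:, :, 4:].any()

    def test_full_and_single_voxel_masks(self):
        full = SelectionMask(np.ones((4, 4, 4), bool))
        assert region_grow(full, (0, 0, 0)).data.all()
        single = np.zeros((4, 4, 4), bool)
        single[1, 2, 3] = True
        got = region_grow(SelectionMask(single), (1, 2, 3))
        assert got.data.sum() == 1

    @pytest.mark.parametrize("conn", [6, 26])
    def test_matches_flood_fill_oracle(self, rng, conn):
        m = rng.random((5, 5, 5)) < 0.55
        seeds = np.argwhere(m)
        seed = tuple(seeds[0])
        got = region_grow(SelectionMask(m), seed, connectivity=conn).data
        np.testing.assert_array_equal(got, flood_fill_oracle(m, seed, conn))

    def test_seed_outside_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        with pytest.raises(SeedNotInSelectionError):
            region_grow(SelectionMask(m), (2, 2, 2))
        with pytest.raises(SeedNotInSelectionError):
            region_grow(SelectionMask(m), (9, 0, 0))


class TestConnectedComponents:
    def test_diagonal_voxels_connectivity(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        m[2, 2, 2] = True
        _, sizes6 = connected_components(SelectionMask(m), connectivity=6)
        _, sizes26 = connected_components(SelectionMask(m), connectivity=26)
        assert len(sizes6) == 2 and len(sizes26) == 1

    def test_empty_mask(self):
        labels, sizes = connected_components(SelectionMask(np.zeros((3, 3, 3), bool)))
        assert sizes == [] and not labels.any()

    def test_raster_first_encounter_order_and_sizes(self):
        m = np.zeros((2, 3, 6), bool)
        m[1, 2, 4:6] = True  # later in raster order
        m[0, 0, 0] = True  # first in raster order
        labels, sizes = connected_components(SelectionMask(m))
        assert labels[0, 0, 0] == 1
        assert labels[1, 2, 4] == 2
        assert sizes == [1, 2]

    def test_partition_matches_region_grow(self, rng):
        m = rng.random((5, 5, 5)) < 0.5
        labels, sizes = connected_components(SelectionMask(m), connectivity=6)
        assert sum(sizes) == m.sum()
        for p in map(tuple, np.argwhere(m)):
            comp = region_grow(SelectionMask(m), p, connectivity=6).data
            np.testing.assert_array_equal(comp, labels == labels[p])


class TestExtractTag:
    def test_block_bounding_box(self, rng):
        data = rng.integers(0, 65536, size=(10, 10, 10), dtype=np.uint16)
        vol = Volume(data, voxel_size_um=(21, 21, 21))
        tags = np.zeros((10, 10, 10), np.uint8)
        tags[3:5, 4:6, 5:7] = 9
        sub = extract_tag(vol, TagVolume(tags), 9)
        assert sub.dims == (2, 2, 2)
        np.testing.assert_array_equal(sub.data, data[3:5, 4:6, 5:7])
        assert sub.voxel_size_um == (21.0, 21.0, 21.0)

    def test_whole_volume_tag_identity(self, rng):
        data = rng.integers(0, 256, size=(4, 4, 4), dtype=np.uint8)
        vol = Volume(data)
        sub = extract_tag(vol, TagVolume(np.ones((4, 4, 4), np.uint8)), 1)
        np.testing.assert_array_equal(sub.data, data)

    def test_l_shape_pads_non_tag(self):
        data = np.full((6, 6, 6), 100, np.uint8)
        tags = np.zeros((6, 6, 6), np.uint8)
        tags[1, 1, 1:4] = 2
        tags[1, 2:4, 1] = 2
        sub = extract_tag(Volume(data), TagVolume(tags), 2, pad_value=0)
        assert sub.dims == (1, 3, 3)
        assert (sub.data[0, 0, :] == 100).all()
        assert sub.data[0, 1, 1] == 0 and sub.data[0, 2, 2] == 0

    def test_value_multiset_preserved(self, rng):
        data = rng.integers(0, 256, size=(6, 6, 6), dtype=np.uint8)
        tags = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        if not tags.any():
            tags[0, 0, 0] = 1
        sub = extract_tag(Volume(data), TagVolume(tags), 1, pad_value=0)
        box = tuple(slice(a.min(), a.max() + 1) for a in np.nonzero(tags))
        tagged_vals = sorted(data[tags == 1].tolist())
        sub_vals = sorted(sub.data[tags[box] == 1].tolist())
        assert tagged_vals == sub_vals

    def test_absent_tag_rejected(self):
        vol = Volume(np.zeros((4, 4, 4), np.uint8))
        with pytest.raises(EmptySelectionError):
            extract_tag(vol, TagVolume.zeros((4, 4, 4)), 5)
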