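"""Object extraction, level-set descriptors and classification.

Oracles: a hand-written flood fill for component labelling/counting, a
pairwise-distance exact EDT for the mean level-set value, and direct
continuum limits (ball: R/4, tube: r/3) as sanity bounds.
"""

from collections import deque

import numpy as np
import pytest

from purkinje3d.segmentation import (SegmentationParams, SegmentedObject,
                                     classify_objects, extract_objects,
                                     mean_level_set_value, segment_dendrite)
from purkinje3d.volumes import Volume


def _vol(mask: np.ndarray) -> Volume:
    """Binary mask as a response volume (1 inside, 0 outside)."""
    return Volume(mask.astype(np.float32), 1.75)


def _obj_from_mask(mask: np.ndarray) -> SegmentedObject:
    zz, yy, xx = np.nonzero(mask)
    return SegmentedObject(1, (zz, yy, xx), int(zz.size),
                           (float(zz.mean()), float(yy.mean()), float(xx.mean())))


def _ball_mask(shape, centre, radius):
    z, y, x = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return ((z - centre[0]) ** 2 + (y - centre[1]) ** 2
            + (x - centre[2]) ** 2) <= radius ** 2


def _flood_fill_components(mask: np.ndarray) -> list[int]:
    """Brute-force 26-connected component sizes."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    idx = np.argwhere(mask)
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for start in map(tuple, idx):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        n = 0
        while q:
            p = q.popleft()
            n += 1
            for off in offsets:
                nb = tuple(p[i] + off[i] for i in range(3))
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)) \
                        and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        sizes.append(n)
    return sorted(sizes)


def _exact_edt_mean(mask: np.ndarray) -> float:
    """|mean level set| by exhaustive pairwise distances to background centres."""
    from scipy.spatial.distance import cdist
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    d = cdist(inside, outside).min(axis=1)
    return float(d.mean())


# --- extract_objects ---------------------------------------------------------

def test_zero_response_yields_no_objects():
    assert extract_objects(_vol(np.zeros((40, 40, 40), bool))) == []


@pytest.mark.parametrize("box_shape,expected_cls", [
    ((1, 13, 23), "rejected_size"),    # 299 voxels: just below the gate
    ((3, 10, 10), "cell_candidate"),   # 300: inclusive lower edge
    ((10, 15, 20), "cell_candidate"),  # 3000: inclusive upper edge
    ((1, 1, 3001), "rejected_size"),   # 3001: just above the gate
])
def test_size_gate_boundary_behaviour(box_shape, expected_cls):
    shape = tuple(s + 30 for s in box_shape)
    mask = np.zeros(shape, bool)
    mask[tuple(slice(15, 15 + s) for s in box_shape)] = True
    objs = extract_objects(_vol(mask))
    assert len(objs) == 1
    assert objs[0].size_vox == int(np.prod(box_shape))
    if expected_cls == "cell_candidate":
        assert objs[0].cls not in ("rejected_size", "rejected_border")
    else:
        assert objs[0].cls == expected_cls


def test_two_blob_sizes_match_flood_fill_oracle():
    mask = np.zeros((60, 60, 60), bool)
    mask[15:20, 15:25, 15:23] = True            # 5*10*8 = 400, interior
    mask[35:43, 30:50, 30:50] = True            # 8*20*20 = 3200
    objs = extract_objects(_vol(mask))
    assert sorted(o.size_vox for o in objs) == _flood_fill_components(mask)
    by_size = {o.size_vox: o for o in objs}
    assert by_size[400].cls not in ("rejected_size", "rejected_border")
    assert by_size[3200].cls == "rejected_size"


def test_border_margin_rule_rejects_touching_objects():
    mask = np.zeros((60, 60, 60), bool)
    mask[5:12, 20:30, 20:30] = True   # reaches z = 5 < margin 10
    objs = extract_objects(_vol(mask))
    assert objs[0].cls == "rejected_border"
    # same object shifted inside the margin survives
    mask2 = np.zeros((60, 60, 60), bool)
    mask2[12:19, 20:30, 20:30] = True
    assert extract_objects(_vol(mask2))[0].cls not in (
        "rejected_size", "rejected_border")


def test_labelling_partitions_above_threshold_voxels():
    rng = np.random.default_rng(3)
    from scipy.ndimage import gaussian_filter, binary_closing, binary_fill_holes
    resp = gaussian_filter(rng.random((40, 40, 40)), 2.0)
    resp = (resp - resp.min()) / np.ptp(resp)
    p = SegmentationParams(min_size_vox=1, max_size_vox=10 ** 6,
                           border_margin_vox=0, response_threshold=0.6)
    objs = extract_objects(Volume(resp, 1.0), p)
    filled = binary_fill_holes(binary_closing(resp > 0.6, np.ones((3, 3, 3))))
    assert sum(o.size_vox for o in objs) == int(filled.sum())


# --- mean_level_set_value ----------------------------------------------------

def test_single_voxel_object_has_mean_lsv_minus_one():
    mask = np.zeros((9, 9, 9), bool)
    mask[4, 4, 4] = True
    assert mean_level_set_value(_obj_from_mask(mask), mask.shape) == pytest.approx(-1.0)


def test_ball_mean_lsv_matches_exact_edt_and_continuum_bound():
    mask = _ball_mask((25, 25, 25), (12, 12, 12), 8)
    got = mean_level_set_value(_obj_from_mask(mask), mask.shape)
    assert -got == pytest.approx(_exact_edt_mean(mask), rel=1e-9)
    assert -got == pytest.approx(8 / 4, rel=0.25)  # continuum R/4


def test_tube_mean_lsv_matches_exact_edt_and_continuum_bound():
    mask = np.zeros((70, 11, 11), bool)
    y, x = np.ogrid[:11, :11]
    disc = (y - 5) ** 2 + (x - 5) ** 2 <= 9
    mask[5:65] = disc
    got = mean_level_set_value(_obj_from_mask(mask), mask.shape)
    assert -got == pytest.approx(_exact_edt_mean(mask), rel=1e-9)
    # continuum limit r/3 plus the half-voxel centre-to-centre digitisation offset
    assert 3 / 3 <= -got <= 3 / 3 + 0.55


def test_empty_mask_raises():
    obj = SegmentedObject(1, (np.array([], int),) * 3, 0, (0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        mean_level_set_value(obj, (5, 5, 5))


# --- classify_objects --------------------------------------------------------

def test_sphere_rule_takes_precedence_over_tube_rule():
    """An object whose |mean_lsv| exceeds the sphere threshold is a corpus
    regardless of its tube ratio (rule order is fixed)."""
    mask = _ball_mask((25, 25, 25), (12, 12, 12), 8)   # |lsv| ≈ 2.2
    obj = _obj_from_mask(mask)
    p = SegmentationParams(sphere_lsv_threshold=1.8, tube_ratio_threshold=1.0)
    classify_objects([obj], p, mask.shape)
    assert obj.cls == "corpus"
    assert abs(obj.mean_lsv) > 1.8


def test_long_tube_classified_as_vessel_via_printed_ratio_rule():
    mask = np.zeros((70, 15, 15), bool)
    y, x = np.ogrid[:15, :15]
    mask[5:65] = (y - 7) ** 2 + (x - 7) ** 2 <= 9
    obj = _obj_from_mask(mask)
    classify_objects([obj], SegmentationParams(), mask.shape)
    # size ≈ 1700, |lsv| ≈ 1 → ratio well above 450
    assert obj.tube_ratio > 450
    assert obj.cls == "vessel"


def test_compact_ball_classified_as_cell_candidate():
    mask = _ball_mask((30, 30, 30), (15, 15, 15), 6)   # ≈ 900 vox, |lsv| ≈ 2
    obj = _obj_from_mask(mask)
    classify_objects([obj], SegmentationParams(), mask.shape)
    assert obj.tube_ratio == pytest.approx(obj.size_vox / obj.mean_lsv ** 2)
    assert obj.tube_ratio <= 450
    assert obj.cls == "cell_candidate"


def test_classification_is_order_independent(rng):
    masks = [_ball_mask((30, 30, 30), (15, 15, 15), r) for r in (4, 6, 8)]
    objs = [_obj_from_mask(m) for m in masks]
    import copy
    a = classify_objects(copy.deepcopy(objs), SegmentationParams(), (30, 30, 30))
    b = classify_objects(copy.deepcopy(objs)[::-1], SegmentationParams(), (30, 30, 30))
    assert [o.cls for o in a] == [o.cls for o in b[::-1]]


# --- segment_dendrite --------------------------------------------------------

def test_dendrite_mode_selects_largest_component_matching_oracle():
    from purkinje3d.phantom import make_dendrite_phantom
    vol, info = make_dendrite_phantom(shape=(80, 80, 80), rng_seed=0)
    obj = segment_dendrite(vol)
    # independent largest-component oracle on the same response field
    from purkinje3d.vesselness import DENDRITE_MODE, frangi_response
    from skimage.measure import label
    resp = frangi_response(vol, DENDRITE_MODE).data
    lab = label(resp > 0.05, connectivity=3)
    sizes = np.bincount(lab.ravel())[1:]
    assert obj.size_vox == int(sizes.max())
    # the returned object hugs the planted tree, not the decoy
    from scipy.spatial import cKDTree
    tree = cKDTree(np.column_stack(obj.coords))
    d_tree, _ = tree.query(np.vstack(info["tree"]) / vol.voxel_len_um)
    d_decoy, _ = tree.query(info["decoy"] / vol.voxel_len_um)
    assert d_tree.max() < 6
    assert d_decoy.min() > 8


def test_dendrite_empty_response_raises():
    flat = Volume(np.full((40, 40, 40), 0.5, np.float32), 0.45)
    with pytest.raises(ValueError, match="no object"):
        segment_dendrite(flat)
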