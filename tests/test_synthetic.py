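"""Generator contracts: determinism, conservation, composition physics."""
import math

import numpy as np
import pytest

import her2quant as hq
from her2quant.errors import InvalidInputError, PatchTooCrowdedError
from her2quant.scoring import DEFAULT_INTERVALS


def test_empty_patch_is_blank_white():
    img, truth = hq.make_patch(0, rng_seed=0, size=64)
    assert len(truth.cells) == 0
    assert (img.pixels == 255).all()
    assert not truth.tissue_mask.pixels.any()


@pytest.mark.parametrize(
    "n,frac,expected", [(50, 0.2, 10), (10, 0.9, 9), (3, 0.5, 2), (7, 0.0, 0)]
)
def test_positive_count_conservation(n, frac, expected):
    _, truth = hq.make_patch(n, positive_fraction=frac, dab_od=0.8, rng_seed=7)
    assert truth.n_positive == expected
    assert len(truth.cells) == n


def test_label_image_matches_cell_count():
    _, truth = hq.make_patch(30, positive_fraction=0.5, rng_seed=3)
    labels = np.unique(truth.cell_label_image)
    assert len(labels[labels > 0]) == 30
    # every center lies inside the tissue mask
    for cell in truth.cells:
        r, c = int(round(cell.center[0])), int(round(cell.center[1]))
        assert truth.tissue_mask.pixels[r, c]


def test_determinism_bit_identical():
    a_img, a_truth = hq.make_patch(25, 0.4, 0.7, 0.6, rng_seed=11)
    b_img, b_truth = hq.make_patch(25, 0.4, 0.7, 0.6, rng_seed=11)
    np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
    np.testing.assert_array_equal(a_truth.cell_label_image, b_truth.cell_label_image)
    assert [c.center for c in a_truth.cells] == [c.center for c in b_truth.cells]


def test_too_crowded_raises():
    with pytest.raises(PatchTooCrowdedError):
        hq.make_patch(200, rng_seed=0, size=64)


def test_compose_zero_od_is_white(vectors):
    rgb = hq.compose_from_od(np.zeros((4, 4)), np.zeros((4, 4)), vectors)
    assert (rgb == 255).all()


def test_compose_single_pixel_hand_value(vectors):
    """One pixel of unit hematoxylin OD: I_c = round(255 * 10**-v_c)."""
    od_h = np.zeros((2, 2))
    od_h[0, 0] = 1.0
    rgb = hq.compose_from_od(od_h, np.zeros((2, 2)), vectors)
    expected = [
        math.floor(255.0 * 10.0 ** -v + 0.5) for v in vectors.od_hematoxylin
    ]
    assert list(rgb[0, 0]) == expected
    assert list(rgb[1, 1]) == [255, 255, 255]


def test_compose_shape_mismatch_rejected(vectors):
    with pytest.raises(InvalidInputError):
        hq.compose_from_od(np.zeros((3, 3)), np.zeros((4, 4)), vectors)


def test_compose_deconvolve_roundtrip(vectors):
    rng = np.random.default_rng(0)
    h = rng.uniform(0, 0.7, (32, 32))
    d = rng.uniform(0, 0.7, (32, 32))
    rgb = hq.compose_from_od(h, d, vectors)
    maps = hq.deconvolve(rgb, vectors)
    assert np.abs(maps.h_map - h).max() < 0.02
    assert np.abs(maps.dab_map - d).max() < 0.02


def test_stain_vectors_invariants(vectors):
    for v in (vectors.od_hematoxylin, vectors.od_dab, vectors.od_residual):
        assert abs(np.linalg.norm(v) - 1.0) < 1e-9
    assert np.linalg.cond(vectors.matrix) < 1e6


def test_pyramid_level_dimensions():
    pyr, _ = hq.make_slide("0", n_tiles=1, rng_seed=0, n_levels=3)
    h0, w0 = pyr.level_dimensions[0]
    for k, (h, w) in enumerate(pyr.level_dimensions):
        assert (h, w) == (math.ceil(h0 / 2**k), math.ceil(w0 / 2**k))


def test_class0_slide_has_no_dab():
    _, truth = hq.make_slide("0", n_tiles=2, rng_seed=1)
    assert all(c.dab_od == 0.0 for c in truth.cells)
    assert truth.aggregate["staining_intensity"] == 0.0


def test_3plus_circumferential_inside_reference_interval():
    _, truth = hq.make_slide("3+", n_tiles=2, rng_seed=1)
    lo, hi = DEFAULT_INTERVALS["circumferential"]["3+"]
    assert lo <= truth.aggregate["circumferential_ratio"] <= hi


@pytest.mark.parametrize("cls", hq.IHC_CLASSES)
def test_class_separability_of_planned_aggregates(cls):
    """200 planned slides per class: aggregates strictly inside the class
    reference intervals for all three indexes."""
    key = {
        "staining_intensity": "staining",
        "positive_cell_ratio": "positive_ratio",
        "circumferential_ratio": "circumferential",
    }
    for seed in range(200):
        rng = np.random.default_rng(seed)
        plan = hq.plan_slide(cls, 2, rng)
        for feat, idx in key.items():
            lo, hi = DEFAULT_INTERVALS[idx][cls]
            assert lo <= plan.aggregate[feat] <= hi, (cls, seed, feat)


def test_slide_cell_centers_inside_tissue(slide_2plus):
    _, truth = slide_2plus
    for cell in truth.cells:
        r, c = int(round(cell.center[0])), int(round(cell.center[1]))
        assert truth.tissue_mask.pixels[r, c]


def test_overlapping_pair_merges_nuclei():
    _, truth = hq.make_overlapping_pair(rng_seed=0)
    assert len(truth.cells) == 2
    maps = hq.deconvolve(hq.make_overlapping_pair(rng_seed=0)[0].pixels)
    from scipy import ndimage as ndi

    _, n = ndi.label(maps.h_map > 0.25)
    assert n == 1  # the two nuclei touch: one connected blob


def test_ground_truth_writer_roundtrip(tmp_path):
    import json

    _, truth = hq.make_patch(5, positive_fraction=0.4, rng_seed=2, size=128)
    from her2quant.synthetic import write_ground_truth

    write_ground_truth(tmp_path, truth)
    payload = json.loads((tmp_path / "ground_truth.json").read_text())
    assert len(payload["cells"]) == 5
    assert sum(c["is_positive"] for c in payload["cells"]) == 2
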