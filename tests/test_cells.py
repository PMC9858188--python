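"""DAB extraction, staining intensity, deconvolution, watershed segmentation
and membrane-ring measurement against generator ground truth."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

import her2quant as hq
from conftest import stained_pixel_mask
from her2quant.cells import positive_labels
from her2quant.synthetic import expected_intensity


def test_dab_mask_empty_on_unstained_inputs():
    img, _ = hq.make_patch(20, positive_fraction=0.0, rng_seed=2, size=192)
    assert not hq.extract_dab_mask(img.pixels).any()  # hematoxylin only
    white = np.full((64, 64, 3), 255, np.uint8)
    assert not hq.extract_dab_mask(white).any()


def test_dab_mask_recall_precision(stained_patch):
    img, truth = stained_patch
    mask = hq.extract_dab_mask(img.pixels)
    true = stained_pixel_mask(truth, mask.shape)
    recall = (mask & true).sum() / true.sum()
    precision = (mask & true).sum() / mask.sum()
    assert recall >= 0.95
    assert precision >= 0.95


def test_intensity_empty_mask_is_zero():
    img = np.full((8, 8, 3), 100, np.uint8)
    assert hq.staining_intensity(img, np.zeros((8, 8), bool)) == 0.0


def test_intensity_black_is_one():
    img = np.zeros((8, 8, 3), np.uint8)
    assert hq.staining_intensity(img, np.ones((8, 8), bool)) == 1.0


@pytest.mark.parametrize("dab_od", [0.3, 0.6, 1.0])
def test_intensity_matches_closed_form(dab_od, vectors):
    """Pure-DAB pixels at concentration d score 1 - luma(255*10^-d*v)/255."""
    od = np.full((16, 16), dab_od)
    img = hq.compose_from_od(np.zeros_like(od), od, vectors)
    measured = hq.staining_intensity(img, np.ones((16, 16), bool))
    assert measured == pytest.approx(expected_intensity(dab_od, vectors), abs=0.01)


def test_intensity_monotone_under_darkening(stained_patch):
    img, _ = stained_patch
    mask = hq.extract_dab_mask(img.pixels)
    darker = (img.pixels.astype(float) * 0.8).astype(np.uint8)
    assert hq.staining_intensity(darker, mask) > hq.staining_intensity(
        img.pixels, mask
    )


def test_deconvolve_white_patch_zero(vectors):
    white = np.full((8, 8, 3), 255, np.uint8)
    maps = hq.deconvolve(white, vectors)
    assert maps.h_map.max() == 0 and maps.dab_map.max() == 0


def test_deconvolve_pure_stain_crosstalk(vectors):
    od = np.full((8, 8), 0.5)
    h_only = hq.compose_from_od(od, np.zeros_like(od), vectors)
    assert hq.deconvolve(h_only, vectors).dab_map.max() < 0.02
    d_only = hq.compose_from_od(np.zeros_like(od), od, vectors)
    assert hq.deconvolve(d_only, vectors).h_map.max() < 0.02


def test_deconvolve_roundtrip_many_maps(vectors):
    rng = np.random.default_rng(7)
    for _ in range(20):
        h = rng.uniform(0, 0.7, (24, 24))
        d = rng.uniform(0, 0.7, (24, 24))
        maps = hq.deconvolve(hq.compose_from_od(h, d, vectors), vectors)
        assert np.abs(maps.h_map - h).max() < 0.02
        assert np.abs(maps.dab_map - d).max() < 0.02


def test_segment_blank_patch():
    labels, cells = hq.segment_cells(np.zeros((64, 64)))
    assert cells == [] and labels.max() == 0


@pytest.mark.parametrize("seed", range(5))
def test_segment_exact_count_and_centroids(seed):
    img, truth = hq.make_patch(50, positive_fraction=0.3, dab_od=0.8, rng_seed=seed)
    maps = hq.deconvolve(img.pixels)
    _, cells = hq.segment_cells(maps.h_map)
    assert len(cells) == 50
    d, _ = cKDTree([c.center for c in truth.cells]).query(
        [c.centroid for c in cells]
    )
    assert d.max() < 3.0


def test_watershed_splits_overlapping_pair():
    img, _ = hq.make_overlapping_pair(rng_seed=4)
    maps = hq.deconvolve(img.pixels)
    _, cells = hq.segment_cells(maps.h_map)
    assert len(cells) == 2


@pytest.mark.parametrize("seed", range(3))
def test_crowded_layout_within_ten_percent(seed):
    img, truth = hq.make_patch(
        60, positive_fraction=0.0, rng_seed=seed, min_center_distance=1.4 * 8.0
    )
    maps = hq.deconvolve(img.pixels)
    _, cells = hq.segment_cells(maps.h_map)
    assert abs(len(cells) - 60) <= 6


def test_measure_ring_empty_dab(stained_patch):
    img, _ = stained_patch
    maps = hq.deconvolve(img.pixels)
    _, cells = hq.segment_cells(maps.h_map)
    cell = hq.measure_ring(cells[0], np.zeros(maps.h_map.shape, bool))
    assert cell.ring_dab_fraction == 0.0 and not cell.dab_overlap


@pytest.mark.parametrize(
    "completeness,lo,hi", [(1.0, 0.9, 1.0), (0.5, 0.35, 0.65)]
)
def test_ring_fraction_tracks_completeness(completeness, lo, hi):
    img, truth = hq.make_patch(
        12, positive_fraction=1.0, completeness=completeness, dab_od=0.8, rng_seed=9
    )
    intensity, dab, labels, cells = hq.measure_patch(img)
    assert len(cells) == 12
    for cell in cells:
        assert cell.dab_overlap
        assert lo <= cell.ring_dab_fraction <= hi


@pytest.mark.parametrize("seed,p", [(0, 0.3), (1, 0.6), (2, 1.0), (3, 0.1)])
def test_mask_product_equals_bruteforce_positivity(seed, p):
    """The fast mask-product rule equals the per-pixel definition: a cell is
    positive iff at least one of its pixels is stain-positive."""
    img, _ = hq.make_patch(40, positive_fraction=p, dab_od=0.7, rng_seed=seed)
    _, dab, labels, cells = hq.measure_patch(img)
    fast = positive_labels(labels, dab)
    brute = set()
    for cell in cells:
        r0, c0, r1, c1 = cell.bbox
        if (dab[r0:r1, c0:c1] & cell.region_mask).any():
            brute.add(cell.label)
    assert fast == brute
    assert {c.label for c in cells if c.dab_overlap} == brute
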