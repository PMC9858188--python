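"""Index computation, aggregation, threshold-table classification and the
clinical rule engine."""
import numpy as np
import pytest

import her2quant as hq
from her2quant.cells import CellInstance
from her2quant.errors import InvalidInputError, NoTumorTilesError
from her2quant.scoring import IHC_CLASSES


def _cell(dab_overlap=False, ring_fraction=0.0):
    return CellInstance(
        label=1,
        contour=np.empty((0, 2)),
        centroid=(0.0, 0.0),
        area=10,
        bbox=(0, 0, 1, 1),
        region_mask=np.ones((1, 1), bool),
        dab_overlap=dab_overlap,
        ring_dab_fraction=ring_fraction,
    )


def _features(staining=0.0, pos=0.0, circ=0.0, n_tiles=1, n_cells=100):
    return hq.SlideFeatures(
        staining_intensity=staining,
        positive_cell_ratio=pos,
        circumferential_ratio=circ,
        n_tiles=n_tiles,
        n_cells=n_cells,
    )


def test_patch_features_zero_cells_flagged():
    f = hq.patch_features([], intensity=0.3)
    assert (f.positive_cell_ratio, f.circumferential_ratio) == (0.0, 0.0)
    assert f.staining_intensity == 0.3
    assert f.low_confidence


def test_patch_features_direct_counting():
    cells = (
        [_cell(True, 0.95), _cell(True, 0.95)]
        + [_cell(True, 0.4)]
        + [_cell(False)] * 7
    )
    f = hq.patch_features(cells, intensity=0.5, completeness_cutoff=0.9)
    assert f.positive_cell_ratio == pytest.approx(0.3)
    assert f.circumferential_ratio == pytest.approx(2 / 3)
    assert f.n_cells == 10 and f.n_positive == 3


def test_patch_features_recover_generator_fraction():
    img, truth = hq.make_patch(50, positive_fraction=0.4, dab_od=0.8, rng_seed=6)
    intensity, _, _, cells = hq.measure_patch(img)
    f = hq.patch_features(cells, intensity)
    assert f.positive_cell_ratio == pytest.approx(0.4, abs=0.05)
    assert f.circumferential_ratio == pytest.approx(1.0, abs=0.05)


def test_aggregate_identity_and_means():
    one = hq.PatchFeatures(0.2, 0.3, 0.4, n_cells=10, n_positive=3)
    agg = hq.aggregate_slide([one])
    assert (agg.staining_intensity, agg.positive_cell_ratio) == (0.2, 0.3)
    two = [
        hq.PatchFeatures(0.2, 0.2, 0.0, n_cells=10, n_positive=2),
        hq.PatchFeatures(0.4, 0.4, 0.0, n_cells=10, n_positive=4),
    ]
    assert hq.aggregate_slide(two).positive_cell_ratio == pytest.approx(0.3)
    weighted = [
        hq.PatchFeatures(0.0, 0.1, 0.0, n_cells=10, n_positive=1),
        hq.PatchFeatures(0.0, 0.5, 0.0, n_cells=30, n_positive=15),
    ]
    assert hq.aggregate_slide(weighted).positive_cell_ratio == pytest.approx(0.4)


def test_aggregate_empty_errors():
    with pytest.raises(NoTumorTilesError):
        hq.aggregate_slide([])


def test_threshold_table_midpoint_boundaries():
    table = hq.ThresholdTable()
    assert table.boundaries("staining") == pytest.approx((0.007, 0.1675, 0.454))
    assert table.boundaries("positive_ratio") == pytest.approx(
        (0.0225, 0.1275, 0.2455)
    )
    assert table.boundaries("circumferential") == pytest.approx(
        (0.0055, 0.407, 0.601)
    )


def test_threshold_table_rejects_disordered_intervals():
    bad = {
        idx: dict(cls_map) for idx, cls_map in hq.DEFAULT_INTERVALS.items()
    }
    bad["staining"] = dict(bad["staining"], **{"3+": (0.0, 0.01)})
    with pytest.raises(InvalidInputError):
        hq.ThresholdTable(intervals=bad)


def test_classify_staining_only_examples():
    assert hq.classify_staining_only(_features(staining=0.0)).ihc_class == "0"
    score = hq.classify_staining_only(_features(staining=0.58))
    assert score.ihc_class == "3+" and score.her2_status == "Positive"
    # values exactly on a boundary assign upward
    assert hq.classify_staining_only(_features(staining=0.454)).ihc_class == "3+"
    assert hq.classify_staining_only(_features(staining=0.1675)).ihc_class == "2+"


def test_classify_integrated_median_votes():
    score = hq.classify_integrated(_features(staining=0.58, pos=0.30, circ=0.80))
    assert score.ihc_class == "3+" and score.her2_status == "Positive"
    assert not score.ish_reflex
    # votes (1+, 2+, 2+) -> 2+ with the ISH-reflex flag
    score = hq.classify_integrated(_features(staining=0.10, pos=0.20, circ=0.50))
    assert score.votes == {
        "staining": "1+",
        "positive_ratio": "2+",
        "circumferential": "2+",
    }
    assert score.ihc_class == "2+" and score.ish_reflex
    assert score.her2_status.startswith("Equivocal")
    zero = hq.classify_integrated(_features())
    assert zero.ihc_class == "0" and zero.her2_status == "Negative"


def test_integrated_monotone_in_each_feature():
    rng = np.random.default_rng(12)
    for _ in range(200):
        s, p, c = rng.uniform(0, 0.7), rng.uniform(0, 0.4), rng.uniform(0, 1)
        base = IHC_CLASSES.index(
            hq.classify_integrated(_features(s, p, c)).ihc_class
        )
        bump = rng.uniform(0, 0.3)
        for kwargs in (
            {"staining": min(s + bump, 1.0), "pos": p, "circ": c},
            {"staining": s, "pos": min(p + bump, 1.0), "circ": c},
            {"staining": s, "pos": p, "circ": min(c + bump, 1.0)},
        ):
            up = IHC_CLASSES.index(
                hq.classify_integrated(
                    _features(kwargs["staining"], kwargs["pos"], kwargs["circ"])
                ).ihc_class
            )
            assert up >= base


def _csco_oracle(ci, wi, any_s):
    """Independent restatement of the clinical rule table, checked row by row."""
    rows = [
        ("3+", ci > 0.10),
        ("2+", ci > 0.0 and ci <= 0.10),
        ("1+", ci == 0.0 and any_s and wi > 0.10),
    ]
    for cls, hit in rows:
        if hit:
            return cls
    return "0"


@pytest.mark.parametrize(
    "ci,wi,any_s,expected",
    [
        (0.11, 0.0, True, "3+"),
        (0.10, 0.0, True, "2+"),  # strict > at the 10% boundary
        (0.09, 0.0, True, "2+"),
        (0.0, 0.40, True, "1+"),
        (0.0, 0.10, True, "0"),
        (0.0, 0.0, False, "0"),
    ],
)
def test_csco_rule_examples(ci, wi, any_s, expected):
    assert hq.apply_csco_rules(ci, wi, any_s) == expected


def test_csco_rules_match_truth_table_grid():
    for ci in np.arange(0, 1.001, 0.01):
        for wi in np.arange(0, 1.001, 0.05):
            for any_s in (True, False):
                ci_, wi_ = round(float(ci), 2), round(float(wi), 2)
                assert hq.apply_csco_rules(ci_, wi_, any_s) == _csco_oracle(
                    ci_, wi_, any_s
                )


def test_csco_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        hq.apply_csco_rules(1.2, 0.0, True)
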