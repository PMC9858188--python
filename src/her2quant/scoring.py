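"""Slide scoring: the three evaluation indexes and the IHC 0/1+/2+/3+ call.

Per tumor tile the pipeline measures three interpretable indexes:

* ``staining_intensity`` - mean darkness of the extracted DAB area, in [0, 1];
* ``positive_cell_ratio`` - DAB-positive cells / all cells;
* ``circumferential_ratio`` - cells whose membrane band is covered on at
  least ``completeness_cutoff`` of its circumference, as a fraction of the
  positive cells (the "complete circumferential staining" notion that
  defines 3+ clinically).

Slide-level aggregates are compared against per-class reference intervals
(the default table is a single-center statistical calibration); decision
boundaries are midpoints between adjacent class intervals, values on a
boundary are assigned upward.  The integrated method takes the median of the
three per-index ordinal votes; 2+ calls always carry an ISH-reflex flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import CellInstance
from .errors import InvalidInputError, NoTumorTilesError

IHC_CLASSES = ("0", "1+", "2+", "3+")
INDEXES = ("staining", "positive_ratio", "circumferential")

#: HER2 expression status implied by each IHC class; 2+ reflexes to ISH.
HER2_STATUS = {
    "0": "Negative",
    "1+": "Low expression",
    "2+": "Equivocal (reflex ISH)",
    "3+": "Positive",
}

#: Default per-class intervals for the three indexes (single-center
#: statistical calibration: min/max of each index per confirmed class).
DEFAULT_INTERVALS: dict[str, dict[str, tuple[float, float]]] = {
    "staining": {
        "0": (0.000, 0.008),
        "1+": (0.006, 0.189),
        "2+": (0.146, 0.367),
        "3+": (0.541, 0.611),
    },
    "positive_ratio": {
        "0": (0.000, 0.041),
        "1+": (0.004, 0.125),
        "2+": (0.130, 0.318),
        "3+": (0.173, 0.338),
    },
    "circumferential": {
        "0": (0.000, 0.000),
        "1+": (0.011, 0.360),
        "2+": (0.454, 0.741),
        "3+": (0.461, 0.908),
    },
}


@dataclass
class PatchFeatures:
    """The three indexes measured on one tumor tile."""

    staining_intensity: float
    positive_cell_ratio: float
    circumferential_ratio: float
    n_cells: int
    n_positive: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        for v in (
            self.staining_intensity,
            self.positive_cell_ratio,
            self.circumferential_ratio,
        ):
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError("indexes must lie in [0, 1]")


@dataclass
class SlideFeatures:
    """Tile aggregates of the three indexes."""

    staining_intensity: float
    positive_cell_ratio: float
    circumferential_ratio: float
    n_tiles: int
    n_cells: int = 0


@dataclass
class SlideScore:
    """Final slide call with per-index votes and clinical status."""

    ihc_class: str
    method: str
    votes: dict[str, str]
    her2_status: str
    ish_reflex: bool


@dataclass
class ThresholdTable:
    """Per-class intervals per index, plus derived decision boundaries.

    The boundary between adjacent classes is the midpoint of the gap (or
    overlap) between their intervals; values equal to a boundary are
    assigned to the higher class.
    """

    intervals: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            idx: dict(cls_map) for idx, cls_map in DEFAULT_INTERVALS.items()
        }
    )

    def __post_init__(self) -> None:
        for idx in INDEXES:
            if idx not in self.intervals:
                raise InvalidInputError(f"missing index {idx!r}")
            mins = [self.intervals[idx][c][0] for c in IHC_CLASSES]
            maxs = [self.intervals[idx][c][1] for c in IHC_CLASSES]
            if any(b < a for a, b in zip(mins, mins[1:])) or any(
                b < a for a, b in zip(maxs, maxs[1:])
            ):
                raise InvalidInputError(f"class intervals not ordered for {idx!r}")
            b = self.boundaries(idx)
            if not all(x < y for x, y in zip(b, b[1:])):
                raise InvalidInputError(f"boundaries not increasing for {idx!r}")

    def boundaries(self, index: str) -> tuple[float, ...]:
        ivs = self.intervals[index]
        return tuple(
            (ivs[lo][1] + ivs[hi][0]) / 2.0
            for lo, hi in zip(IHC_CLASSES, IHC_CLASSES[1:])
        )

    def classify_value(self, index: str, value: float) -> str:
        """Class whose boundaries bracket ``value`` (>= assigns upward)."""
        k = sum(value >= b for b in self.boundaries(index))
        return IHC_CLASSES[k]

    def interval(self, index: str, ihc_class: str) -> tuple[float, float]:
        return self.intervals[index][ihc_class]


def patch_features(
    cells: list[CellInstance],
    intensity: float,
    completeness_cutoff: float = 0.9,
) -> PatchFeatures:
    """Compute the three indexes from measured cells and staining intensity.

    A tile without cells yields zero ratios and is flagged low-confidence.
    """
    if not 0.0 <= intensity <= 1.0:
        raise InvalidInputError("intensity must lie in [0, 1]")
    n = len(cells)
    n_pos = sum(c.dab_overlap for c in cells)
    n_complete = sum(
        c.dab_overlap and c.ring_dab_fraction >= completeness_cutoff for c in cells
    )
    return PatchFeatures(
        staining_intensity=intensity,
        positive_cell_ratio=n_pos / n if n else 0.0,
        circumferential_ratio=n_complete / n_pos if n_pos else 0.0,
        n_cells=n,
        n_positive=n_pos,
        low_confidence=n == 0,
    )


def aggregate_slide(features: list[PatchFeatures]) -> SlideFeatures:
    """Aggregate tumor-tile features to slide level.

    Staining intensity averages over all tumor tiles; the positive-cell
    ratio is cell-count weighted and the circumferential ratio is weighted
    by positive-cell count, so each ratio keeps its natural denominator.
    """
    if not features:
        raise NoTumorTilesError("no tumor tiles to aggregate")
    intensity = float(np.mean([f.staining_intensity for f in features]))
    n_cells = sum(f.n_cells for f in features)
    n_pos = sum(f.n_positive for f in features)
    pos = (
        sum(f.positive_cell_ratio * f.n_cells for f in features) / n_cells
        if n_cells
        else 0.0
    )
    circ = (
        sum(f.circumferential_ratio * f.n_positive for f in features) / n_pos
        if n_pos
        else 0.0
    )
    return SlideFeatures(
        staining_intensity=intensity,
        positive_cell_ratio=float(pos),
        circumferential_ratio=float(circ),
        n_tiles=len(features),
        n_cells=n_cells,
    )


def _score(ihc_class: str, method: str, votes: dict[str, str]) -> SlideScore:
    return SlideScore(
        ihc_class=ihc_class,
        method=method,
        votes=votes,
        her2_status=HER2_STATUS[ihc_class],
        ish_reflex=ihc_class == "2+",
    )


def classify_staining_only(
    slide: SlideFeatures, table: ThresholdTable | None = None
) -> SlideScore:
    """Classify from the staining-intensity index alone."""
    table = table or ThresholdTable()
    cls = table.classify_value("staining", slide.staining_intensity)
    return _score(cls, "staining_only", {"staining": cls})


def classify_integrated(
    slide: SlideFeatures, table: ThresholdTable | None = None
) -> SlideScore:
    """Median of the three per-index ordinal votes.

    With three voters the median is always well defined; it reduces to the
    staining-only call when all indexes agree and is monotone in every
    feature.
    """
    table = table or ThresholdTable()
    votes = {
        "staining": table.classify_value("staining", slide.staining_intensity),
        "positive_ratio": table.classify_value(
            "positive_ratio", slide.positive_cell_ratio
        ),
        "circumferential": table.classify_value(
            "circumferential", slide.circumferential_ratio
        ),
    }
    ordinals = sorted(IHC_CLASSES.index(v) for v in votes.values())
    cls = IHC_CLASSES[ordinals[1]]
    return _score(cls, "integrated", votes)


def apply_csco_rules(
    percent_complete_intense: float,
    percent_weak_incomplete: float,
    any_staining: bool,
) -> str:
    """IHC class from the clinical (CSCO-style) rule table.

    * 3+ - complete, intense circumferential staining in **more than** 10 %
      of invasive tumor cells (strict inequality at the 10 % boundary);
    * 2+ - complete intense staining present but in <= 10 % of cells (the
      equivocal clause; the weak-to-moderate >10 % clause is not
      representable with these two fractions alone);
    * 1+ - faint/incomplete membrane staining in more than 10 % of cells;
    * 0 - everything else (no staining, or faint staining in <= 10 %).
    """
    for v in (percent_complete_intense, percent_weak_incomplete):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError("fractions must lie in [0, 1]")
    if percent_complete_intense > 0.10:
        return "3+"
    if percent_complete_intense > 0.0:
        return "2+"
    if any_staining and percent_weak_incomplete > 0.10:
        return "1+"
    return "0"
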