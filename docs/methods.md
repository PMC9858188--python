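# Methods

## Staining model

Bright-field IHC follows the Beer–Lambert law: transmitted light in channel
`c ∈ {R,G,B}` is `I_c = 255 · 10^(−Σ_s OD_sc · conc_s)`, so stain
concentrations add linearly in optical density `OD_c = −log10(I_c/255)`.
Each stain is a unit 3-vector of per-channel optical densities; the package
defaults to the Ruifrok–Johnston H-DAB pair (hematoxylin
`(0.650, 0.704, 0.286)`, DAB `(0.268, 0.570, 0.776)`) with the residual
channel completing the basis via the normalized cross product (condition
number ≈ 3). Color deconvolution multiplies pixel OD vectors by the inverse
stain matrix and floors negative concentrations at zero. Base-10 logarithms
are used throughout — composition and deconvolution must share a base for
the round-trip to close — with natural log available via `od_base`.
Intensity is floored at 1 before the log so OD stays finite.

With concentrations bounded by 0.7 per stain (total per-channel OD ≤ 0.89,
consistent with OD values of order 1), 8-bit quantization limits round-trip
error to ≈ 0.013 OD after inverse-matrix amplification; the tested bound is
0.02 OD. At higher concentrations the quantization error of dark pixels
(ΔOD ≈ 0.434·0.5/I) grows hyperbolically, which is why the round-trip
checks sample below 0.7.

## Synthetic data: what it emulates and what it does not

`make_patch`/`make_slide` render white background (full transmission),
nuclei as filled hematoxylin ellipses (axes 3.6–4.6 px, OD 0.50–0.85 at
~0.5 µm/px, 20×), and membranes as 2 px DAB annuli of radius 8 px whose
stained arc starts at a seeded random angle and covers a controllable
fraction of the circumference — the geometric encoding of "complete" vs
"incomplete" membrane staining. Cell centers are rejection-sampled with a
minimum spacing of `2·membrane_radius + 4` px; the 4 px guard guarantees
that every membrane pixel is nearer to its own nucleus than to any
neighbour's, so label expansion attributes membranes unambiguously. A
crowded mode (spacing 1.4·radius) and an adherent two-cell fixture
(nucleus radius 6 px at 10.8 px spacing, producing one merged blob) exist
for stress-testing the watershed. Quantization is 8-bit round-half-up.

Slides place 512 px content tiles on a tile-aligned grid inside a white
border, under an irregular tissue blob carrying a faint hematoxylin tint
(OD 0.10) that stands in for cytoplasm; membranes are rendered as pure DAB
(no tint underneath) so ground-truth arc coverage is exact. Pyramid levels
are 2×-downsampled (level k has dims ⌈dims₀/2ᵏ⌉).

Per-class slide parameters are drawn from windows that sit strictly inside
the class reference intervals *and* on the correct side of the derived
decision boundaries, with margin for rasterization noise; positive and
complete cell counts are apportioned across tiles by largest remainder and
clamped so the coarse ratios of small counts stay inside the window. The
"ambiguous staining" mode draws 1+/2+ intensities from 0.150–0.185, legal
for both classes but straddling their boundary (0.1675) — the only
index/class combination where interval-legal staining can cross a boundary
— making staining uninformative while the other two indexes still separate
the classes.

Not emulated: scanner noise, focus blur, tissue folds, stain-batch
variation, nuclear pleomorphism, stromal/immune cells, and realistic cell
density (tens of cells per tile rather than thousands). Passing tests
therefore demonstrate correctness of the measurement chain under the
staining model, not robustness to real-slide artifacts; on real material
the HSV brown gate and the threshold table would need center-specific
calibration.

## Tissue masking

Masking runs on the highest-resolution pyramid level whose longest side is
≤ 2048 px. Hue and saturation (scaled to 0–255) are each thresholded by an
exact Otsu implementation (ties broken toward the smallest threshold);
tissue is the high side of both, combined with AND by default (white
background has S≈0 regardless of hue; OR is available). Components *and
holes* smaller than 0.1 % of the mask area are filtered — thin membrane
annuli fall on the background side of the hue threshold and would
otherwise punch pinholes in the mask. Tiles are enumerated on a 0-based,
half-open, row-major level-0 grid; a tile is admitted at ≥ 25 % tissue.

## Tumor detection

The classifier contract maps batches of square 8-bit RGB patches to tumor
probabilities. The default heuristic is a fixed logistic over mean
saturation, mean value and DAB-pixel fraction with coefficients
`(80, −2, 300)` and bias 0.6, chosen from the closed-form color model
(saturation tracks both counterstain density and stain intensity). The
trainable backend is a scikit-learn MLP (one 32-unit hidden layer) over
nine color/stain summary features, fitted with SGD at learning rate 0.01,
momentum 0.9, minibatch 64, 50 epochs, on a 9:1 split — deliberately the
same optimizer settings as a conventional deep-learning patch classifier —
and records its loss curve and validation accuracy. Probability maps are
independent of tile order and batch size; the map is binarized at 0.5 (≥
assigns tumor), and a 512 px scoring tile is admitted when the mean
binarized probability over its 256 px footprint is ≥ 0.5.

## Index measurement

- **DAB gate**: hue 8–40°, S ≥ 0.08, V 0.10–1.0. Under the forward model a
  pure-DAB pixel's saturation approximately equals its staining intensity
  (both ≈ 1.17·d for small concentration d), so the S floor is what bounds
  the faintest measurable stain; 0.08 keeps the faint end of the 1+ range
  measurable. Morphological cleanup is a 3×3 closing only — an opening
  would erase 2 px membranes.
- **Intensity**: mean of `1 − luma/255` (Rec. 601) over the gate; an empty
  gate scores 0.0, matching the zero floor of the IHC-0 interval.
- **Segmentation**: Otsu on the hematoxylin map's histogram → 3×3 opening →
  hole filling → Euclidean distance transform → `peak_local_max` markers
  (minimum separation 0.7 × median component radius, floor 2 px; components
  without a peak get their EDT argmax) → watershed → area filter
  (min 30 px²) → clumps above 3× median area split into
  `round(area/median)` parts by k-means on coordinates (fixed seed) →
  labels expanded 6 px outward to whole-cell extents (nucleus edge ≈ 4 px +
  6 ≈ membrane radius 8–10 px).
- **Positivity**: mask-product rule — a cell is positive iff its expanded
  region intersects the DAB gate; provably identical to scanning each
  cell's pixels, and tested against that brute force.
- **Ring completeness**: the cell boundary dilated by 2 px forms the
  membrane band; coverage is the fraction of 36 ten-degree angular sectors
  around the centroid containing at least one DAB pixel inside the band.
  Angular occupancy measures arc completeness directly and is insensitive
  to the 1–2 px radial mismatch between the expanded boundary and the true
  membrane, where a pixel-count quotient would systematically undershoot.
  A cell is "complete" at ≥ 0.9 coverage (the `completeness_cutoff`);
  36 bins keep ≈ 2 band pixels per sector so a fully stained ring is not
  penalized by empty thin sectors.

## Scoring

Per tile: positive ratio = positive cells / all cells; circumferential
ratio = complete cells / positive cells (0 when none are positive). The
circumferential denominator is the positive-cell count because the
reference intervals place the circumferential ratio *above* the positive
ratio for 2+/3+ — impossible if both shared the all-cells denominator —
and because "fraction of stained cells whose ring closes" is the quantity
the 3+ criterion describes. Aggregation to slide level: intensity is an
unweighted tile mean (defined even for cell-free tiles); each ratio is
weighted by its own denominator, so the aggregate equals the pooled count
quotient.

The threshold table defaults to the per-class min/max intervals of a
single-center calibration; decision boundaries are midpoints between
adjacent class intervals (staining 0.007/0.1675/0.454, positive ratio
0.0225/0.1275/0.2455, circumferential 0.0055/0.407/0.601), boundary values
assign upward (clinical convention favors flagging). The integrated call
is the median of the three ordinal votes: symmetric, monotone in every
feature, and equal to the staining-only call when all indexes agree. An
alternative would be staining-primary with ratio veto; the median was
chosen for monotonicity and because it degrades gracefully when exactly
one index is uninformative. 2+ is always reported as equivocal with an
ISH-reflex flag, never auto-resolved.

The clinical rule engine applies the guideline rows with a strict `>` at
the 10 % boundary: exactly 10 % complete intense staining is *not* 3+ and
falls to the equivocal clause. Its two fraction arguments encode
complete-intense and faint-incomplete staining; the guideline's
"weak-to-moderate in > 10 %" equivocal clause would need a third fraction
and is outside this function's inputs.

## Evaluation

Accuracy, precision, recall and F1 are computed from confusion counts with
NaN (plus a warning) on zero denominators — silent zeros corrupt averages.
ROC sweeps thresholds with tied scores grouped and integrates by
trapezoid; average precision is step-interpolated (not 11-point). Both are
verified against closed forms (AUC = Mann–Whitney U / (n₁·n₀); AP by an
explicit all-thresholds sweep).

## Problem sizes and numerical choices

Test and acceptance workloads use 256 px patches with 50 cells, slides of
two 512 px tiles (~70–110 cells per slide), 10 slides per class for the
end-to-end check, and 100–1000 instances for property checks — sizes at
which every claim is exact or tightly bounded while the full suite runs in
minutes. Determinism: every stochastic step flows from a single integer
seed through `numpy.random.default_rng`; rerunning any generator or the
full pipeline with the same seed is bit-identical (reports differ only in
the provenance timestamp). Degenerate inputs are defined, not special-
cased ad hoc: empty DAB gate → intensity 0; no cells → zero ratios flagged
low-confidence; no positive cells → circumferential 0; all-white slide →
"indeterminate" report; single-valued histogram → explicit degenerate-
histogram error.

## Known limitations

- The default threshold table is a single-center calibration; it is a
  config key, not a universal constant.
- The heuristic classifier keys on color statistics and will mark any
  cell-dense region as tumor; it is a pre-filter stand-in, not a tumor
  model. The MLP backend is only as good as its training fixture.
- Circumferential measurement assumes roughly convex, isolated cells;
  heavily overlapping membranes in crowded tissue would blur arc
  attribution.
- 2+ (a)-type "weak to moderate, uneven" patterns are not modelled by the
  generator and not separable by the rule engine's two fractions.
- Vendor WSI formats are not parsed; slides enter as multi-page TIFF or
  flat images.
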