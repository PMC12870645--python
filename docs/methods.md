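# Methods

## Pixel preprocessing

Four rules run in a fixed order per batch of ROIs: summed-hot-pixel removal,
multi-channel artifact removal, global median subtraction, percentile
normalization. Choices the underlying procedure leaves open, fixed here:

- **Percentile definition**: linear interpolation between order statistics
  (`numpy.percentile` default). Fixed and documented so golden files are
  stable.
- **Exceedance is strict** (`>`): "above the percentile" is read as strictly
  above, so a constant image never loses pixels.
- **Negatives after median subtraction clip to 0**: downstream normalization
  assumes non-negative intensities.
- **Hot-pixel percentiles are within-ROI for both rules 1 and 2**; the
  cross-image pooling happens only in the median-subtraction step. The
  "specified protein channels" of rule 2 default to *all* channels and are
  configurable (`artifact_channel_set`), since no canonical list exists.
- A channel whose 99th percentile is 0 maps to all zeros rather than
  dividing by zero.

Consequences worth knowing: rule 1 zeroes at most ~0.01 % of pixels per ROI,
so a planted artifact count is recovered exactly only when the number of
planted pixels is below that budget and the background is effectively
discrete (ties at the threshold are kept). With continuous noise the rule
also trims the natural intensity tail — that is its intended behavior, not a
defect.

## Quantification

Mean (not median or sum) intensity per label, per channel; centroid is the
unweighted mean of member pixel coordinates in μm (x = column, y = row;
identical to pixel indices at 1 μm/px). Intensity-weighted centroids were
rejected as an unstated extra assumption. The conservation identity
Σ_cells mean × area = channel total over labeled pixels is asserted in
tests.

## Spatial graphs and niches

- **Radius**: 20 μm default (20 px at acquisition resolution). Boundary
  inclusive (distance ≤ r). A k-d tree accelerates queries but the edge set
  must equal the O(n²) brute-force set exactly, which tests enforce.
- **No edge correction** at ROI borders: border cells simply have fewer
  neighbors.
- **A cell is not its own neighbor** in composition vectors.
- **K-means input is the raw count matrix** (no scaling or
  fraction-normalization); a fractions option exists but is off by default.
  k-means++ with 10 restarts, Lloyd iterations to 1e-4 relative tolerance,
  seeded and logged. Niche labels are 1-based. The reference k for real
  tissue panels is 50; the synthetic cohort analyses use k = 12, which
  comfortably exceeds the ~7 planted neighborhood archetypes while keeping
  the WCSS curve and role mapping interpretable at this problem size.
- **Role mapping**: a fitted niche is a "GC niche" when > 50 % of its member
  cells carry a germinal-center cell label, "MZ" when mantle labels
  dominate. This bridges data-driven niche ids to the fixed niche sets the
  follicle stage expects.

## Interaction and group statistics

The interaction score for an ordered pair (a, b) in an ROI is the mean
number of b-cells within the radius per a-cell; pairs with no a-cells are
missing, not zero. The analysis unit for all group tests is the lymph node
(per-ROI values averaged per LN — each point in the published-style
comparisons is one LN); per-ROI testing is available. The test is a
two-sided Wilcoxon rank-sum (exact when both groups are ≤ 20 tie-free units,
normal approximation with tie correction otherwise) with Benjamini–Hochberg
FDR within each metric family. With 6 vs 6 units the smallest attainable
two-sided p is 2/924 ≈ 0.0022 and the attainable size at α = 0.05 is
0.041 — the null calibration check accounts for this discreteness.

`differential_composition` is a deliberately simple nonparametric stand-in
for model-based compositional regression: no patient-level random effect, no
count model; outputs carry `method = wilcoxon-standin`. With one LN per
patient (as in the synthetic cohorts) the distinction is immaterial; with
repeated LNs per patient the p-values ignore within-patient correlation and
should be read accordingly.

## Follicle detection and decortication

"Densely interconnected" has no published density criterion, so it is
operationalized as connected components of the within-20-μm graph restricted
to the target niche set, keeping components with ≥ `min_region_cells` = 20
members (invented, config-exposed). GC regions use the GC niche set; whole
follicles the GC ∪ MZ superset, which guarantees the nesting property (each
GC inside exactly one follicle).

The perigerminal decortication score counts, among non-GC cells within 20 μm
of any GC member, the fraction carrying an MZ niche. GC members are excluded
from the denominator — including them would deflate every score identically.
An empty neighborhood scores 0 with a flag. Classification: dormant if the
follicle has no GC-niche members; decorticated if the perigerminal MZ
fraction is below `decortication_threshold` = 0.25 (invented — the reference
taxonomy is qualitative); active otherwise. Downstream counts report
sensitivity to this threshold (see
`results/decortication_threshold_sensitivity.csv`). The perifollicular band
is all non-member cells within 100 μm of any follicle member; cells of other
follicles are excluded only if they belong to the focal region set.

## Synthetic tissue generator

Each compartment is a homogeneous Poisson point process on its support:
GC-B cells in discs (radius 120 μm), mantle-B in annuli (width 40 μm),
FRC-boundary in a thin outer ring (10 μm), and paracortex T / myeloid /
Treg-like cells over the ROI excluding GC cores (T cells do percolate into
follicle rims). Defaults: 1000×1000 μm ROI, 3 follicles, densities of
6000 / 8000 / 2000 / 2500 / 400 / 150 / 300 cells/mm² for
GC-B / mantle-B / FRC / T / suppressive / mregDC-like / Treg-like — chosen
to give a few thousand cells per ROI with B-follicle densities well above
the paracortex, the ordering seen in cortical lymph-node tissue.

Planted effects: **decortication** removes an angular sector of the mantle
annulus of fraction equal to `decortication_level` (partial levels stay
geometrically meaningful); **infiltration** routes `infiltration_rate` of
the suppressive-myeloid cells uniformly into follicle interiors. The
two-arm cohort preset plants decortication 0.8 and infiltration 0.35 in six
"higher-stage N1" nodes against six intact controls. All randomness flows
from the passed seed; same seed, byte-identical tables.

What the generator does **not** emulate: marker co-expression and spillover
between adjacent cells, clustered (non-Poisson) cell placement, irregular
follicle shapes, light/dark-zone GC polarity, cell-shape realism, and
patient-level correlation between LNs. Passing tests therefore demonstrate
correctness of the computational pipeline under idealized geometry, not
performance on real tissue; in particular, suppressive infiltration is
scattered rather than aggregated, so it surfaces in within-follicle cluster
enrichment rather than as a dedicated suppressive niche.

Image rendering draws each cell as a ~4 μm disc (nearest-centroid ownership
where discs overlap) with per-label channel means plus Gaussian noise
floored at 0, and can plant hot pixels at recorded locations for testing the
pixel stage.

## Problem sizes

The shipped analyses and checks use 12-LN cohorts of one 1 mm² ROI each
(~50k cells), niches at k = 12, 1000-rep null calibration, 100-rep power
simulation, and 20 cohort replicates for the end-to-end check — sizes chosen
so the whole suite re-runs in a couple of minutes on one CPU while leaving
the per-LN test at its natural 6-vs-6 granularity.

## Known limitations

- The Wilcoxon path ignores patient clustering (see above).
- Region detection by connected components can merge follicles closer than
  the connect radius; the generator enforces a separation buffer, real
  tissue does not.
- The decortication threshold and minimum region size are conventions, not
  estimates; conclusions about *counts* of decorticated follicles should
  always be read against the sensitivity table.
- Mean-intensity quantification inherits the well-known spillover of signal
  between tightly packed neighbors; no compensation is applied.
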