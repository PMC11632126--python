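# Methods

## The scoring model

A scorecard is an ordered list of metrics, each a pair (metric spec, score
function). The score function is piecewise linear in the metric value:
knots `(v_1, p_1), …, (v_k, p_k)` with strictly increasing values; between
knots points interpolate linearly, outside the knot range they clamp to the
terminal knot (so a value past the failing end stays at 0 — a protocol
violation, not an extrapolated negative). Points are real-valued (cards use
half and quarter points); all internal comparisons use an absolute
tolerance of 1e-9 and rounding to two decimals happens only at the report
layer.

Metric values come from the cumulative DVH. Conventions, chosen once and
applied everywhere:

- grids are `(z, y, x)`, 0-based, spacing in mm, volumes in cc;
- cumulative curves are built from a differential histogram on edges
  `0, h, 2h, …` (default `h = 0.05` Gy) extending one bin past the maximum
  structure dose; the value at an edge is exactly the occupancy-weighted
  volume with dose ≥ that edge;
- both inversion directions interpolate linearly between edges;
- `D_x` uses the plateau convention: the largest dose whose cumulative
  volume still meets the request (so on a step curve the 50% request
  returns the hotter plateau edge);
- `D100%` is the minimum dose; `MaxDose` is the voxel maximum when a dose
  grid is available (curves imported from DVH tables fall back to
  curve-derived summary statistics, accurate to a bin);
- `D0.03cc` on a structure smaller than 0.03 cc degrades to the maximum
  dose with a warning rather than erroring, for batch robustness;
- occupancy weights are binary (voxel center in/out) in everything shipped;
  fractional weights are accepted throughout;
- the conformation number is the van't Riet composite
  `CN = (TV_D/TV)·(TV_D/V_D)` evaluated voxel-exactly against the `BODY`
  structure, returning 0 when nothing reaches the dose level. No published
  definition accompanies the metric text, so the van't Riet form — the
  standard composite penalizing both under-coverage and spill — is a
  documented choice.

Binned metrics converge to voxel-exact values as the bin width shrinks;
the tests bound the error by one bin width at 0.1 / 0.05 / 0.01 Gy.

## Built-in cards and reconstructed knots

The three cards ship with their published structure lists, metric texts,
ordering and maximum point values (totals 158.5 / 158.5 / 142 over
29 / 29 / 25 metrics). The published per-metric knot coordinates are not
public, so every function here is a reconstructed three-knot
fail / variation / aspirational shape:

- zero-point knots sit at published protocol-violation thresholds where
  one exists — hippocampus Dmin 7.6 Gy (limited-sparing 20 Gy card) or
  9 Gy (30 Gy cards), hippocampus D0.03cc 13 Gy resp. 16 Gy;
- the variation knot awards 72% of the metric's points;
- the aspirational knot (max points) sits at a value a very good plan of
  that card's intent approaches but rarely reaches.

Dose-valued knots are placed as fractions of the card prescription, so
rescaling a card to another prescription is exact (knots, absolute volume
levels, conformation isodose levels and the HI denominator all scale by the
Rx ratio; percent-of-Rx levels and dimensionless knots are untouched). The
20 Gy limited-sparing card is marked non-scalable: it derives from an
institution-specific protocol whose hippocampal constraints do not scale to
30 Gy. Card files (JSON, or a one-metric-per-row CSV) override everything,
including the derived-structure recipes; the shipped defaults are data, not
behavior. Two interpretations the metric texts leave open are resolved as
defaults and kept overridable: `_BrainStem#Hi` is taken as brainstem ∩ PTV
(scored for coverage via D95%), and `_Brain&BODY Volume at 99.5% [CC]`
rewards larger covered volume.

## Normalize to max score

Under a global dose rescaling by `r`, dose-valued metrics scale as
`r·value` (including `MaxDose [%]` and HI, whose denominator is fixed); a
volume metric at absolute level `d` becomes `V(d/r)` on the unscaled curve
(percent-of-Rx levels resolve against the unchanged prescription first);
the conformation number at level `L` is re-evaluated at `L/r`. The total
`S(r)` is piecewise smooth with breakpoints where `r·value` crosses a knot,
where `d/r` crosses a DVH edge, and where an interpolated volume crosses a
knot; between breakpoints it has the form `A + B·r + C/r`, which can peak
in the interior of a bracket. The search therefore enumerates all
breakpoint radii inside the window (default [0.90, 1.10], which must
contain 1), adds a coarse uniform sweep as a safety net, and polishes every
bracket with a bounded scalar optimization. Ties within 1e-9 points resolve
toward the factor closest to 1, then the smaller factor; the reported
score can consequently sit up to that tolerance below the numerical peak.
Degenerate metrics (value 0) contribute no candidates and are skipped with
a log message.

During the search the conformation number is evaluated from the two
interpolated cumulative curves rather than voxel counts: the voxel-exact CN
is a step function of `r` whose ~10⁵ discontinuities would have to be
enumerated for an exact search. Scoring with `normalization="off"` always
uses the voxel-exact CN; with `normalization="max_score"` both the baseline
and the renormalized totals use the curve-based CN so the guarantee
`S(r*) ≥ S(1)` holds on the objective actually optimized. The difference is
bounded by the CN metric's 1 point and is far smaller in practice.

The window and tie-break are this package's documented choices; the
vendor tool publishes neither. As the published rationale notes, it is the
steep coverage functions that actually confine the factor, not the window.

## Synthetic phantom

The phantom emulates a cranial HA-WBRT case at desk scale (64³ voxels,
2 mm, < 1 s per plan): ellipsoidal BODY and brain, bilateral hippocampi as
curved 4.5 mm-radius tubes in the medial temporal region, anterior-inferior
eyes/lenses/lacrimal glands, optic nerves converging on the chiasm,
brainstem and inferior spinal cord; the avoidance region is the hippocampi
expanded 5 mm (exact Euclidean distance transform) and the PTV is brain
minus avoidance.

The dose model is
`dose = s · Rx · B · (1 − dip_depth · H) · (1 + hotspot bump) · (1 + noise)`:

- `B` — the brain indicator blurred with `falloff_mm`, renormalized so the
  plateau reaches the brain surface and clipped at 1; the Gaussian shoulder
  (conformity) lies outside the target.
- `H` — the sparing dip `exp(−(D/σ)^p)` with `D` the Euclidean distance to
  the hippocampal center line, recovered from the mask as (max depth −
  depth) inside and (max depth + surface distance) outside. `p`
  (`dip_exponent`) sets the gradient steepness: a supergaussian (p = 4)
  confines the gradient to the 5 mm margin (high coverage, higher
  hippocampal near-max dose); a Gaussian (p = 2) skirt bleeds into the PTV,
  trading coverage for whole-structure sparing. This makes a deep-sparing
  plan's coverage deficit *geometric* — like the penumbra around a real
  avoidance volume — so a small global upscale cannot buy the coverage
  back, which matters when plans are renormalized to max score.
- `s` — fixes the `(1 − coverage)` quantile of the noisy dose over the PTV
  to exactly Rx, so PTV V100% equals `coverage` by construction.
- the hotspot is a broad (22 mm) Gaussian bump at the PTV centroid peaking
  at `hotspot_pct` of Rx; `noise_sd` is multiplicative Gaussian noise; all
  randomness flows from one generator seeded by `cfg.seed`.

Three preset configurations (`STUDY_PLAN_CONFIGS`) encode the intent
archetypes. Their coverage values and hippocampal dose fractions are
calibrated to the published validation-plan averages for the corresponding
models — deep sparing: V100 ≈ 95.1%, hippocampus Dmin/D0.03cc ≈ 0.19/0.34
of Rx; moderate: 98.5%, 0.24/0.48; limited: 99.0%, 0.24/0.56 — with the dip
width fitted at the default grid resolution (the discrete center-line
distance inside a 4.5 mm tube on a 2 mm grid tops out at ≈ 2.5 mm, so the
widths are resolution-specific constants, not transferable physics).

What the phantom does *not* model: beam geometry, MLC effects, CT
heterogeneity, anatomical variability between patients, and realistic
inter-structure dose correlations. Passing tests therefore demonstrate the
correctness of the metric/scoring machinery and the qualitative
intent-separation property, not agreement with any real plan's numbers —
the published per-patient dosimetric values are not reproducible without
the original DICOM plans and the unpublished knot tables.

## Numerical and I/O choices

- Dose grids store Gy as float64 internally, float32 in NRRD bundles;
  masks as 8-bit. SimpleITK handles NRRD (note its (x, y, z) axis order is
  reversed relative to the internal arrays).
- Report CSVs round points/percents/doses to two decimals at serialization
  only; an optional per-metric detail file carries one row per
  plan × card × metric. A `--no-timestamp` flag makes reports
  byte-reproducible.
- The DICOM-RT adapter rasterizes RTSTRUCT contours per axial slice onto
  voxel centers (XOR for nested contours, zero-padding so structures
  clipped by the grid edge still trace closed loops); round trips are exact
  only to rasterization tolerance, and the NRRD bundle is the lossless
  path.
- Scorecard structure names bind to plans by exact name, then an explicit
  alias map, then a `PTV_*` → `PTV_WB` fallback (protocol cards encode the
  prescription in the target name; plans name their target once).
- Lenient scoring awards 0 points with a flag for unresolvable metrics
  (missing structure, or a conformation number requested on a DVH-only
  plan); strict mode raises.

## Known limitations

- Reconstructed knots reproduce each card's direction and weighting, not
  the published per-metric point values; only card totals and published
  fail thresholds are verifiable.
- The intent-ordering experiment is an ordering claim per plan (each
  archetype peaks on its own card); with reconstructed knots the pairwise
  margins are a few points and column-wise orderings across plans are not
  asserted.
- Margin expansion is isotropic and voxel-center based; no sub-voxel
  surface geometry.
- DVH-only plans lose voxel-exact summary statistics (mean/max/min are
  then bin-resolution) and the conformation number.
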