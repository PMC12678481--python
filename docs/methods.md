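# Model and methods

`histodyn` packages two things: (i) an agent-based kinetic model of histone
H3/H3.3 nuclear availability and chromatin incorporation on the cortex of a
syncytial *Drosophila* embryo during the pre-ZGA nuclear cycles (NC10–13,
plus NC14 in haploid and density-gradient scenarios), and (ii) the
quantification pipeline that live-imaging studies of this system use:
per-cycle mitotic chromatin totals, pre-NEB nuclear concentrations, aligned
nuclear-import curves, fixed-radius neighborhood analysis, photoconversion
assays, and a two-way ANOVA reporting layer. The simulator generates the
per-nucleus, per-frame tracking tables that in the laboratory come from
confocal movies via segmentation and tracking, so every pipeline stage can
be tested offline against exact ground truth.

## The kinetic model

Each nucleus on the cortical sheet carries, for each tagged species
(channel), a free nuclear amount F and a chromatin-bound amount B, in
arbitrary intensity units (a.u.). The embryo holds one shared cytoplasmic
pool P per species. Over a cycle:

- **Growth.** A nucleus reforms at volume `v_min` (65 µm³) and relaxes
  toward its per-cycle maximum `v_max(NC)` (525 → 190 µm³ from NC10 to
  NC13) as `V(t) = v_min + (v_max − v_min)(1 − e^{−r t/T_i})` with ramp
  rate r = 6; `v_max` falls as nuclei double, matching the observed shrink
  of maximum nuclear volume.
- **Import.** During interphase,
  `dF/dt = k_import · (P/V_embryo) · V^{2/3} / (1 + β·ploidy·n)`,
  i.e. surface-area-scaled uptake from the shared pool, reduced by local
  crowding through the number of neighbors n within 20 µm at the nucleus's
  cycle start. β is species-specific: H3 import is strongly density-
  sensitive (β = 0.35 with high flux), H3.3 less so — the model's
  expression of the observation that variant import is less N/C-sensitive.
  β is multiplied by ploidy because each neighboring genome's demand, not
  the nucleus count per se, does the competing; haploids compete half as
  hard.
- **Incorporation.** Two pathways. *Replication-coupled* (H3, and the
  H3-protein chimera expressed from the variant locus, "ASVM"):
  `dB/dt = k_inc · F · u(t) · ploidy`, where `u(t) = max(0, 1 − t/T_S)` is
  the unreplicated genome fraction — deposition happens only while new DNA
  is being made. *Replication-independent* (H3.3):
  `dB/dt = k_inc · γ_NC · (n/n̄_NC)^q · F · ploidy`, active throughout
  interphase. γ_NC is the per-cycle cell-cycle-state gate; the factor
  `(n/n̄_NC)^q` (q = 1.5, n̄ the cohort mean neighbor count) modulates it
  by *local* density, so within one embryo crowded nuclei deposit
  relatively more variant histone. Scenario perturbations scale or abolish
  γ (checkpoint mutant: ×0.5 from NC12; chaperone mutant: ×0).
- **NEB and division.** At nuclear envelope breakdown the free pool
  returns to the cytoplasm; chromatin-bound histone stays on the mitotic
  chromatin and splits equally between the two daughters. Metaphase is the
  midpoint of the mitosis interval.
- **Synthesis.** Maternal translation replenishes the H3 pool at a
  constant 30 a.u./s (its mRNAs are stabilized maternally; the
  `slbp` scenario scales this away together with the starting pool).
  H3.3 synthesis is negligible on this timescale and defaults to 0.

Integration is explicit per-step (dt = 5 s) with an exact exponential
update for the linear incorporation step and a proportional clamp when a
step's total import demand would overdraw the pool (logged as a warning).
Mass is conserved identically: cytoplasm + Σfree + Σbound = initial pool +
∫synthesis, to floating-point precision at every frame, for every scenario
— the ground-truth object records these ledgers and the test suite checks
the residual against a 10⁻³ bound.

**Measurement model.** Recorded totals are
`true · Lognormal(cv) · bleach^frame + background` per channel and frame
(defaults cv = 0.05, background = 20 a.u., bleach 1.0); measured volumes
carry a smaller lognormal error (cv 0.03). Mean intensity is total /
measured volume. Frames are written every 45 s; converted nuclei can be
followed at 15 s by setting `frame_interval`.

**Photoconversion.** An event converts the entire green content (free and
bound) of one nucleus to red instantaneously (efficiency parameter,
default 1). Red obeys the same incorporation kinetics, receives no import
(the cytoplasm holds no red) and is never exported, so total nuclear red
is non-decreasing until NEB; at NEB free red disperses into a cytoplasmic
sink that does not re-import (its dilution into the embryo-scale pool
makes re-import negligible) while bound red stays on chromatin. The
convenience routine `photoconvert_mid_cycle` targets an interior nucleus
whose neighbor count is most typical of its cohort (median, ties broken
toward the embryo centre) — a "representative nucleus" choice that keeps
the single-nucleus assay from being dominated by one nucleus's local
crowding.

**Geometry.** Nuclei live on a 2-D sheet (500 × 180 µm default) at height
5 µm with 0.3 µm jitter; initial positions are relaxed by soft repulsion,
daughters are placed ± one nuclear radius along a random in-sheet axis and
relaxed to non-touching spacing. A fraction (10%) of boundary-band nuclei
sit 3 µm below the sheet, emulating the incomplete edge nuclei that real
movies contain; the Z-coordinate filter (threshold 2 µm below the cohort
median plane, exposed as a parameter since the source analysis does not
state its cutoff) removes exactly these from curve averaging while keeping
them in neighbor counts. The density-gradient (`shkl`) scenario samples
initial positions from a centre-peaked triangular density (slope 1.6),
adds a mitotic wave (90 s across the embryo) and lets the sparsest quartile
of NC13 nuclei — posterior-weighted on ties — perform a partial extra NC14
division.

## Calibration

The model intentionally has few mechanisms; its constants were calibrated
once so that the full pipeline, run end-to-end on simulated embryos,
reproduces the study system's headline numbers (all as multi-seed means):
H3 pre-NEB concentration falls ~40% and H3.3 ~20% from NC10 to NC13;
photoconverted free fractions fall ~70% → ~30% (H3.3) and ~55% → ~20% (H3)
between NC11 and NC13; in the haploid chaperone-mutant scenario the ASVM
chimera's chromatin signal falls only ~20% from NC10 to NC14 versus ~40%
for H3 while H3.3 deposition is abolished; 60% of histone-depleted
(`slbp`) embryos arrest in NC13. Three structural features were forced by
this calibration and are worth knowing about:

1. **Near-exhaustion of the H3 pool during NC13** is what makes the H3
   import curve plateau a few minutes into NC13; the shallow late slope is
   the synthesis-fed steady state. Because everything the embryo owns ends
   up inside nuclei once the pool empties, the NC13 concentration is
   budget-limited, which couples `k_import`, the synthesis rate and the
   NC13 maximum volume.
2. **Per-species crowding sensitivity** (β) separates the fast H3
   concentration fall from the gentler H3.3 fall while letting H3.3's
   chromatin totals *rise* with local density in the gradient scenario.
3. **The per-NC gate profile** γ = {0.08, 0.25, 0.48, 0.33} for NC10–13
   reflects the estimated division of labour between cycle identity and
   local density: most of the developmental rise of H3.3 deposition is
   carried by the density response, with γ trimming each cycle to the
   measured free fractions. How much of the gate is checkpoint-dependent
   versus density-dependent is genuinely open; the `chk1` scenario's
   gate scale (0.5) is a free knob and labelled as such.

## The quantification pipeline

- **Mitotic chromatin totals**: per nucleus, the total intensity at its
  designated metaphase frame (median mitosis frame); per cycle the mean;
  all normalized to the reference-cycle mean (NC10; NC11 for gradient
  embryos). Cycles with no mitotic nuclei (arrest) are omitted with a log
  note.
- **Interphase concentration**: mean nuclear intensity one lookback
  (45 s) before NEB, where NEB is the end of the nucleus's last interphase
  frame; same normalization. Whether the source analysis background-
  subtracted these means is unstated; the default here is the raw mean
  with background subtraction available as a flag.
- **Import curves**: per nucleus, total intensity from T0 (minimum-volume
  frame, searched in the first 40% of interphase to dodge late-volume
  artifacts, earliest frame on ties) to NEB; normalized either to the
  within-cycle mean of per-nucleus maxima (= 1 by construction) or to the
  reference cycle's. Initial import rate: OLS slope of the first five
  timepoints.
- **Neighborhood analysis**: 3-D Euclidean counts within 20 µm (inclusive
  boundary) at minimum volume; edge nuclei filtered by Z *after*
  contributing to counts; per-count bins (optional coarsening), weighted
  by member count; per-bin mean curves re-normalized so the grand mean of
  per-nucleus maxima is 1.
- **Photoconversion assays**: export rate = OLS slope of interphase red
  vs time as a fraction of the initial red per minute (negligible below
  1%/min); free fraction = 1 − (red on chromatin at the first post-NEB
  frame)/(red total at the last pre-NEB frame), clipped to [0, 1] with a
  log note. The chromatin-retained ratio is this package's
  operationalization — bound red stays on mitotic chromatin while free
  red disperses — and the estimator is exactly unbiased on noise-free
  simulations. Which post-NEB frame to use is parameterized (default:
  first).
- **Cycle durations**: metaphase-to-metaphase, with all same-batch
  durations scaled so the control NC11 mean equals 10 min.
- **Statistics**: two-way ANOVA (genotype × cycle) with Type-II sums of
  squares, chosen because per-genotype embryo counts are unbalanced in
  practice (the decomposition question is moot on balanced designs, where
  Types I/II/III coincide — tested). Replicates are per-embryo means by
  default, per-nucleus in gradient mode.

## The imaging stage

`render_image_stack` draws each nucleus as a 3-D Gaussian whose integral
equals its measured total (σ = 0.35–0.5 of the nuclear radius), summing
overlaps, onto a voxel grid (defaults mirror 0.149 µm pixels / 1 µm
Z-steps). `segment_frame` thresholds (Otsu or fixed), labels 26-connected
components, discards cores under `min_size`, then expands each core onto
surrounding voxels still above 2% of the threshold so object totals track
the full Gaussian mass; all statistics are computed on that support, so
total = mean × size holds exactly. `track_objects` links frames by greedy
mutual-nearest-neighbor within `max_disp`, treating two claimants on one
predecessor as a division (parent ends; both daughters get fresh ids with
`parent_id` set). Ties resolve by distance then label order, so tracking
is deterministic. This stage is deliberately minimal — no learning-based
pixel classification, no watershed declumping — and is not a general
tracker; it is adequate for the sparse, slow synthetic stacks it is tested
on. A reader for ilastik-style tracking CSV exports maps their columns
onto the TrackTable schema through an overridable column map (export
column names vary by version).

## What the synthetic data does and does not capture

The generator reproduces the statistical structure the pipeline assumes:
doubling nucleus counts, volume growth to a falling per-cycle maximum,
shared depleting pools with local competition, two incorporation pathways,
edge nuclei, asynchrony and partial extra divisions in gradient embryos,
arrest, photoconversion, multiplicative intensity noise, bleaching and
background. It does not model chromatin structure (no loci or
nucleosomes), transcription, spindle mechanics or chromosome bridging
(the `slbp` scenario represents bridging only as embryo-level arrest),
imaging point-spread asymmetries, or segmentation failure modes of real
movies (touching nuclei, debris). Passing tests therefore certify the
*analysis code* against a model with known truth, not the biology of any
particular embryo; on real data the pipeline's accuracy is bounded by
segmentation quality, which this package deliberately keeps simple.

## Numerical choices and degenerate inputs

- dt = 5 s; frame interval must be an integer multiple of dt; event times
  round to the step grid.
- Pool overdraw clamps import proportionally (warning), keeping pools
  non-negative and mass exact.
- Ties: minimum-volume T0 and tracking assignments break ties toward the
  earliest frame / smallest label; the NC14-dividing subset in gradient
  embryos is a rank cut (neighbor count, then posterior position), not a
  quantile threshold, to avoid tie inflation on integer counts.
- Nuclei with fewer than two interphase frames are excluded from
  concentration and curve analyses with a warning; conversion of a
  non-existent nucleus or outside interphase raises.
- Free fractions outside [0, 1] (noise) are clipped with a log note.
- Determinism: all randomness flows from `SimConfig.seed` through three
  split generators (geometry, biology, measurement noise); identical
  configs give bit-identical tables, and report bundles are byte-stable.

## Problem sizes

Defaults simulate 64 → 512 nuclei (NC10 → NC13) at 45 s cadence
(~22 000 table rows, well under a second per embryo); the calibration
checks average 10 embryos per condition and 50 for the arrest fraction.
The rendering fixtures use 6 → 12 nuclei over two cycles on half-micron
voxels. These sizes were chosen to keep every analysis statistically
stable while the whole suite stays desk-scale.

## Known limitations

- The kinetic constants are a calibrated minimal model: they reproduce
  the headline percentages and trend directions, not absolute intensities
  or per-embryo variance structure.
- The γ/density split of the H3.3 gate is underdetermined by the
  calibration targets (see above); alternative splits reproduce the same
  control numbers with different gradient-scenario strength.
- The per-nucleus free-fraction estimate inherits two-frame measurement
  noise (±5 pp single-embryo scatter at cv = 0.05); averages over ≥ 6
  embryos are required for the headline comparisons.
- The tracker has no gap closing or merge resolution: a pair of touching
  nuclei segments as one object and re-splits later, which the division
  rule then mislabels. Keep rendered densities below ~1 nucleus/(8 µm)².
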