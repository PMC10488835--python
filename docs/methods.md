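# Methods

## The measurement model

An electroanatomical map is a triangulated endocardial surface with a
local activation time (ms) and a unipolar voltage amplitude (mV) at each
vertex. Local conduction velocity is estimated over circular patches of
the surface rather than from point-pair gradients, which averages over
wavefront-direction variability: for a patch of clipped area *A* and
activation spread Δt = t_last − t_first,

    CV = 2 · sqrt(A / π) / Δt        (mm/ms ≡ m/s)

The diameter is recovered from the *actual* clipped area, not the nominal
π r², so partially covered circles at cutout borders or map edges are
handled consistently. For a planar wavefront crossing a flat circular
patch the first and last activations sit at opposite ends of the diameter
along the propagation direction, making the estimator exact in the
continuum limit; the test suite verifies < 2% error for speeds in
0.3–1.5 m/s on sheets with 0.5 mm edges.

Assumptions worth stating explicitly:

* A single wavefront crosses each circle. Colliding fronts compress Δt
  and inflate the estimate — two exactly opposing fronts meeting
  mid-circle inflate it ~2× (the arrival profile becomes V-shaped, with
  the spread r/v instead of 2r/v). The strict **> 6 m/s exclusion rule**
  screens the physiologically implausible tail this produces; values at
  exactly 6 m/s are kept.
* Activation annotation noise is small relative to Δt (≈ 10–30 ms for a
  5 mm radius at physiological speeds).
* Voltage per circle is the area-weighted mean of the linearly
  interpolated field over the clipped patch (a vertex-mean option
  exists); on a centred linear gradient the area-weighted mean equals
  the centre value, which the tests check.

## Circle construction

Patches are Euclidean-ball clips, not geodesic disks: the distance-to-
centre field is linearly interpolated over each triangle and iso-clipped
at the radius, splitting crossing edges at the interpolated point and
interpolating all scalar fields at the split points. On low-curvature
chamber walls the difference from a geodesic disk is second order; a
5 mm clip of a fine flat sheet reproduces π·25 = 78.54 mm² to < 1%
(observed convergence is roughly quadratic in edge length: 0.17% error
at 0.5 mm edges, 0.04% at 0.25 mm).

Circle centres are placed by greedy farthest-point sampling over
non-cutout vertices with a single `spacing` parameter (default 5 mm,
equal to the radius): centres are pairwise ≥ spacing apart and every
analysable vertex lies within spacing of a centre. The seed picks the
start vertex and breaks exact distance ties via a random priority
permutation; runs are bitwise reproducible. Placement density at the
defaults yields circle counts per map comparable to the reference
study's per-map overview (~100–190 per chamber). A triangle touching
any cutout vertex is excluded entirely (conservative exclusion near
transitions), and a circle centred on a cutout vertex is rejected.

Degenerate cases: an empty intersection returns an empty-patch marker;
Δt = 0 (constant activation) yields an undefined velocity and the circle
is excluded with reason `zero_dt` rather than propagating an infinity.

## Wall stratification

Wall labels are input annotations per vertex, not computed anatomy.
Chamber schemes: ventricles {septal, lateral, posterior, anterior};
right atrium {septal, lateral, posterior, superior}; left atrium adds
anterior to the atrial set. The default `strict` rule assigns a circle
to a wall only when every covered vertex carries that label — matching
per-region analyses in which circles lie entirely within one wall — so
per-wall circle sets are disjoint subsets of the whole-map set. A
`majority` (> 50%) rule is available for sparsely labelled maps.

## Statistics

Chamber/wall comparisons use a linear mixed model per response fitted by
REML (statsmodels `MixedLM`): fixed effects are mapping location and
heart rate (no interaction), with a random intercept per animal for the
repeated, unbalanced observations. Velocity is log-transformed (natural
log) and results are back-transformed, so velocity contrasts are ratios
and voltage contrasts stay mV differences; delta-method standard errors
accompany back-transformed estimates. Estimated marginal means are
evaluated at 90 bpm (the reference heart rate; extrapolation beyond the
observed range warns), averaging over any additional factors. All-pairs
contrasts are adjusted with the studentized-range (Tukey) criterion,
targeted subsets with Sidak's closed form `1 − (1 − p)^m`; adjusted
p-values never fall below raw ones.

Degrees of freedom: `MixedLM` provides no Satterthwaite approximation,
so the default is a containment/between-within partition — coefficients
of covariates constant within an animal (intercept, sex) are tested
against animal-level df, covariates varying within animals against
residual df — with a plain normal approximation available via
`df_method="normal"`. Calibration is checked empirically: over 500
simulated studies with the study-like design (4 animals, 21 maps) at a
reduced 30 circles per map, every fixed-effect 95% CI covers its planted
value in ≥ 93% of replications (observed 94–99%). The reduction from the
native ~131 circles per map keeps 500 REML fits affordable; at very
small per-map sizes (≈ 10 circles) coverage of sparsely-mapped chamber
contrasts dips a point or two below nominal, which is the small-sample
price of the df approximation, not a generator artefact.

Optimizer robustness: gradient-based REML fits can stall at a spurious
optimum when the random-intercept variance hits the zero boundary; when
a fit looks degenerate (non-finite estimates, boundary variance,
non-convergence) derivative-free refits (Powell, CG) are tried and the
best restricted likelihood wins. Boundary fits are flagged `singular`,
not fatal; rank-deficient fixed-effect designs raise an explicit error.

The sex effect is tested by adding sex to the fixed effects; being
constant within animal it receives animal-level df (with four animals,
df = 2 — honest but weak, as it should be). Correlations between CV and
VA use Pearson's r with df = n − 2, reported per scope (overall, per
chamber, optionally restricted to CV below a 1.5 m/s cap); |r| < 0.2 is
verbalised as "no linear correlation". Excluded circles (outlier or
zero-Δt) never enter models or correlations.

## Synthetic data: what it does and does not emulate

Activation fields are closed-form, not eikonal-solver output, keeping
ground truth exact: planar `t(x) = (x·n)/v`, focal
`t(x) = |x − origin|/v` (chord distance — exact on flat sheets,
approximate on curved geometry), and colliding = pointwise minimum of
two planar fields. Voltage is a per-wall mean plus iid Gaussian noise,
clipped at zero; there is no spatial autocorrelation within a wall
because no generative voltage-field model is reported for real maps.
Cutout disks and wall labels (polar cap for the atrial superior wall,
azimuthal sectors otherwise) are planted with the map.

Studies compose a hierarchy that matches the statistical model exactly:
per-map speed = chamber mean (m/s at 90 bpm) × exp(animal intercept) ×
exp(slope·(HR − 90)), and additively for voltage. Default chamber means
(LA 0.79, LV 0.59, RV 0.54, RA 0.50 m/s) and wall voltage means
(uniform within atria, regionally structured within ventricles) echo
the reference study's reported estimates; the default design table
(which animal mapped which chamber at which heart rate, 21 maps, 4
animals, 2 female) replays the packaged study overview. Defaults chosen
without a reported counterpart: animal intercept SDs 0.10 (log m/s) and
0.8 mV; heart-rate slopes −0.002 /bpm (log CV; mild rate-dependent
conduction slowing) and −0.01 mV/bpm; per-vertex voltage noise 1 mV.

Two fidelity gaps matter for interpretation. First, a planar 3-D wave
sweeps an inclined curved surface faster than its plane speed, so on
ellipsoid chambers the mesh pipeline recovers the planted *ordering* of
chamber speeds but runs ~15–20% above the planted absolute values;
value-level checks of the statistics therefore use the measurement-level
sampler (`sample_measurement_table`), which draws circle measurements
directly from the hierarchical model. Second, ellipsoids with planted
azimuthal wall sectors say nothing about real anatomical wall geometry;
passing wall-stratification tests demonstrates correct bookkeeping, not
anatomical validity.

Determinism: a fixed scenario seed reproduces maps bitwise (labels and
integers exactly; floats to machine precision). Truth tables serialise
every generative parameter per map and are round-trip tested.

## Problem sizes and tolerances

* Flat-sheet geometry checks: 14–36 mm sheets at 0.25–0.5 mm edges;
  patch area within 1% of π r²; CV recovery within 2%.
* Study-scale pipeline runs: 21 ellipsoid maps at icosphere subdivision
  4 (2 562 vertices each), ~2 200 circles, a few seconds end to end.
* Calibration: 500 REML refits at 30 circles/map (~630 rows each),
  under a minute.
* The packaged per-map overview table (21 maps) feeds the study-level
  summary path: 21 maps, mean 5 632 points and 131 circles per map.

## Known limitations

* Velocity is scalar; no direction-resolved (vector) CV, no bipolar
  voltage.
* Euclidean-ball patches under-represent geodesic disks on highly
  curved or folded regions (trabeculated surfaces, appendages).
* The between-within df rule is an approximation; with four animals,
  between-animal inferences (intercept, sex) are conservative and
  coverage of the intercept CI runs high (~99%).
* The generator's voltage field has no within-wall structure, so tests
  cannot detect methods that would conflate spatial voltage gradients
  with wall effects on real data.
* Mesh repair is out of scope: meshes failing validation are rejected,
  and non-watertight surfaces get a best-effort volume with a warning.
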