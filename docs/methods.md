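# Methods

## Stock accounting

A profile is an ordered stack of contiguous half-open depth increments
[top, bottom) in cm, each carrying bulk density ρ (g cm⁻³) and organic
carbon concentration c (g C kg⁻¹). Unit algebra: layer soil mass
M = ρ·d·100 Mg ha⁻¹ and fixed-depth stock S_FD = M·c/1000 Mg C ha⁻¹.

**Reference masses.** The ESM coordinate system of a treatment is the
vector of its layers' t0 soil masses averaged across replicate plots;
cumulative reference masses are their prefix sums. The same table is used
for both times and all replicates, so stocks are always compared over
identical soil mass. A user-supplied reference table can replace the
t0-derived one (e.g. to reuse published reference masses).

**Classical ESM** evaluates cumulative stock as a piecewise-linear function
of cumulative mass (slope c/1000 within each sampled layer) at the
cumulative reference masses. This is algebraically identical to the
top-down cascade: surplus sampled mass relative to the cumulative reference
is shed at the layer's own concentration, deficits are borrowed from the
next deeper layer at that layer's concentration.

**Spline ESM** (cumulative coordinates) fits a natural cubic spline —
second derivative zero at both ends — through the origin plus one knot per
sampled layer boundary, and evaluates it at the cumulative reference
masses. The natural boundary condition is our choice; only "cubic spline"
is canonical in this literature, and the cross-method guard below bounds
the consequence. Evaluation at a knot is exact, so a profile whose sampled
masses equal the references reproduces its FD stocks under all three
methods (tested to 1e-9 relative).

**Extrapolation.** If the deepest cumulative reference mass exceeds a
profile's sampled mass, the default is an error naming the shortfall — the
conservative stance that one should sample deeper than the target mass.
With `allow_extrapolation=True` the last spline segment (spline method) or
a line at the deepest layer's concentration (classical method) is extended,
and the rows are flagged. Note that extrapolation is routine in practice:
with references defined as treatment *means* of replicate masses, about
half the replicates necessarily fall a noise-margin short of the deepest
cumulative reference. The pipeline therefore enables extrapolation by
default, and the crediting/association drivers enable it internally because
their 60 cm / 30 cm horizons are unaffected by deep-layer shortfalls.

**Overshoot.** Cubic interpolation can produce small negative layer stocks
where concentrations are near zero and noisy. These are reported as-is with
a warning rather than clipped, because clipping would silently bias
cumulative sums.

**Harmonization.** When the two campaigns used different depth grids,
intensive fields (ρ, c) are remapped by overlap-weighted averaging onto the
target grid — the generalization of adjusting a coarse bulk-density grid by
weighted averages of the two adjacent increments. Stocks are never remapped
directly; they are recomputed from remapped intensive fields. Remapping is
linear in the field and conserves ∑ρ·d over a common span (tested to 1e-9).

## Change statistics

Changes (t1 − t0) in ρ, c, and stocks are summarized per treatment × layer
by a Welch (unequal-variance) two-sample t: mean difference, two-sided CI
at the requested level (default 95%), t, Welch–Satterthwaite df, p, percent
change 100·Δ/mean_t0, and Hedges' g — the standardized mean difference
J·Δ/s_pooled with pooled Bessel-corrected SD and small-sample factor
J = 1 − 3/(4(n0+n1−2)−1). Welch is the default because pooled-versus-Welch
is not canonically fixed for these comparisons; g deliberately uses the
pooled SD even alongside a Welch test, matching common effect-size
practice. The ESM-vs-FD contrast treats the two methods' per-plot stock
changes as two samples (unpaired Welch by default; a paired option exists
since the same plots underlie both vectors). No multiple-testing
adjustment is applied anywhere; rows are reported individually.
Degenerate inputs are explicit: zero variance in both groups with equal
means yields g = 0, p = 1 by convention; with unequal means it is an error,
not a silent infinity.

`required_sample_size(cv, rel_change, alpha, power)` returns the smallest
per-group n for a two-sided two-sample t to detect a mean shift of
`rel_change`×baseline against SD `cv`×baseline, scanning n upward on the
noncentral t distribution (effect size δ = rel_change/cv, noncentrality
δ·√(n/2)). It is validated against a 10⁵-replicate power simulation.

## Bulk-density attribution

Per plot, over the top 30 cm (the two surface layers summed; a per-layer
mode exists): the stock carried by soil mass gained or lost through BD
change, Σ(ρ_t1−ρ_t0)·d·100·c_t1/1000, is correlated (Pearson) against the
t1 FD−ESM stock gap. The gap is oriented FD−ESM so both variables share a
sign — negative under loosening, positive under compaction — making
one-directional scenarios give r near +1; a flag flips the orientation.
Zero variance in either variable raises an error rather than returning 0.

## Crediting

The creditable amount per hectare is a lower confidence limit, not a mean:

* *difference between means* (default): LCL = Δmean − t(0.75, df_Welch)·SE,
  i.e. the lower bound of the two-sided 50% Welch CI — equivalently a
  one-sided 75% bound. Under a no-change null this issues credits 25% of
  the time, the designed over-crediting rate (verified by simulation).
* *mean difference*: lower bound of the two-sided 90% one-sample CI on
  paired per-plot differences.

Conversion: 1 Mg C = 44/12 t CO₂e; credits for a field are
max(0, ⌊LCL_CO₂e × area⌋). Floor rounding is our choice as the conservative
reading — published whole-credit tables are internally inconsistent on
half-credit cases, so the anchors used in testing are rows where LCL×area
is integral. Credits are computed per layer (0–15, 15–30, 30–60 cm) to
expose how depth intervals contribute; a treatment-mean BD change above 5%
flags FD rows with a note recommending ESM. Only a static (t0) baseline is
supported; business-as-usual counterfactual crediting is out of scope.

## Synthetic data

The generator emulates replicated two-time-point trials: per replicate and
layer, t0 = mean + Gaussian noise (resampled if unphysical), t1 =
t0·(1+relative change) + fresh noise. Three structural choices matter:

* **Per-plot response variation** (`bd_change_noise_sd`): the relative BD
  change itself varies across plots. Without it, measurement noise enters
  the FD−ESM gap and the BD-driven delta with opposite signs and the
  attribution correlation is structurally capped near 0.6; field-scale
  reports of r ≈ 0.9 imply response variation dominates measurement error.
  Century-style presets use BD measurement SD 0.03 g cm⁻³ (composited
  cores) against response SDs of 0.07/0.05 in the surface layers.
* **Depth-scaled concentration noise**: deep-layer SDs are large relative
  to their means (e.g. 0.9 on a mean of 2 g C kg⁻¹), reproducing the wide,
  zero-straddling CIs typical of subsoil stock changes.
* **Mass-preserving null** (`mass_preserving`): t1 concentrations are
  derived from the replicate's own t0 column so that cumulative stock as a
  function of cumulative mass is unchanged (the t0 field is extended below
  the sampled column at the deepest concentration, since compaction pulls
  deeper soil into the fixed window). True ESM change is zero by
  construction — exactly for the classical method, within spline tolerance
  otherwise — while FD reports an apparent gain.

Presets: `century_maize_like` (surface BD −16%, concentration +41%, n = 6,
grid 0–15/15–30/30–60/60–100/100–200 cm), `century_wheat_like` (BD −13%,
small concentration gains), `wicst_like` (no-till compaction: BD +19%,
concentration −19%, n = 12, grid to 90 cm), `compaction_null`
(deterministic repacking, +15%/+5% surface compaction). Noise is Gaussian
and independent across layers and replicates apart from the plot-level
response term; real soils add spatial autocorrelation, covarying layers,
measurement drift between campaigns, and non-Gaussian tails, so passing
tests demonstrate correctness of the accounting and calibration of the
rules under the emulated structure, not field-scale detectability.

## Numerical and testing notes

* Spline correctness is checked against a 0.1-cm brute-force integration of
  smooth underlying ρ(z), c(z) fields whose layer values are the fields'
  mass-weighted means; agreement is within 0.5% relative at query masses
  1–7% below the sampled total. (Against *piecewise-constant* layer fields
  the truth is piecewise-linear in mass and any smooth interpolant differs
  near kinks by up to ~1% at strong curvature — that comparison bounds
  interpolation-model disagreement, not implementation error.)
* Classical vs spline ESM agree within 2% relative on smooth profiles,
  guarding the choice of classical variant.
* Problem sizes used in the shipped checks — 10⁴ replicates for CI coverage
  and crediting calibration, 10⁵ for power validation, 200 seeds for
  scenario fidelity — were chosen to put Monte-Carlo error well inside the
  asserted tolerances.
* Boundary matching uses an absolute 1e-9 cm tolerance; all tables are
  CSV (UTF-8, '.' decimal, full float precision) and round-trip exactly.
* Determinism: every stochastic path takes a single integer seed
  (numpy `default_rng` / `SeedSequence` spawning for multi-treatment sets);
  identical config + input produce byte-identical outputs.

## Known limitations

* Reference masses derive from the same replicates they are applied to;
  no uncertainty is propagated from the reference-mass estimate itself.
* The classical-ESM borrow rule values deficit mass at the adjacent deeper
  layer's concentration only (no sub-layer refinement).
* No mixed-effects/blocked modeling of the experimental design, no spatial
  interpolation of grid baselines, no gap-filling of missing layers, and no
  process-based SOC modeling.
* `credit_table` uses the spline ESM variant for its ESM rows; the
  classical variant is available through the stocks table if preferred.
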