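# Methods

This note documents the models, numerical choices, and limitations behind
cellmech, in the spirit of a software methods section. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions and units

All internal quantities are SI: meters, newtons, seconds, pascals, joules.
Piezo position z increases toward the cell; repulsive (contact) force is
positive, adhesive force negative. Indentation is δ = (z − z₀) − (d − d₀),
piezo travel minus cantilever bending past the contact point (z₀, d₀).
Display helpers convert to nm, pN, kPa, fJ, but every API exchanges SI.

## Force-curve processing

**File format.** Curves travel as TSV with a `#`-prefixed metadata header
(spring constant, speed, optional setpoint and dwell) and columns
`time_s, z_m, deflection_m, segment`. The spring constant is mandatory —
force cannot be reconstructed without it, so a missing key is a hard
error, never a default. Floats are written as Python `repr`, which
round-trips to full precision.

**Baseline.** A linear force-vs-z baseline is fitted over the free
(non-contact) end of a segment — the head of an approach, the tail of a
withdraw — with one round of 3σ outlier rejection; the default window is
60% of the segment for indentation approaches (which are half free travel)
and 15–25% in the pipeline configurations, where events or the contact
region would otherwise intrude. `noise_sigma` is the SD of the final
residuals, floored at 10⁻¹⁷ N so thresholds remain defined on noise-free
synthetic data.

**Contact point.** Scanning from the deepest indentation toward the free
end, the first crossing of 3σ above the corrected baseline gives a coarse
contact index. Refinement fits the piecewise model F = 0 for x < x₀,
F = c·(x − x₀)^q for x ≥ x₀ on the tip–sample separation axis x = z − d
(where the contact law is an exact power law), scanning candidate x₀ on
the sample grid, minimizing the residual sum of squares, and interpolating
the minimum parabolically. The exponent q follows the tip model (2 for a
cone, 3/2 for a sphere/paraboloid, 1 for the SCFS press region). The
candidate scan reaches several windows back toward the free end because on
soft samples the threshold crossing overshoots the true contact by many
samples. On noise-free synthetic curves the recovered z₀ sits within one
sample spacing of the generator's contact offset; the refinement was the
single largest accuracy lever in development — a plain local quadratic
root was biased by >10 nm on Hertzian curves.

## Indentation mechanics

**Young's modulus.** F = B·δᵐ is fitted by nonlinear least squares (B
free, m fixed by the geometry, seeded from a log–log regression) over
δ ∈ (0, δ_cap], with δ_cap = 10% of the cell height when supplied, else
10% of the maximum recorded indentation. The shallow cap keeps the
contact-mechanics assumptions (semi-infinite medium, small strain) honest
for a ~µm-tall cell. E is recovered from B via the cone/Hertz prefactors
with ν = 0.5 by default. The default probe is a paraboloid of radius 1 µm
(colloidal probes), with the conical Sneddon form available; the geometry
is an explicit configuration choice, never silent.

**Plasticity index.** η = 1 − A₂/A₁ with A₁ the trapezoidal area under
the approach force–indentation curve and A₂ the area under the
nonnegative part of the withdraw curve from maximum indentation to its
zero-force crossing. Adhesive (negative) withdraw force is excluded from
A₂ so η stays in [0, 1] by construction; raw values pushed outside the
interval by noise are clipped and flagged (`clipped_eta`). Both areas are
computed on force vs indentation (not vs piezo travel).

**Aggregation.** Repeats at one position are averaged arithmetically into
one value per cell; group statistics run on per-cell values (n = cells,
never curves).

## SCFS adhesion

**Work of detachment.** W = ∫ max(0, −(F − F_baseline)) ds by trapezoid
from the contact point to the end of the last detected unbinding event
(fallback when no events are detected: the last 3σ excursion from
baseline). The bound is padded by a few samples because median smoothing
delays the detected step index; overshooting into the flat baseline is
harmless since the integrand there is ~0. W is nonnegative and invariant
under baseline offset by construction.

**Step detection.** The corrected force is smoothed with an 11-sample
moving median; candidate steps are positive jumps over a ≤5-sample span
exceeding max(min_step, 5σ); candidates closer than the smoothing window
merge into one event, positioned at the sharpest single-sample rise.

**Rupture/tether classification.** The pre-step slope is a least-squares
fit of force vs pulled distance over 100 nm before each step (truncated
at the previous event). |slope| above threshold → rupture, else tether.
The default threshold is 3× the SD of same-size-window slope fits along
the free baseline — scale-free in the noise — floored per event at 10% of
the step force divided by the pre-window, which keeps the decision
meaningful on noise-free data where the noise-derived threshold collapses
to zero.

## Image quantification

Cytoskeleton segmentation: Otsu threshold of the Gaussian-smoothed
(σ = 2 px) image, computed after clipping the brightest 1% of pixels
(very bright aggregates otherwise pull the Otsu split above the filament
intensity and collapse the mask onto the aggregates alone); components
< 64 px are dropped. Clipping at a quantile preserves Otsu's invariance
to intensity rescaling. Aggregates: white top-hat with a disk of radius
5 px, thresholded at mean + 3σ of the in-mask response, intersected with
the mask, components ≥ 4 px kept. The readout is
100·|aggregates|/|cytoskeleton| in percent. Images are assumed pre-cropped
to single cells; no nuclear segmentation is attempted.

## Statistics

Each group is screened with Shapiro–Wilk at α = 0.05; any failure switches
the whole endpoint to the nonparametric family (one test family per
endpoint). Normal: one-way ANOVA, post-hoc Dunnett vs control or Tukey
all-pairs (both via scipy). Non-normal: Kruskal–Wallis with a Dunn
post-hoc (rank z statistic with tie correction) adjusted by the Šidák
rule over the compared pairs — the variant is configurable (Bonferroni,
none) since post-hoc software differs here. A plain two-group comparison
without a named control uses Wilcoxon–Mann–Whitney; naming a control
keeps the multi-group family even at two groups. Descriptives use
linear-interpolation quantiles so reports are bit-reproducible.

ΔΔCt: ΔCt = Ct_target − Ct_reference per replicate; groups are summarized
by mean ΔCt (not mean of folds); per-replicate folds 2^(−(ΔCt −
mean ΔCt_control)) are returned for downstream group tests. The
suppression statistic counts targets with negative log2 fold change
(zeros excluded) and uses an exact two-sided binomial test against 0.5 —
the field reports a p bound for such fractions without naming a test, and
the sign test is the assumption-free choice.

## Synthetic-data generator

The generator exists to give every pipeline an analytic oracle.

**Indentation cycles.** Loading follows the tip-model power law exactly;
unloading follows F = F_max·(δ/δ_max)^p with p = (m+1)/(1−η) − 1, so the
area ratio A₂/A₁ = (m+1)/(p+1) = 1 − η is known in closed form. This
hysteresis model is a deliberate idealization chosen because it makes η
analytically known — real viscoelastic unloading is not a clean power
law. Curves are emitted as piezo position and deflection (d = F/k)
sampled uniformly in z, inverted from a dense interpolation table of
z(δ) = z₀ + δ + F(δ)/k. Noise is additive Gaussian force noise and/or
proportional (multiplicative) force noise; the grid of accuracy checks
uses 5% proportional noise with a 2 pN additive floor as the instrument
noise model. Defaults mirror the acquisition settings of the motivating
experiments: spring constant 0.08 N/m, speed 1 µm/s, 1 µm maximum
indentation.

**Retractions.** A linear contact-unloading region crosses zero at the
contact point; each event is either a rupture (linear adhesive ramp
ending in an instantaneous step, area ½F²/|slope|) or a tether (flat
plateau at depth F for a set length, area F·length). Events are placed
with Dirichlet-jittered gaps, at least 3× the 100 nm pre-window apart,
with the final 20% of the pull kept event-free so the baseline is
observable. Ground-truth work is the closed-form event-area sum. Defaults:
spring constant 0.32 N/m, 0.5 nN setpoint, 20 s dwell.

**Populations.** Cell stiffness is log-normal — strictly positive and
matching the skewed median/quartile summaries such experiments report —
parameterized directly by median and quartiles (σ_log from the quartile
ratio). Plasticity is normal truncated to [0, 0.95]. SCFS work is
log-normal; per-curve event counts are Poisson, labels Bernoulli, and
step forces are scaled so the analytic work matches the drawn per-repeat
value. Within-cell repeat variability is multiplicative Gaussian with a
default CV of 5% — the within-cell spread is not reported in the
motivating work, so this is a placeholder a user should override when
they know their instrument. Population runs use 10 pN additive force
noise and 500 samples per segment.

**Images.** Filaments are straight strokes (dilated centerlines,
half-width 3 px) with 1 px blurred edges — near-binary so the filament
area is insensitive to the exact segmentation threshold — plus bright
discs for aggregates placed on the filament network, background offset,
and Gaussian noise, written as 16-bit gray scale. Truth masks are pixel
exact. The generator can target a requested aggregate fraction by adding
puncta until the truth mask reaches it.

**Expression tables.** Ct tables are generated from per-group cycle
shifts with Gaussian Ct noise; DEG tables contain an exact requested
count of negative log2 fold changes among flagged targets.

What the generator does *not* emulate: brush/glycocalyx layers, substrate
stiffness bleed-through, hydrodynamic drag, piezo creep and hysteresis,
worm-like-chain tether elasticity, multi-cell images, or amplification-
efficiency deviations in qPCR. Passing the recovery tests therefore shows
the analysis chain is correct for the stated models, not that those
models capture every property of real instrument data.

## Problem sizes in the checks

The bundled accuracy checks use sizes chosen to estimate each property
stably: 200 curves across 0.3–5 kPa and both tip geometries for modulus
recovery; 500 simulated unbinding events (plus 300 pure-noise curves) for
detection/classification; two groups × 60 cells × 3 repeats × 20
replicate simulations for the population pipeline, with the published
group medians (1.65 vs 1.05 kPa, with their quartiles) as generator
settings; 1000 replicates of three identical normal groups (n = 30) for
type-I control; 20 images per condition for the image benchmark,
mirroring the 20-cells-per-condition design of the motivating study.

## Known limitations

* The Young's-modulus fit assumes the plain contact model; no brush or
  substrate-correction terms are implemented.
* The unloading power-law is a generator idealization; η estimated on
  real curves inherits whatever the instrument's hysteresis actually is.
* Step detection assumes near-instantaneous unbinding; slow, ramped
  detachments spread over many samples can be under-split.
* Dunn's adjustment variant differs between statistics packages; results
  match the Šidák rule unless configured otherwise.
* The image pipeline quantifies a single channel of pre-cropped cells and
  makes no attempt at colocalization or 3-D stacks.
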