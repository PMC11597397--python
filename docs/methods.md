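# Methods

## The pulse curve and its variants

The observable is percent modern carbon (pMC) in dentine collagen of a
growth layer, as a function of the calendar year the layer was deposited.
The five-parameter curve

    pMC(year) = a + b · exp((c − year)/d2) / (1 + exp((c − year)/d1))

is a logistic rise (timescale `d1`, half-rise year `c`) modulated by a slow
exponential decay (timescale `d2`) that represents mixing of bomb-enriched
surface water with the ^14C-depleted deep ocean. At `year = c` both
exponentials equal 1, so the curve passes through `a + b/2` there. The
model assumes a flat pre-pulse baseline `a`; this is an approximation (the
Suess effect and reservoir variation impose slow trends), adequate because
pre-pulse points are few and show no trend. The maximum is at
`year* = c + d1·ln(d2/d1 − 1)` with value
`pMC* = a + b·(d1/d2)·(d2/d1 − 1)^(1 − d1/d2)`; the formula needs
`d2/d1 > 1`, which the parameter invariant `d2 > d1` guarantees (at
`d2/d1 = 2` the peak sits exactly at `c`).

Series that never show a post-peak decline cannot identify `d2`. The
four-parameter variant drops the decay term and reparametrises `b` as the
post-pulse *asymptote* (increment `b − a`), so that the two variants'
parameter tables can be compared directly (`b_four ≙ a + b_five` roughly,
up to the peak overshoot).

Evaluation is overflow-safe: the logistic factor is computed through
`expit`/`logaddexp`, so years arbitrarily far before `c` are fine.

Curve inversion (dating) uses bracketed Brent root-finding on the monotone
rising limb, bracket `[c − 60·d1, year*]` (four-parameter: `c ± 60·d1`),
to 1e−8 yr. A falling-limb inverse exists but is flagged ambiguous: the
decay is slow relative to measurement error, so falling-limb dates carry
decade-scale uncertainty and are only emitted on request.

## Weighted fit

Estimation minimises Σ wᵢ(pmcᵢ − pMC(yearᵢ; θ))² with inverse-variance
weights wᵢ = 1/sdᵢ² from the reported AMS standard deviations. The
optimiser is bounded trust-region least squares started from a data-driven
guess (baseline = min pMC, half-rise at the first year the data cross the
midpoint, d1 = 5 yr) plus a 20-point Latin-hypercube multi-start; input
points are sorted internally so the result is row-order invariant. The
timescale separation is enforced structurally by optimising `s = d2 − d1 > 0`.
Non-convergence is reported honestly: optimiser failure, or `s` escaping
to its upper bound (5000 yr) — the flat direction of a rise-only dataset —
sets `converged=False` with a diagnostic recommending the four-parameter
fallback. The narwhal-only series behaves exactly this way; its
four-parameter fit converges cleanly.

The residual scale `sigma = sqrt(RSS_w/(n − p))` is dimensionless under
these weights. For the real tusk data `sigma ≈ 3.8`: the biological
scatter around the curve is several times the AMS measurement uncertainty,
which matters for the bootstrap choice below.

## Bootstrap confidence intervals

95% intervals (per parameter, and pointwise for the curve on a one-year
grid) come from a residual bootstrap: recentred residuals are resampled
with replacement, added to the fitted curve, and the model refitted
(warm-started at the point estimate); percentile quantiles over 1000
replicates give the intervals. Failed refits are dropped and counted; more
than 10% failures raises a warning.

Residual flavour: the default resamples **raw** residuals, treating the
errors as exchangeable. A standardized-weighted flavour (resample r·√w,
rescale by 1/√w at the destination) is available, but it is appropriate
only when the reported measurement s.d. genuinely tracks the error
variance. Two observations argue for the raw default here: on the real
data `sigma ≈ 3.8 ≫ 1`, i.e. the reported s.d. badly understate the actual
scatter, and in simulation (where reported s.d. are generated independent
of the realized noise, as labs effectively do) the standardized flavour
produced an artificially heteroscedastic pseudo-error pool and measurably
under-covering intervals, while the raw flavour achieved 91–93% empirical
coverage at the nominal 95% (percentile intervals at this n are expected
to sit slightly below nominal). The Monte-Carlo coverage study in the test
suite uses 200 replicates of ~160-point cohorts with 299 bootstrap
replicates per fit — a desk-scale design; the real-data analysis always
uses 1000.

## Prediction interval

The 80% band for a *new* measurement simulates, at each grid year, a
bootstrap parameter draw (curve uncertainty) plus Gaussian observation
noise, and takes the pointwise 10%/90% quantiles of 1000 draws. The
observation s.d. defaults to `sigma · median(reported sd)` — the implied
standard deviation of a typical new measurement under the weighted error
model. Setting it to zero collapses the band onto the curve-uncertainty
envelope, a useful degenerate check. On held-out synthetic points the band
contains 82–83% of observations (nominal 80%).

## Chronologies, classification, ages

A layer series under annual deposition is a linear calendar:
`year(layer) = anchor_year + (layer − anchor_layer)`. Tooth chronologies
anchor the prenatal tip (layer 0) at the birth year; tusks with broken
tips anchor the first preserved GLG at its inferred deposition year. Both
conventions are one rule with different anchors, and together they
reproduce every published layer/year pair of the bundled dataset.

The 95 pMC threshold separates pre- from post-pulse dentine. The default
classifier applies a 2σ buffer: a measurement is called pre-bomb or
post-onset only when its ±2 sd interval clears the threshold, otherwise
at-threshold (onset-era dentine) — matching how borderline first-layer
values are read in practice. A bare-threshold mode is available.

Age estimation from a dated first layer adds the missing-tip GLG interval:
age = (death − first layer year) + [lo, hi], birth mirrored. Years are
kept real-valued; rounding to calendar years happens only at reporting.

Dating of an unknown sample inverts the curve on the rising limb and
propagates pmc ± 2 sd through the inverse, widened by the 2.5–97.5%
spread of the inverse under bootstrap parameter draws when available.
Values at or below the fitted baseline are reported undatable (any
pre-pulse year is consistent); values above the fitted maximum raise an
error.

## Leave-one-out validation

The fold unit is the individual: all its samples are held out, the curve
is refitted to everyone else, and each held-out measurement with pMC
strictly between 95 and the refitted maximum (the informative rising
window) is inverted to a deposition year and mapped to a birth year via
its layer index. Per-individual estimates are combined by unweighted mean
(inverse-variance weighting optional); errors are signed (predicted −
true), summarised by mean, median, sd and standard error of the mean.
Individuals with no eligible measurement are listed and excluded. On
noiseless synthetic cohorts the procedure returns zero error to numerical
tolerance; at 0.3 pMC noise with births spanning the rise the mean
absolute error is about 1 yr. Individuals born after the peak invert
degenerately onto the rising limb (their layers sit near the asymptote),
which is a property of the method, not a bug — the tool targets animals
alive during the rise.

## Synthetic cohorts

The generator emulates the multi-individual layer-series design: each
individual gets a birth year (uniform in a range), a lifespan, and a set
of sampled layer indices (even or random placement); layer k is deposited
in year birth + k and its pMC is curve(year) + N(0, noise_sd). Defaults
are the conditions of the real data: the published all-species parameters
(a=92.2, b=12.9, c=1965, d1=6.4, d2=218.2) as truth, noise 0.3 pMC (the
magnitude of the printed AMS s.d. column), reported s.d. drawn uniformly
from [0.25, 0.55] *independently* of the realized noise (as lab-reported
uncertainties effectively are), 20 individuals × 8 layers ≈ 160 points,
births 1900–1985, observations capped at 2008. All randomness flows
through one numpy PCG64 generator seeded by an explicit integer; the same
spec reproduces the same dataset bit for bit across platforms.

What the generator does *not* emulate: trophic-lag smoothing of the
^14C signal (discussed for belugas), pre-pulse baseline trends, layer
mis-counts, or between-individual biological offsets. Passing recovery
and coverage tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to those
real-data complications.

A biennial variant deposits one layer every two years while the recorded
chronology still assumes annual deposition. An assumed-annual timeline
then traverses the pulse at twice the true speed, so the fitted `d1` on a
biennial cohort is about half that of the matching annual cohort (ratio
annual/biennial ≈ 2.0, measured over replicates with a common 1935–1945
birth era — a narrow era isolates the timescale distortion from
between-individual smearing of the apparent rise). Recording the true
two-year spacing restores recovery, and a noiseless biennial cohort
misfits systematically (positive objective) under the annual assumption —
the diagnostic signature the annual-deposition test relies on.

## Numerical and design choices

* Seeds are explicit arguments everywhere; default 20240350.
* Convergence: relative objective change below 1e−10 within 500
  iterations; singularity/bound escape reported as non-convergence.
* Repeated measurements of one layer (same lab) are legitimate and kept;
  only rows identical in (specimen, layer, lab, pmc) are rejected as
  double entries.
* Isotope summaries use `math.fsum`, so they are exactly order-invariant;
  single-value groups report sd = 0 with an explicit flag.
* The prenatal/postnatal δ15N classifier is a nearest-reference-mean
  heuristic with a ±0.5‰ indeterminate buffer (≈ one measurement s.d.);
  references closer than 1‰ are refused as uninformative. It is a
  screening aid, not a calibrated classifier.
* Deposition years in the bundled dataset are the source chronology's
  estimates, treated as known inputs to fitting; no errors-in-variables
  treatment is attempted.

## Known limitations

* The five-parameter `d2` is weakly identified even in rich designs (its
  interval can span hundreds of years); peak-year estimates inherit that
  uncertainty.
* Bootstrap percentile intervals sit 2–4 points below nominal coverage at
  n ≈ 160; bias-corrected variants are not implemented.
* Dating assumes the sample comes from the rising-limb era; post-peak
  samples are only weakly datable and pre-pulse samples not at all.
* No marine reservoir-age corrections, atmospheric reference curves, or
  trophic-lag modelling.
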