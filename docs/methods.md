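# Methods

`reefscape` implements a complete analysis chain for diver-based surveys of
temperate reef fish communities and their structural habitat: pressure-logger
traces are converted into reef-rugosity metrics, belt-transect fish records
into community metrics, and the two are related with generalized linear
models and multivariate community statistics.  A synthetic-data generator
with planted parameters makes every stage testable end to end without field
data.  This note records the models, the defaults and why they were chosen,
and what the synthetic validation does and does not demonstrate.

## Logger traces and distance calibration

A diver tows a 1 Hz pressure logger along a 30 m transect at a nominal
10 cm/s, raising it ~1 m and rapidly lowering it ("spikes") 5 times at the
start, 3 times at every 5 m mark, and 5 times at the end.  Absolute pressure
(PSI) is converted to depth via the hydrostatic relation

    depth = (p − p_atm) × 6894.757 / (ρ g),

with p_atm = 14.696 PSI (1 atm), ρ = 1025 kg/m³ (seawater) and
g = 9.81 m/s².  Negative depths (surface noise) are clipped to zero and
counted.  No tide or barometric correction is applied.

**Spike detection** uses a matched rise–fall criterion: a shallowing of at
least `min_excursion` (default 0.5 m) completed within 2 samples, paired
with an equal deepening within `max_width` (default 6 s).  This exploits the
physics of the maneuver — the logger goes up *and comes back* within
seconds, whereas reef features do not: a ledge never comes back down within
the window, and a block or hull wall keeps the logger shallow until the
diver has crossed it.  A rolling-median-baseline detector was tried first
and rejected: the median lags steep ramps and misreads ramp corners and
narrow blocks as excursions.  One residual ambiguity is physical, not
algorithmic: at 1 Hz, a spike executed exactly while the diver steps off a
block of similar height can have its rise masked.  Spike groups are
therefore clustered with a 12 s gap — in-group spikes are 6 s apart, so a
single missed spike (12 s hole) cannot split a group, while adjacent groups
are ≥ 15 s apart at any admissible swim speed.

**Distance calibration** assigns the detected groups to 0, 5, …, 30 m and
maps time to distance piecewise-linearly between group centres; per-segment
speed is 5 m over the centre-to-centre interval, which handles off-nominal
swim speeds at the finest granularity the spike layout supports (a single
global rescale is available via the same machinery by ignoring interior
groups).  **Spike removal** drops each detected rise-to-fall window plus a
1 s guard.  Because the matched-event detector delimits the contaminated
samples exactly, a wider guard only destroys clean reef samples: a 2 s
guard was found to blank every clean sample between in-group spikes and to
bias recovered depth variance (hence rugosity) low by several percent.  A
profile in which fewer than half the on-transect samples survive removal is
rejected as a quality error.

## Complexity metrics

* **Digital reef rugosity (DRR)** — sample standard deviation (n−1) of the
  depths along a transect, in metres.  The n−1 denominator is the default of
  the common statistics environments; the difference is < 1% at the sample
  sizes involved.
* **Chain rugosity** C = D/L, with D the summed hypotenuse lengths between
  successive (distance, depth) samples and L the linear distance; C = 1 iff
  the profile is affine.
* **Vertical relief** — max depth − min depth.
* **Semivariogram** γ(d) = Σᵢ (yᵢ − yᵢ₊d)² / (2N(d)) over all pairs at lag d,
  computed on a profile resampled to a uniform 10 cm grid so lag classes are
  exact under variable swim speed, and reported to L/2 (the spatially
  structured range; larger lags available behind a flag).
* **Kernel density** of DRR by reef type uses a Gaussian kernel with
  Silverman's bandwidth.

Resampling uses linear interpolation with end clamping; metrics in the
pipeline are computed on the 10 cm grid.

## Fish community metrics

Belt transects are 30 m × 4 m (120 m²).  Biomass uses the allometric
length–weight relationship W = a L^b (W in g, L in cm), with species-level
coefficients and a family-average fallback (means of a and b over the
family's species observed in the study) for fish identified only to family;
fallback use is counted in the outputs.  Schools spanning a size range are
scored at the midpoint length.  Size classes are small 1–10 cm, medium
11–29 cm, large 30–49 cm, extra-large ≥ 50 cm; integer-cm recording means
the classes partition all lengths (non-integer inputs are floored with a
warning).

Two transects per reef per season are averaged into one replicate.
Averaged abundances are rounded to the nearest integer (half away from
zero — the convention is a package choice; only "nearest integer" is
inherent) because the count models require integers; biomass stays
continuous.  Richness is likewise averaged and rounded; a pooled-species
mode is available because averaging versus pooling is a genuinely open
choice, and the two differ when the transects sample different species.
Sediment depth is measured every 3 m with both endpoints included (11
points on 30 m); its within-transect standard deviation, averaged over
replicate transects, indexes how permanent (low SD) or ephemeral (high SD)
sediment cover is.

## Habitat models

Replicate-level responses are modelled with log-link GLMs: abundance with a
negative-binomial error distribution, biomass with a gamma, richness with a
Poisson.  The full model contains DRR, DRR², depth, and temperature, plus
sediment SD for natural reefs only; candidates drop the {temperature},
{sediment SD}, and {DRR, DRR²} blocks in all combinations, always keeping
DRR when DRR² is present.  Selection is by minimum AIC with
AIC = 2k − 2 logL, where k counts the NB dispersion or gamma shape when
estimated.  Non-convergent candidates are excluded from selection but kept
in the reported AIC table.

The NB dispersion (size θ) is estimated by profiling the likelihood over
the IRLS mean fit (the alternating scheme of the standard NB-GLM
implementations); the gamma shape solves its ML score equation
log k − ψ(k) = mean(y/μ − log(y/μ)) − 1.  Wald tables report β, SE, Z =
β/SE, and two-sided normal P-values, with SEs evaluated at the ML
dispersion.  Zero-biomass replicates are excluded from gamma fits (positive
support) with a logged count.

**Goodness of fit** is assessed graphically (estimated distribution with
observations superimposed) and analytically: each observation is treated as
a test statistic against its fitted conditional distribution, with
two-sided tail probability P = 2·min(F(y), 1−F(y⁻)) capped at 1 (one-sided
available).  For continuous families this statistic is uniform under a
correct model, which the calibration study verifies by KS test.

**Pattern classification**: with both rugosity terms significant at α =
0.05, a negative quadratic coefficient, and the vertex −β₁/(2β₂) inside the
observed DRR range, the relationship is *unimodal*; both terms merely
marginal (P ≤ 0.10) or one significant and the other marginal gives
*marginally unimodal*; a single significant term gives *linear* or
*quadratic*; otherwise *none*.  The marginal band (0.05, 0.10] is
configurable.  Covariates enter raw (uncentred).

## Community structure

Community analyses work on the replicate × family abundance matrix,
square-root transformed for distance-based methods.  Bray–Curtis
dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) feeds a one-way PERMANOVA
(pseudo-F from squared-dissimilarity partitioning, P from free relabeling
of samples, 1000 permutations by default with the (1+count)/(1+n_perm)
convention; exhaustive enumeration for small designs) and a nonmetric MDS
(SMACOF with isotonic regression minimizing Kruskal stress-1, k = 2, 20
random restarts plus a classical-scaling start, Shepard pairs emitted).
Indicator analysis uses untransformed abundances and the group-size
corrected IndVal: A = the group's (or group combination's) share of summed
per-group mean abundance, B = occurrence frequency within the combination,
statistic √(A·B), significance by label permutation; combinations up to
pairs are reported so indicators of, e.g., both artificial morphologies are
expressible.  Univariate metrics are compared across the four morphologies
with one-way ANOVA (log transform for abundance and biomass, log(x+1)
fallback when zeros occur) and pairwise pooled-variance t-tests with Holm
adjustment.

## Synthetic data

The generator emulates the four field streams with planted truth.

* **Profiles.**  Pavement-and-rubble: flat with gentle undulation and
  micro-roughness; ledge: a logistic step of height `relief_amplitude`
  (widths 0.2–1 m, sharp to gradual); concrete: 2–4 low blocks 2–4 m wide
  (clustered pipe piles); ship: a rectangular superstructure with ramps
  whose horizontal run grows with hull height (a towed logger cannot track
  a vertical wall).  Micro-roughness is Gaussian with ~1 m correlation
  length: reef relief varies over decimetres to metres, and sample-to-sample
  white noise at 10 cm would be unobservable through 1 Hz sampling and
  spike blanking — no processor could recover it, making round-trip
  validation ill-posed.
* **Traces.**  Per-5 m-segment swim speeds are Normal(10, 1.5) cm/s,
  clipped to 0.4–1.5× the mean (so spike groups never merge in time);
  spike groups are centred on the crossing time of each 5 m mark; pressure
  noise is Gaussian, default 0.02 PSI ≈ 1.4 cm of depth.
* **Fish.**  Total count per transect is negative-binomial with log-mean
  β₀ + β₁·DRR + β₂·DRR² + β_depth·depth + β_temp·T.  Defaults mirror the
  fitted field models: natural reefs (2.26, 9.72, −9.81, 0.11, 0) and
  artificial reefs (4.37, 1.31, −0.37, 0.12, 0).  The NB size defaults to
  3.0 — a free choice (no field estimate is available to copy), giving the
  strong overdispersion typical of schooling reef fish counts.  Counts are
  allocated to 14 families by morphology-specific composition profiles —
  concrete demersal-weighted, ships pelagic-weighted (mackerel, snapper,
  jacks) — then to species and integer-cm lengths via size-class samplers;
  large schools are recorded as min–max length ranges.  One species is
  deliberately absent from the shipped coefficient table to exercise the
  family fallback.
* **Study layout.**  Default 16 natural + 14 artificial sites, 4 seasons,
  2 transects per site × season, sediment every 3 m on natural sites only
  (pavement: 4 ± 2.5 cm, ephemeral veneer; ledge: 1 ± 0.5 cm), seasonal
  temperatures 17–27 °C.  Optional Bernoulli weather dropout thins a site
  to one season.  All randomness derives from one seed; identical config
  and seed give byte-identical outputs.

**What the generator does not emulate:** fish behaviour (schools are i.i.d.
draws, no attraction between adjacent reefs), spatial autocorrelation
between sites, tide and logger drift, detection error by divers, and any
coupling of composition to rugosity beyond the morphology labels.  Passing
validation therefore demonstrates that the *pipeline* is correct and well
calibrated under the planted model, not that the planted model describes
any particular reef system.

## Validation studies and problem sizes

The reproduction script and the test suite run the same studies at the
following sizes, chosen to give stable estimates at interactive runtimes:
round-trip rugosity recovery on 20 transects across the four morphologies
(observed worst-case error ≤ ~4% at 1.4 cm pressure noise); unimodal
classification power at n = 67 replicates over 50 seeds with planted
(2.0, 6.0, −6.0, 0.1, 0) and vertex 0.5; type-I rate over 500 null
simulations; semivariogram agreement with a brute-force double loop on 200
random profiles of ≤ 60 points (exact to floating-point round-off);
permutation-test exactness against full enumeration on 4–5-sample designs;
and predictive-P-value uniformity at n = 500.

## Numerical choices and degenerate inputs

NB dispersion is profiled on log α over [10⁻⁶, 10³]; Poisson-like data run
to the boundary and report a very large size, which is the correct limit.
Rank-deficient design matrices are rejected as degenerate rather than
silently pseudo-inverted.  The semivariogram enforces max_lag ≤ L/2 unless
overridden.  nMDS ties in the isotonic fit are handled by stable rank
ordering; coordinates are centred, and stress is the best across restarts.
Bray–Curtis is undefined for an all-zero sample; such rows are rejected
(the pipeline drops empty replicates before community analysis).
Permutation P-values can never be zero by the (1+count)/(1+n_perm)
convention.

## Known limitations

Single-predictor-block model search (no interactions); no mixed effects or
spatial correlation structure; no multiple-testing correction across the
response × reef-type family of models; PERMANOVA assumes exchangeable
samples (no strata); the indicator statistic follows the group-size
corrected convention and other IndVal variants will differ numerically;
family-level community analysis only.
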