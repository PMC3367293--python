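# Methods

This note documents the statistical model behind `morankrig`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Spatial weights and Moran statistics

Weights are binary distance-band weights: $w_{ij} = 1$ iff
$0 < d(i,j) \le t$ on projected planar coordinates (default unit km), with
no row standardisation. The raw weight sums $S_0 = \sum_{ij} w_{ij}$,
$S_1 = \tfrac12\sum_{ij}(w_{ij}+w_{ji})^2 = 2S_0$ (binary symmetric) and
$S_2 = \sum_i (w_{i\cdot}+w_{\cdot i})^2$ feed the null moments of Moran's
I. Row standardisation is deliberately not offered: the standardisation
changes the meaning of $S_1, S_2$ and therefore of $Z(I)$, and the
distance-band definition of "neighbour" is a 0/1 membership.

The variance of $I$ uses the classical normality-assumption moments,

$$\operatorname{Var}[I] =
\frac{n^2 S_1 - n S_2 + 3 S_0^2}{S_0^2 (n^2 - 1)} - E[I]^2,
\qquad E[I] = -\tfrac{1}{n-1},$$

oracle-tested against an independent implementation of the same formula.
An alternative randomisation-assumption variance is not implemented; on
log-transformed concentrations (screened for normality first) the
normality form is the appropriate default, and the null-calibration
experiment confirms the nominal 5% rejection rate empirically. Under full
connectivity $\operatorname{Var}[I] = 0$ exactly ($I$ is then the constant
$-1/(n-1)$); correlogram points in that regime keep their $I$ value and
carry an undefined (NaN) $Z(I)$.

Geographic (lat/lon) input cannot be detected reliably from coordinates
alone, so suspicious coordinates trigger a warning rather than a hard
rejection; users are told to project first.

### Local Moran's I and LISA categories

$I_i = (z_i / m_2) \sum_j w_{ij} z_j$ with $m_2 = \sum_k z_k^2 / n$
computed over **all** sites, so that $\sum_i I_i = S_0 \, I$ — a testable
decomposition of the global statistic. Significance defaults to
conditional permutation (999 draws, two-sided pseudo-p < 0.05, mandatory
seed); one shared permutation-index matrix is drawn over the $n-1$ "other"
sites and reused across sites, the standard implementation of conditional
randomisation. An analytic conditional-normal approximation is available
(`method="analytic"`). Significant sites are labelled by the signs of
$z_i$ and its spatial lag (High-high, Low-low, Low-high, High-low); all
non-significant or neighbourless sites are Not-significant.

Permutation inference is granular at very small $n$: with $k$ neighbours
drawn from $n-1$ values the attainable p-values are coarse, so toy
configurations with $n \lesssim 10$ may show no significance at all. This
is a property of the test, not a defect.

### Correlogram and characteristic distances

The default threshold grid runs from the smallest distance at which no
record is an island up to half the maximum pairwise separation, in 30
steps. d1 and d2 are the thresholds maximising $I$ and $Z(I)$ (ties break
toward the smaller threshold — closer distance, more similarity); d3 and
d4 are linearly interpolated zero crossings of $I$ (positive→non-positive,
then negative→non-negative). d4 is read as the *second zero crossing* (end
of the first negative range); when no negative range exists d4 is absent
and the d4 model is pruned downstream. When $I$ never crosses zero inside
the grid, d3 is likewise reported absent with a warning (the positive
correlation range extends beyond the sweep) rather than raising: this is
a grid-extent limitation, not a pathology of the data.

## Variogram estimation and fitting

Pairs with separation $\le$ the active lag are grouped into equal-width
bins (default 10) represented by their mean separation; empty bins drop.
Fitting is unweighted least squares on bin semivariances (matching the
R²/RSS conventions of classic variogram software), with optional
$\sqrt{N(h)}$ weighting. Initial values: $C_0$ = first-bin gamma, partial
sill = max bin gamma minus $C_0$, range = active lag / 3; bounds keep all
variances non-negative and ranges positive. The fitted range parameter
$a$ is reported alongside the practical range $3a$ — conventions differ
between software packages, so both are always exposed.

The nested model is fitted **jointly** to the long-lag empirical variogram
(both structures and the nugget free), initialised from the two
single-structure fits; summing two independently fitted models would
double-count the nugget and overshoot the sill. If the two ranges collapse
within 5% the model degrades to a single structure with a warning.

`gamma(0) = 0` exactly — the nugget is a discontinuity at the origin, which
is what makes ordinary kriging an exact interpolator.

## Kriging, back-transform, cross-validation

Ordinary kriging uses the `n_neighbors = 12` nearest samples (minimum 4,
no radius cap by default) — values mirroring common GIS practice, fully
configurable. Negative weights are permitted; clamping would destroy
exactness. The kriging variance is $\lambda^\top \gamma_0 + \mu$,
floored at 0 against roundoff.

For log-modelled analytes the default back-transform is the lognormal
ordinary-kriging correction $\exp(\hat y + \sigma_K^2/2 - \mu)$, which
removes the downward mean bias of the naive $\exp(\hat y)$; the naive mode
is retained for sensitivity runs.

Leave-one-out cross-validation predicts every sample with itself removed.
ME, MAE, RMSE and MSE are computed on the back-transformed concentration
scale (mg/kg), because that is the scale at which maps and pollution
status are used; RMSSE is computed on the working (log) scale where the
kriging standard deviation is defined. Model ranking follows: ME closest
to zero first, |RMSSE − 1| as the tie-break, then the label
alphabetically for exact ties.

## Pollution assessment

Single-factor index $P_i = C_i / S$ with *strict* inequality ($P > 1$ is
polluted; configurable to $\ge$). Agreement tables report percent of all
samples. Summary statistics use the $n-1$ standard deviation. Background
classification bins a prediction grid at multiples of the background value
(class 0 below background, last class open above); masked cells propagate
as −1.

## Synthetic-data generator

The generator emulates a regional soil survey: uniformly scattered sites
on a square domain; a latent Gaussian log-scale field with covariance
$C(h) = \sum_k C_k e^{-3h/a_k}$ (practical-range parameterisation, so the
specified range matches the variogram module's practical range) plus an
independent nugget; lognormal concentrations by exponentiation. Sampling
is exact (Cholesky factorisation with a $10^{-10}$ relative jitter),
capped at 3,000 sites — correctness over scale. Every draw requires a
seed.

Anomalies: cluster patches receive an additive log-uplift; point outliers
are set to mean + $m\cdot$SD on the log scale at sites whose
neighbourhood mean is in the lowest decile, producing genuine High-low
geometry (a point source in a clean area — placement in an *average*
neighbourhood would not be a spatial outlier at all). Injected indices
are recorded as ground truth. Three-tier stratified sampling draws nested
subsets (uniform low-density tier; medium/high tiers optionally
density-weighted), mirroring staged survey designs.

The canonical study conditions (`survey_spec`) are a 100 km domain with
1,018 sites, log-mean 4.0, nugget 0.04, and structures (0.12, 6 km) +
(0.12, 60 km). The 6 km local structure sits at the scale where raw
correlograms peak in such surveys and *inside the first bin* of a
half-maximum-lag variogram — which is why the traditional fit absorbs it
into the nugget and reports nugget/sill ratios in the 30–50% range even
though the true nugget share is ~14%. The generator does **not** emulate:
trends or spatially varying means, anisotropy, measurement censoring,
multi-analyte cross-correlation, or non-lognormal marginals. Passing
tests therefore demonstrate correctness of the machinery and the
direction of the method's advantages under these idealised conditions,
not performance on any particular real survey.

## Simulation studies (`morankrig.experiments`)

Problem sizes were chosen to make each question answerable at desk scale:

- **Parameter recovery** — 20 fields × 500 sites, true practical range
  20 km (one fifth of the domain, so several correlation ranges fit
  inside the sampled area; ranges approaching a third of the domain are
  not identifiable to useful precision at this $n$), 15 bins to resolve
  the variogram rise. Reports median relative errors of sill and
  practical range.
- **Null calibration** — 200 nugget-only fields × 100 sites, one 15 km
  threshold each; reports the $|Z(I)| > 1.96$ rejection rate.
- **Model comparison** — 10 survey-condition fields with injected
  hotspots; full pipeline for d1, d2, d5, nested; reports median MAE/RMSE
  per model and total hotspot status flips (polluted measured →
  unpolluted predicted) for nested vs d5. The CV-error advantage of the
  guided models is the stable signal; the flip contrast is directionally
  consistent but small at this scale and varies with the seed stream —
  on some streams it can invert. Totals rather than medians are used for
  the flip comparison because per-field counts are small.
- **Outlier recovery** — 20 weak-structure fields × 400 sites, six +4 SD
  outliers each; reports the median fraction flagged significant
  High-low at the injection neighbourhood distance.

Per-replicate seeds are derived from the base seed via `SeedSequence`, so
every experiment is exactly reproducible.

## Known limitations

- Isotropic models only; no spherical/Gaussian alternatives (the
  exponential family is the method's working model).
- No indicator, universal or co-kriging; no block support.
- The exact-covariance generator does not scale beyond 3,000 sites.
- Raster export is Esri ASCII grid text (GeoTIFF writers are out of
  scope); GeoJSON I/O handles Point features only.
- The d4 reading ("end of the first negative range") is one of two
  plausible interpretations of the sum-of-ranges idea; it is the one
  consistent with correlograms whose negative range is followed by a
  second positive range.
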