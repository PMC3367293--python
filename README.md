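# morankrig

Spatial-autocorrelation-guided geostatistics for mapping soil contaminants.

Regional surveys of heavy metals in agricultural soil (Cr, Ni, Zn, Hg, …)
need interpolated concentration maps for exposure and risk assessment.
The standard tool is ordinary kriging driven by a semivariogram, but the
semivariogram's *active lag distance* — the maximum pair separation entering
the empirical estimate — is conventionally set to half the maximum
separation by trial and error, and a single model fitted at that lag blurs
short-range structure (pollution hotspots) into the nugget. `morankrig`
implements the alternative: extract characteristic distances from Moran's I
spatial correlograms and use them as active lag distances, so the variogram
models — including a nested short- plus long-range model — are informed by
the scales at which spatial correlation is actually strongest.

Intended users: environmental scientists and spatial statisticians working
with georeferenced point-sample concentration tables (CSV/GeoJSON, projected
coordinates in km).

## The statistics

Global Moran's I for attribute $x$ with binary distance-band weights
$w_{ij}$ ($w_{ij}=1$ iff $0 < d_{ij} \le t$):

$$I(t) = \frac{n}{S_0}\;\frac{\sum_i\sum_j w_{ij} z_i z_j}{\sum_i z_i^2},
\qquad z_i = x_i - \bar x,\; S_0 = \sum_{ij} w_{ij}$$

standardized under the normality assumption to
$Z(I) = (I - E[I]) / \sqrt{\operatorname{Var}[I]}$ with $E[I] = -1/(n-1)$;
$|Z(I)| > 1.96$ flags significance. Sweeping the threshold $t$ gives the
correlogram, from which four characteristic distances are read: **d1**
(argmax $I$), **d2** (argmax $Z(I)$), **d3** (first zero crossing), **d4**
(end of the first negative range). Local Moran's I
$I_i = (z_i/m_2)\sum_j w_{ij} z_j$ classifies sites into High-high /
Low-low clusters and High-low / Low-high outliers by conditional
permutation.

The empirical semivariogram under active lag $L$,

$$\gamma(h) = \frac{1}{2N(h)} \sum_{d_{ij} \approx h,\; d_{ij} \le L}
\bigl(z(x_i) - z(x_j)\bigr)^2,$$

is fitted with the exponential model
$\gamma(h) = C_0 + C\,(1 - e^{-h/a})$ (practical range $3a$) or the nested
two-structure model
$\gamma(h) = C_0 + C_1(1 - e^{-h/a_1}) + C_2(1 - e^{-h/a_2})$ with
$(a_1, C_1)$ seeded from the d1-lag fit and $(a_2, C_2)$ from the d2-lag
fit. Ordinary kriging solves the semivariogram system under
$\sum_i \lambda_i = 1$; log-scale predictions are back-transformed with the
lognormal correction $\exp(\hat y + \sigma_K^2/2 - \mu)$. Models are scored
by leave-one-out cross-validation (ME, MAE, RMSE, MSE, RMSSE) and by 2×2
agreement of single-factor pollution status ($P_i = C_i/S > 1$) between
measured and predicted concentrations.

## Worked example

`examples/03_model_comparison.py` simulates a 1,018-site survey-like
lognormal field with two covariance structures (6 km and 60 km practical
ranges), injects hotspot patches and point outliers, and runs the full
comparison:

```
characteristic distances: {'d1': 4.7, 'd2': 22.4, 'd3': None, 'd4': None}

cross-validation (concentration scale, mg/kg):
 model analyte     ME    MAE   RMSE      MSE  RMSSE
    d1   metal -2.416 24.585 52.880 2796.249  1.052
    d2   metal -2.043 24.801 53.085 2818.012  1.062
    d5   metal -1.867 25.557 53.979 2913.773  0.984
nested   metal -2.160 24.631 52.806 2788.510  1.075

pollution-status agreement, nested model (percent of samples):
measured    polluted  unpolluted
predicted
polluted        0.69        0.39
unpolluted      1.18       97.74
```

Reading the numbers: the correlogram peaks at ~5 km (d1) — the hotspot
scale — while the traditional model d5 (active lag = half the maximum
separation, here ~69 km) cannot resolve it and pays for that with the
largest MAE/RMSE/MSE of the roster. The d1, d2 and nested d1+d2 models cut
cross-validation error, and the agreement table shows the nested model
keeping 0.69% of samples correctly classified as polluted while 1.18% are
underestimated. RMSSE near 1 means the kriging variances are honest.

Other examples: `01_correlogram_and_distances.py` (correlogram +
characteristic distances), `02_variogram_and_kriging.py` (variogram fit and
gridded prediction), `04_lisa_outliers.py` (local Moran recovery of
injected High-low point sources). Each prints what it computes and what
the numbers mean.

A thin CLI mirrors the library: `morankrig simulate | screen | correlogram
| distances | variogram | lisa | run` (see `morankrig --help`).

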