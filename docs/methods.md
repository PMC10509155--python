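# Methods

## Measurement model

A stem segment's specific hydraulic conductivity is
`K_s = F·L/(ΔP·A_x)` in kg s⁻¹ m⁻¹ MPa⁻¹. Two readings per stem — native
winter state ("field") and after flushing emboli with KCl solution
("flushed") — give `PLC = 100·(K_s_max − K_s_field)/K_s_max`. Flushing can
only increase conductivity, so a negative PLC (possible under measurement
noise) is clamped to 0 and recorded in the structured warnings, never
silently dropped.

Root pressure compresses the air bubble of a closed water-filled
manometer; by the ideal gas law at constant temperature,
`P_R = 100·(L_atm/L_pd − 1)` kPa. Negative values (pre-dawn bubble longer
than atmospheric) usually indicate a leaking fitting and are flagged but
returned. The maximum embolism-reversal height is `h_c = (P_R − P_c)/10`
m; the reference pressure `P_c` is not defined in the source protocol and
defaults to 0 (gauge pressure at the stem base), which reproduces the
published heights from the published site-mean root pressures; it is an
explicit parameter everywhere.

Vessel diameter is the mean of the longest and shortest lumen axes.
Branch summaries need >100 vessels (a warning is attached below that);
the species(-site) mean is the unweighted mean of its branch means.
Diameter classes are left-closed 10-µm bins `[10k, 10(k+1))` — the
left-closed convention makes a 10-µm vessel unambiguous — and the
Hagen–Poiseuille contribution of a class uses the *individual* vessel
radii (`Σ_class r⁴ / Σ_all r⁴`), not class midpoints. "Wide vessels" are
strictly `> 100 µm`. The KS statistic compares the cumulative frequency
and cumulative conductivity distributions at the class boundaries; the
asymptotic p-value uses the two-sample Kolmogorov distribution with both
effective sample sizes equal to the vessel count (an explicit convention
— there is no uniquely correct effective n for a weighted-vs-unweighted
comparison of the same vessels), and a permutation alternative is
provided that shuffles per-vessel r⁴ weights against diameters (null: no
association between vessel size and conductivity share).

## Trait statistics

The analysis unit is the species-site mean: 16 rows in the reference
design (7/5/4 species at the warm/mid/cold site). ANCOVA fits
`trait ~ tmin + site` with type-II tests. Because the covariate takes one
value per site it is aliased with the site factor; the aliased covariate
is dropped, the site F-test proceeds on the remaining df (2 and 13 in the
reference design), and the result carries a collinearity flag rather than
failing. Levene's test is median-centred. Tukey HSD uses the studentized
range on the pooled within-site error. No multiple-testing correction is
applied across traits.

PCA standardises each trait (ddof = 1) and decomposes the correlation
structure via SVD; percent variances sum to 100 by construction, and the
sign convention (largest-magnitude loading positive per component) makes
results deterministic. Per-site OLS of growth rate on component scores
reports R² and two-sided p; sites with fewer than 3 units are flagged
`insufficient_n` instead of being dropped. Site-mean correlations use
Pearson's r with a t-based two-sided p on n−2 df — with 3 sites this p
has 1 df and is essentially uninformative; the R² is the meaningful
summary at that n.

## Phylogenetic mixed model

The covariance between species i and j is the root-to-MRCA shared path
length, scaled to unit maximum diagonal (invariant to branch-length
units). The model `y = Xβ + Za + e`, `a ~ N(0, σ²_a·A)`,
`e ~ N(0, σ²_e·I)` is sampled by Gibbs: β from its conditional normal
(flat prior), `a` from its conditional normal, variances from inverse
gammas. The (V, nu) prior parameterisation maps to IG(nu/2, nu·V/2);
the default (V = 1, nu = 0.002) is the conventional weakly informative
choice, and with only 16 units the variance posteriors remain noticeably
prior-sensitive — DIC differences, not variance point estimates, are the
intended output. DIC uses the conditional deviance
`D(β, a, σ²_e) = −2 log N(y | Xβ + Za, σ²_e I)`, with
`DIC = 2·D̄ − D(posterior means)` (the pD form); a negative effective
parameter count is flagged. ΔDIC = DIC_without − DIC_with > 10 is read as
evidence for a phylogenetic effect. Default run lengths are 110,000
iterations, 10,000 burn-in, thinning 100; the `ci` profile (11,000 /
1,000 / 10) is used in the test suite, where a simulation study shows the
comparison stays under the threshold on ≥80% of no-signal replicates and
favours the phylogenetic model on most strong-signal
(σ²_a/σ²_e = 5) replicates at n = 16.

## Synthetic-data generator

The generator emulates the study design: 3 sites (climate table fixed to
the published station records), 7/5/4 species per site over a 10-species
pool, 25–30 growth individuals, 10 stems with paired field/flushed flow
measurements, 5 branches × 120 vessels, 5 manometers and one wood sample
per stem per species-site unit. Records are generated backwards from
trait targets: per-species lognormal offsets (mean 1, drawn once and
shared across sites, so site contrasts dominate species identity —
matching the observed absence of phylogenetic signal) multiply the
published site means to give unit targets; stem, plant and individual
values are lognormal around those targets; and the emitted raw records
invert the measurement equations exactly (flows from `K_s`, bubble
lengths from `P_R`, dry mass from density), so the flushed-implied
conductivity is ≥ the field-implied conductivity on every stem and
`noise_scale = 0` collapses the pipeline onto the configured site means
to floating tolerance.

Dispersion choices: the between-species CVs are set to roughly *half* the
dispersion implied by the published standard errors (capped at 0.4).
Taken literally, several published SEs (e.g. conductivity 1.1 ± 3.9,
growth 2.1 ± 2.09 at the cold site) imply species distributions with most
of their mass at negative values, which is impossible for these traits;
halving keeps species means strictly positive under a lognormal while
preserving the ordering and rough scale of between-species spread. The
within-unit CVs (stems 0.15, individuals 0.30, manometers 0.15, wood
samples 0.05, vessels-within-branch 0.35) are typical field-scale values
for these measurement types. Flow-measurement geometry (segment 0.2 m,
ΔP 0.005 MPa, stem diameter uniform 5–10 cm, 60% xylem fraction,
atmospheric bubble 3 cm) is not reported in the source protocol; these
values keep flows in realistic ranges and are config-overridable.
Hagen–Poiseuille proportionality between anatomy and conductivity holds
within a unit (stem-level factors), not across sites: the published
conductivity and vessel-diameter site means are measured quantities that
are not exactly r⁴-proportional, and the pipeline treats the trait
targets as authoritative.

What the generator does *not* emulate: frost-event time series, spatial
autocorrelation among individuals, within-site microclimate, true
phylogenetic structure in the trait offsets, or measurement drift.
Passing tests therefore certify the estimators and their calibration
under the assumed error model, not the field behaviour of real lianas.

The phylogeny generator produces random-coalescent ultrametric trees
(rescaled to a configurable depth) or a star tree; real genus-level trees
can be supplied as Newick. All randomness derives from one integer seed
through a fixed sub-stream order (species offsets, growth, stems,
vessels, manometers, wood, tree), so identical seed and config give a
byte-identical bundle.

## Problem sizes in routine runs

The test suite uses reduced per-unit effort (4 stems, 2 × 30 vessels, 3
manometers) where only structure matters, full design sizes where
calibration is measured: ANCOVA null calibration uses 1,000 replicates of
the 16-unit design; parameter recovery uses 100 full bundles; the DIC
simulation study uses 20 replicates per scenario at the `ci` MCMC
profile. Oracle checks (fourth-power sums, maximum CDF gap) run on
1,000 and 500 random vessel sets respectively.

## Known limitations

- The per-site species assignment is fixed by the package (the published
  per-site lists are not available); only the 7/5/4 counts and the
  10-species pool are authoritative.
- The asymptotic KS p-value convention (both effective n = vessel count)
  is one defensible choice among several; use the permutation option when
  the p-value itself matters.
- With n = 16 units the mixed-model variance components are
  prior-sensitive; DIC comparisons are meaningful, absolute DIC values
  are not comparable across data sets.
- The ANCOVA covariate is aliased with site in the reference design, so
  "temperature effect" and "site effect" are not separable at 3 sites;
  the package tests the site term and says so via the collinearity flag.
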