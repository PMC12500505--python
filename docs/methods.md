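# Methods

## The measurement model

A tracer incubation spikes one substrate pool (ammonium, or urea
expressed in N units = 2 × molar urea) with ¹⁵N-enriched substrate at
roughly 10 % of the ambient concentration. The label fraction of the
spiked pool,

    F = (C_amb·a_amb + C_tr·a_tr) / (C_amb + C_tr),

is treated as constant over the ≤ 12 h incubation; no substrate-pool
dilution correction is applied. Ambient pools default to natural ¹⁵N
abundance (0.003663 atom fraction, configurable), tracer spikes to 0.99.

**Nitrite production.** ¹⁵NO₂⁻ accumulates at `rate·F·t`. The rate is
the OLS slope of ¹⁵NO₂⁻ on time (converted h → d) divided by `F`. All
bottles enter the regression as independent observations; duplicate
bottles are *not* averaged per time point, because they are separate
incubations and averaging would discard degrees of freedom. A printed
formulation of this correction as a multiplication by `F` is
dimensionally inconsistent with tracer dilution; the division form is
standard ¹⁵N-tracer practice and is the default here (the multiply
variant exists behind a config flag purely for audit).

**N₂O production.** Both N atoms of product N₂O are drawn binomially
from the single labelled pool: `p44=(1−F)²`, `p45=2F(1−F)`, `p46=F²`.
No hybrid (mixed-source) N₂O formation is modelled. The ¹⁵N-atom excess
series `[45] + 2·[46]` therefore accumulates at `2·F·R`, so
`R = slope/(2F)` — an exact inversion for any `F` in (0, 1], verified to
1e-9 against the forward model and to < 1 % against a per-molecule
Monte-Carlo atom-labelling simulation. The regression uses atom excess
rather than summed 45+46 molecule counts; under the binomial model the
atom-excess inversion is exact, whereas molecule counting requires an
extra `(2−F)/2` factor.

**Detection limits.** `DL = t(1−α, df)·SE₀(slope)/(kF)` with `k = 1`
(nitrite) or `2` (N₂O atom excess), `SE₀ = σ/√Sxx` the null-slope
standard error of the design, one-sided `α = 0.05`. The t-quantile was
cross-checked against the simulated null distribution of the
studentized slope (10⁴ draws, within 10 %). When no instrument noise
estimate is supplied, the fit's own residual scale stands in for σ.
Negative fitted slopes are retained and flagged below detection rather
than truncated to zero: truncation would bias every downstream ratio.
Rate inversions with `F` below 0.01 are flagged (`low_label_fraction`)
because they amplify noise more than 100-fold.

## Derived statistics

N₂O yield is `100·a/(a+b)` with `a` the N₂O rate **on an N-atom basis**
(2 × nmol N₂O) and `b` the nitrite rate (nmol N); the molecule basis is
available by config since field reports rarely state which basis they
use. Standard errors propagate to first order. Rate ratios use the
quotient rule `σ_r = |r|·√((σ_a/a)²+(σ_b/b)²)`, validated against 10⁵
Monte-Carlo draws to within 5 % for relative errors ≤ 10 % (the
first-order formula degrades for noisier denominators, as expected).
Treatment comparisons are Welch t-tests on the slope-derived estimates
with Welch–Satterthwaite degrees of freedom from each slope fit;
percent change is always relative to the in-situ (untreated) estimate.

## Cross-site regression and outlier flagging

The substrate-ratio framework fits
`log10(urea_ox/nh4_ox) = m·log10(urea_N/nh4) + b` over compiled site
records. Records are ratio-eligible only when all four quantities are
positive and neither rate is below detection; ineligible records are
excluded, not substituted at ½·DL (substitution is a config choice the
default deliberately avoids). R² is reported as the squared Pearson
correlation of the log-transformed variables, which for OLS coincides
with the coefficient of determination to 1e-10.

The robust fit is Huber IRLS (tuning constant 1.345, 95 % Gaussian
efficiency) combined with iterated hard rejection: fit on kept points,
estimate the residual scale by the MAD of kept residuals, flag points
beyond `2·scale`, and repeat to convergence (≤ 10 iterations). Because
clipping at 2 SD truncates the residual distribution, the kept-subset
MAD systematically underestimates σ by a factor 0.951; the scale is
divided by this truncation factor each iteration. Without the
correction the false-flag rate on clean Gaussian data ratchets from the
nominal `2Φ(−2) ≈ 4.6 %` up to ~7 %; with it the measured rate is
≈ 5 %. Theil–Sen with a single-pass MAD scale is available as a config
alternative. p-values come from the t distribution of the OLS slope
and, for the robust fit, the asymptotic normal statistic of the final
IRLS slope.

## Gene-coverage ratios

Per-nucleotide mean gene coverage is normalised by library size
(million reads); no gene-length adjustment is needed because
per-nucleotide coverage is already length-free. Multiple hits of a gene
within a sample are summed before forming the AOA *ureC*:*amoA* ratio
(coverage sums approximate total gene copies; averaging is a config
alternative). A sample with *amoA* present but no *ureC* has a genuine
ratio of 0; a sample without *amoA* has a *missing* ratio and is
reported as such, never as 0 or ∞. The upstream bioinformatics
(assembly, annotation, taxonomy, read mapping) is outside this package:
its input boundary is the documented per-gene coverage table.

## The synthetic study

The generators encode the study conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| time_grid, replicates | 0/4/8/12 h × 2 | duplicate-bottle design |
| n2o_noise_sd | 0.33 nM | N₂O concentration precision |
| no2_noise_sd | 0.005 nmol N L⁻¹ | ¹⁵NO₂⁻ excess precision; chosen so the design's nitrite-rate DL ≈ 0.09 nmol N L⁻¹ d⁻¹ at F = 0.2 |
| F_targets | 0.20 (NH₄⁺), 0.12 (urea) | inside the observed 0.085–0.372 / 0.061–0.180 ranges, enforced |
| true_rates | 50/0.04 and 5/0.005 | nitrite and N₂O rates per substrate; true yields 0.16 % and 0.20 % |
| inhibition_factor | 0.4 | urea-oxidation multiplier under +2 µM ammonium (60 % decrease) |
| global slope/intercept | 1.113 / −0.97 | power-law coupling of rate ratio to substrate ratio |
| scatter_log10 | 0.3 | log10 scatter about the coupling law |
| outlier_fraction, polar_shift | 0.05, +1.0 | polar-regime sites one decade above the line |
| generatio slope/intercept | 0.083 / −0.018 | ureC:amoA vs substrate ratio, clamped at 0 |

Two isotopologue noise modes exist. The default applies the 0.33 nM
concentration precision to every isotopologue channel; under it the
N₂O-rate detection limit is of order 10 nmol L⁻¹ d⁻¹ and sub-nmol N₂O
production is structurally unmeasurable — that mode is appropriate for
testing calibration (CI coverage is noise-level-free) but not field
realism. The `ratio` mode applies 0.33 nM to the bulk (mass-44) channel
and a per-mil *relative* precision (default 1e-3) to the minor 45/46
channels, which is how an isotope-ratio MS actually performs; it yields
an N₂O-rate DL ≈ 2.5e-3 nmol L⁻¹ d⁻¹, consistent with published
sub-nmol detection limits, and median relative errors ≈ 2 % across
rates 0.001–1. Analyses that need measurable N₂O rates (yields, the
manipulation comparison) use ratio mode.

Habitat structure of the synthetic compilation: habitats
(estuary/coastal/open-ocean/OMZ, weights 0.20/0.25/0.35/0.10, plus a
configurable polar fraction) carry log10 substrate-ratio means
−0.6/−0.3/0.1/0.0 (polar −0.5) with within-habitat SD 0.25, and
ammonium medians 2/0.5/0.05/0.1 µM. These were chosen once so the
pooled log10-ratio SD (≈ 0.37) together with the 0.3 scatter reproduces
a field-like R² ≈ 0.66. A consequence is that the synthetic compilation
is *less* dispersed than real field compilations: the fraction of sites
preferring ammonium comes out near 99 %, higher than the ~78 % seen in
field data, and the generator makes no claim to reproduce that
statistic. Other simplifications: noise is Gaussian on concentrations;
F is time-invariant; no Michaelis–Menten kinetics, oxygen co-limitation,
N₂O consumption, or hybrid N₂O formation; the polar regime is an
intercept shift, not a mechanism; coverage sampling is Poisson around
abundance × depth with libraries 10–100 M reads. Passing tests
demonstrate the estimators are correct and calibrated under these
conditions — they do not validate the biogeochemical assumptions against
real oceans.

All generators are pure functions of (config, seed): one seed feeds
named integer substreams (`default_rng([seed, stream])`), so repeated
calls are bit-identical and the CLI `simulate` command is
byte-deterministic.

## Numerical and interface choices

Slope fits use closed-form OLS (scipy); with a degenerate
(zero-variance) predictor the log–log fit reports a flat line at the
mean rather than failing, while the linear gene-ratio fits treat it as
an error — constant substrate ratios are a meaningful edge case in the
first context and a data bug in the second. Table floats are written as
`%.17g` and parsed with the round-trip parser, so writer→reader is
lossless and seeded outputs are byte-stable. Units are embedded in
column headers (µM N vs µM, nM, rates per day) because unit slips are
the dominant failure mode when combining urea and ammonium data.

Problem sizes used by the analysis drivers and the acceptance script —
500-site compilations, 60-sample coverage tables, 500 replicates per
cell of the 5 × 4 rate-recovery grid, 10⁵-draw Monte-Carlo checks —
were chosen to keep every statistical check's sampling error well below
its acceptance margin.

## Known limitations

* Exact reproduction of published instrument detection limits is not
  attempted: those depend on unpublished replicate statistics; the DL
  machinery is exact for whatever noise estimate is supplied.
* The ¹⁷O isobaric contribution to mass 45 is not modelled.
* The compiled-dataset checks require the field compilation to be
  supplied locally (`data/compiled_global_sites.csv`); they are the
  only part of the suite that cannot run from synthetic data alone.
* First-order ratio error propagation understates uncertainty when the
  denominator's relative error exceeds ~20 %; below-detection flags on
  the ratio are the intended guard.
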