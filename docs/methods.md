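# Methods

This note records the modelling assumptions, default parameters and
numerical choices behind `vinespec`, and what the synthetic study can and
cannot demonstrate.

## Data model

A `SpectraSet` is a samples x bands reflectance matrix on a strictly
increasing wavelength grid in nm; the canonical instrument grid is
302–1148 nm at 2 nm bandwidth (424 bands), and all wavelengths are stored
as grid values. Band lookups resolve off-grid requests to the nearest
grid band, ties toward the lower wavelength, and always report the
resolved wavelength. Calibration divides raw counts by a white-reference
scan per band and clips to [0, 1] (a near-100% Spectralon reference can
produce ratios slightly above 1; the clip is deliberate). No smoothing or
derivative preprocessing is applied anywhere — indices operate on plain
calibrated reflectance. No band masking is applied at the grid extremes
either; several canonical indices use bands at 434–448 nm and
1140–1148 nm, so masking would silently redefine them.

A `TraitTable` carries An (mg L⁻¹), TSS (%), TA (%) and the maturation
index TSS/TA, computed per sample as TSS ÷ TA; TA must be strictly
positive.

## Index forms and their symmetries

The two-band ratio R_a/R_b is *not* symmetric for regression purposes:
the map x → 1/x is nonlinear, so the OLS R² of a trait on R_a/R_b and on
R_b/R_a differ. The search therefore enumerates ordered pairs for RSI2.
The two-band normalized difference flips sign under a band swap, leaving
R² unchanged, so NDI2 is searched over unordered pairs. The three-band
form (R_a − R_b − R_c)/(R_a + R_b + R_c) is symmetric in b and c
(b = c allowed — several canonical indices repeat a band), so triplets
are enumerated as (a; {b, c}) with b ≤ c.

Zero denominators yield NaN for that sample, propagated as missing and
deleted pairwise in downstream regressions — never imputed, never
silently zero.

The default registry's four report-table alias spellings
(`RSI_668,442`, `RSI_680,1140`, `R_822,750,552`, `R_1144,684,562`) map
onto the canonical definitions (`RSI_668,448`, `RSI_684,1140`,
`NDI_822,750,552`, `NDI_1144,684,562`); the definitional table governs.

## Band search

For each candidate combination the trait is regressed on the index by
simple OLS and R² = r² recorded. The vectorized search computes
column-wise correlations with pairwise deletion; cells with fewer than 3
valid pairs or (numerically) zero variance are flagged NaN (the a = b
diagonal is always degenerate: constant 1 for ratios, constant 0 for
normalized differences). The scalar path (`fit_simple_regression`)
returns R² = 0 with a `degenerate` flag instead, so callers that need a
number get one; equality of the two paths on the non-degenerate cells is
oracle-tested against naive loops.

The three-band search caps the triplet count (default budget 4x10⁷;
exceeded budgets raise with advice to coarsen the stride) and retains a
top-k list rather than the full tensor. Default stride is 4 nm, which on
the 424-band grid keeps the exhaustive triplet pass in desk-scale
minutes; exhaustive 2 nm runs are permitted under the budget. Global
ranking across forms breaks R² ties toward fewer bands, then
lexicographically smaller wavelengths — simpler indices win ties.

## Group statistics

Group descriptives use the n−1 SD. Mean separation is one-way ANOVA plus
Tukey's HSD at α = 0.05 (Tukey–Kramer when group sizes differ), rendered
as a compact letter display via the insert-absorb algorithm: groups
sharing no letter differ significantly. Report tables star significance
at p ≤ 0.05 / 0.01 / 0.001 and mark the rest `ns`.

Percent differences between group means are reported relative to the
first-named (larger) group, rounded to one decimal:
100 (m_ref − m_other)/m_ref.

## Regression models

Metrics: RMSE = √(Σ(y − ŷ)²/N) and R² = 1 − RSS/TSS, computed once on
the pooled out-of-fold prediction vector (a per-fold R² is undefined for
single-sample folds). R² may be negative for models worse than the mean.

Hyperparameter grids are fixed and enumerated exhaustively, winner =
minimum LOOCV RMSE:

| model | grid | fixed settings |
|---|---|---|
| GBR | stages Ns ∈ {5, 10, 15, 20, 25}; features/split Mf ∈ {all, sqrt, log2} | learning rate 0.1, squared-error loss, tree depth 3 |
| DT | depth Md ∈ {1, 3, 5, 7, 9}; min leaf Ms ∈ {2, 4, 6, 8, 10}; max leaves Mln ∈ {∞, 10, 20, 30, 40, 50} | ccp_alpha = 10⁻⁶ |

"all" features per split is the historical meaning of the `auto` option
for regression ensembles. The GBR fixed settings are conventional
defaults, made explicit and overridable in `GBRSpec`. Ties break toward
the simpler model: smaller Ns; smaller Md, larger Ms, smaller Mln (with
unbounded counting as largest). Tuning exploits boosting's sequential
structure: one fit per fold at the largest stage count yields every
smaller count via staged prediction — exact, and verified against
per-spec refits in the tests.

Hyperparameters are tuned by the same LOOCV that reports performance;
with no held-out set this is mildly optimistic, and the train-vs-CV gap
in the reports is the visible symptom. Hybrid-index fusion is greedy
forward selection with re-tuning at every candidate evaluation, stopping
at no improvement or a size cap; ties break by candidate order. The
report-table feature sets for each model x trait ship as named presets so
those configurations can be re-run verbatim. Random forests, PLSR and
deep models are out of scope.

## Synthetic study generator

The generator's defaults are the study conditions: three maturity groups
(LM/SM/FM, 35 samples each) whose An/TSS/TA follow truncated normal
distributions with the published per-group min/max/mean/SD. Truncation
shifts a normal's mean, so the location parameter is solved numerically
(bracketed root-find) so that the *truncated* mean equals the configured
mean; sample means then recover the targets within Monte-Carlo error. The
truncated normal is the simplest family consistent with all four printed
statistics. Trait–trait correlation is induced by the group structure
only — no within-group copula is imposed, because only pooled
correlations are documented for the study; the pooled sign pattern
(An–TSS positive, TA negative against the rest) emerges from the group
differences and is asserted in tests.

Spectra are rendered as baseline(λ) − Σ_f depth_f · exp(−(λ−c_f)²/2w_f²)
+ ε, clipped to [0, 1], with a logistic baseline rising from 0.10 in the
blue to a 0.55 NIR plateau (midpoint 700 nm, scale 80 nm) and features:

| center | width (σ) | driver | coefficient |
|---|---|---|---|
| 520 nm | 40 nm | An | 1.2x10⁻⁴ per mg L⁻¹ |
| 675 nm | 25 nm | TA | 0.20 per % |
| 970 nm | 50 nm | TSS | 0.012 per % |

Centers follow the absorption physiology (anthocyanin ~520 nm; the
chlorophyll-like red feature tracks acidity because unripe, high-TA fruit
is greener; a water/sugar feature in the NIR). Coefficients are sized so
the deepest dip stays clear of the zero clip (max An ≈ 1039 mg L⁻¹ gives
depth ≈ 0.125 against a ≈ 0.14 baseline at 520 nm); clipping would
destroy the linear trait–reflectance link the analysis assumes. Band
noise is i.i.d. Gaussian, sd 0.005 reflectance — small relative to the
planted signal ranges. One integer seed drives both trait sampling and
band noise (the noise stream is derived from it by a fixed offset).

What the generator does *not* emulate: radiative-transfer realism
(PROSPECT-style optics), wavelength-dependent instrument noise,
within-group biochemical covariance, scattering/specular effects, and
sun-angle variation. Consequently, passing tests demonstrate that the
algorithms recover structure that is present by construction — band
locations, planted predictability, group separation — not that the field
R² values themselves are reproducible; those depend on undeposited field
data.

Because every band inside a feature's support carries nearly the same
linear signal, the argmax of the correlogram wanders a few nm around the
planted center from seed to seed (noise breaks near-ties); recovery
checks therefore run at a fixed seed and assert proximity (±10 nm), not
identity.

## Pipeline

Stages (data → stats → indices → band search → models) each write plain
CSV/JSON before the next begins, so any stage can be re-run in isolation;
a manifest records the config snapshot, version, timestamps and file
list. Defaults are desk-scale: NDI2 correlograms at 8 nm stride for all
four traits, both model kinds on the full 30-index registry. With a fixed
seed two runs produce byte-identical stage outputs (timestamps live only
in the manifest and log). Float formatting in CSVs is fixed at %.10g to
make that byte-identity well-defined.
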