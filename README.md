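# vinespec

Spectral-index optimization and machine-learning regression for
non-destructive grape ripeness assessment from VIS/NIR reflectance.

## The problem

Table-grape harvest timing is judged from biochemical ripening indicators —
anthocyanin concentration in the berry skin (An, mg L⁻¹), total soluble
solids of the juice (TSS, % Brix), titratable acidity (TA, % tartaric
acid) and the maturation index TSS/TA. Measuring them by wet chemistry is
destructive and slow. Because ripening changes pigments and water/sugar
content, it also changes the fruit's reflectance spectrum: anthocyanin
absorbs near 520 nm, chlorophyll near 670–680 nm, water near 970 nm. A
portable VIS/NIR spectrometer (302–1148 nm at 2 nm bandwidth here) can
therefore proxy the chemistry.

`vinespec` implements the full indirect-assessment pipeline for
researchers in fruit phenotyping / chemometrics:

- **Spectral reflectance indices (SRIs).** Two-band ratio indices
  RSI(a,b) = R_a / R_b, two-band normalized differences
  NDI(a,b) = (R_a − R_b)/(R_a + R_b), three-band normalized differences
  NDI(a,b,c) = (R_a − R_b − R_c)/(R_a + R_b + R_c), plus the classic
  published NDVI, NAI, GI and PRMI. A canonical 30-index registry
  (4 published + 12 two-band + 14 three-band) ships as the default
  working set.
- **Exhaustive band optimization.** For every band pair (or triplet) on a
  strided grid, the trait is regressed on the index by OLS and the R²
  recorded — the 2-D/3-D "correlogram maps" used to pick optimal
  wavelengths. Searches respect the forms' exact symmetries (ordered
  pairs for ratios, unordered for normalized differences, b ≤ c for the
  three-band form).
- **Group statistics.** Per-maturity-group descriptives, one-way ANOVA
  with Tukey HSD compact letter displays at α = 0.05, Pearson correlation
  matrices per group and pooled, and percent-difference contrasts between
  group means.
- **ML regression with LOOCV.** Decision-tree and gradient-boosting
  regression of each indicator on SRI features, with exhaustive
  hyperparameter grids ranked by leave-one-out RMSE (R² = 1 − RSS/TSS and
  RMSE = √(Σ(y − ŷ)²/N) computed on pooled out-of-fold predictions), and
  greedy forward "hybrid-SRI" feature fusion.
- **Synthetic study generator.** The field study's data are not deposited,
  so a generator reproduces its statistical structure: three maturity
  groups (less/semi/fully mature, 35 clusters each) with truncated-normal
  trait distributions matching the published group min/max/mean/SD, and
  spectra rendered as a smooth continuum minus trait-driven Gaussian
  absorption features plus band noise. Every stage of the pipeline runs
  on it end-to-end with no download.

## Worked example

```python
import vinespec as vs

ds = vs.make_dataset(seed=1)                      # 105 samples x 424 bands
res = vs.BandSearch(ds.spectra, ds.traits, "An", stride=4).fit()
print(res.summary(3).to_string(index=False))
```

```
       index form wavelengths       r2        slope   intercept       pvalue
RSI_510,1114 RSI2    510,1114 0.983753 -4539.400355 1168.539633 5.659647e-94
 RSI_510,834 RSI2     510,834 0.983644 -3970.496076 1171.036316 7.977083e-94
 RSI_510,802 RSI2     510,802 0.983398 -3763.354543 1167.695055 1.722816e-93
```

The best two-band ratio pairs a band at 510 nm — inside the planted
anthocyanin absorption feature centred at 520 nm — with a flat NIR
reference band, and explains 98% of the anthocyanin variance in this
noise regime; the negative slope says more anthocyanin means a deeper
visible absorption dip.

Group statistics with Tukey letters (groups sharing no letter differ at
α = 0.05 — anthocyanin rises sharply with maturity):

```python
gs = vs.describe_groups(ds.traits)
print(gs.table[gs.table.trait == "An"].to_string(index=False))
```

```
group trait  n        min         max       mean         sd letter
   LM    An 35  21.715010  285.052284 131.086025  69.738275      a
   SM    An 35 147.243687  460.350613 230.126752  69.815874      b
   FM    An 35 385.683243 1008.830539 730.595863 183.056448      c
```

A gradient-boosting model of TSS on three registry indices, tuned and
scored by LOOCV:

```python
fm = vs.evaluate_registry(ds.spectra, vs.default_registry())
model = vs.SRIRegression(fm, ds.traits["TSS"], kind="gbr", trait="TSS", seed=1)
result = model.fit(features=["RSI_540,950", "GI", "NDI_822,750,552"])
print(result.summary().to_string(index=False))
```

```
Variable                Proposed features Optimal parameters Train R2  Train RMSE   CV R2  CV RMSE
     TSS RSI_540,950, GI, NDI_822,750,552         (25, sqrt)  0.85***        0.89 0.65***     1.34
```

Train R² = 0.85 against cross-validated R² = 0.65 quantifies the optimism
of the training fit; the winning hyperparameters (25 boosting stages,
sqrt feature subsampling) minimized LOOCV RMSE over the full grid.

The same workflow is available from the shell:

```bash
vinespec run-all --seed 1 --out run1        # simulate -> stats -> indices
                                            # -> band search -> models -> report
vinespec correlogram --trait An --form ndi3 --stride 8 --top-k 20
vinespec train --trait TSS --model gbr --features select --max-subset 5
```

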