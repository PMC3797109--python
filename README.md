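# carryover

Tools for quantifying **mass-dependent carry-over effects** in migratory
capital breeders, built around a six-year study of female light-bellied
Brent geese (*Branta bernicla hrota*): birds fatten on Icelandic spring
staging grounds, migrate to the Canadian High Arctic, and return the
following winter with (or without) juveniles. The question the pipeline
answers is whether heavier pre-migration birds rear more offspring, and
whether that advantage depends on breeding-season weather.

The package is aimed at population ecologists who want the full analysis
chain as tested, reusable code: because the original field data are not
deposited, a first-class synthetic-data generator reproduces the assumed
statistical structure so that every stage can be exercised and validated by
parameter recovery.

## The model

For female *i* measured in year *t*, the offspring count the following
winter is modelled as

```
y_it ~ Poisson(λ_it)
log λ_it = β0 + β1·mass_it + β2·nao_t + β3·mass²_it + β4·mass²_it·nao_t + u_t
u_t ~ N(0, σ²_u)
```

where `mass` is the z-scored, seasonally corrected **scaled mass index**
(SMI = M·(L0/L)^b, with the SMA exponent b the ratio of the log–log OLS
slope to the Pearson correlation), `nao` is the z-scored residual of June
NAO after removing a quadratic trend in year, and `u_t` is a year random
intercept. Eight candidate fixed-effect structures (Mass, NAO, Mass + NAO,
Mass × NAO, Mass², Mass² + NAO, Mass² × NAO, Null) are fitted by maximum
likelihood (Laplace approximation), ranked by AICc, pruned with the nesting
rule, and model-averaged. Two Bayesian layers follow: an MCMC refit of the
top model for posterior prediction bands, and a bivariate Gaussian/Poisson
latent trait model whose posterior residual correlation between raw mass
and offspring count is the carry-over statistic.

## Worked example

```python
import carryover as co

cfg = co.SimConfig(seed=101)            # 6 years, 216 birds, study-scale defaults
ds = co.generate_dataset(cfg)
rs = co.generate_resightings(ds, cfg)
prep = co.preprocess_dataset(ds.birds, ds.nao, rs,
                             sma_slope=3.4, reference_length_mm=89.6)
fits = co.fit_candidate_set(prep.data)
table = co.apply_nesting_rule(co.rank_and_weight(fits, n=len(prep.data)))
print(table)
```

prints

```
        name  k      loglik  aicc  delta  weight  in_delta6  retained
Mass^2 * NAO  6 -253.577235 519.6   0.00   0.930       True      True
         NAO  3 -259.839982 525.8   6.22   0.041      False     False
  Mass + NAO  4 -259.838898 527.9   8.30   0.015      False     False
Mass^2 + NAO  5 -259.435361 529.2   9.59   0.008      False     False
  Mass * NAO  5 -259.666751 529.6  10.06   0.006      False     False
        Null  2 -269.286378 542.6  23.05   0.000      False     False
        Mass  3 -269.278716 544.7  25.10   0.000      False     False
      Mass^2  4 -268.978561 546.2  26.58   0.000      False     False
```

The generating model (a quadratic mass × NAO interaction on the log scale)
is recovered as the only retained model with weight 0.93: heavy birds do
best, but only in years with negative June NAO (favourable Arctic weather).
`co.model_average(table)` then gives the averaged coefficients — here the
NAO main effect is −0.67 and the mass² × NAO interaction −0.23, close to
the generating values −0.58 and −0.27 — and
`co.marginal_r2(table.retained[0], prep.data)` reports the fixed-effect
(marginal) R², 0.585 in this run.

The same chain is available from a shell:

```
carryover simulate --seed 101 --out run/
carryover preprocess --birds run/birds.csv --nao run/nao.csv \
    --resightings run/resightings.csv --out run/preprocessed.csv
carryover fit --data run/preprocessed.csv --models all --out run/fits.json
carryover select --fits run/fits.json --data run/preprocessed.csv --out run/selection.json
carryover run-all --seed 101 --out run/     # everything above plus the Bayesian layer
```

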