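# segjoint

Joint segregation analysis (JSA) of six-generation crosses under
major-gene plus polygene mixed inheritance models.

Plant quantitative geneticists use JSA to ask, before any genotyping,
*how* a quantitative trait is inherited: is it driven by one or two
individually resolvable "major" genes, by a diffuse polygenic
background, or by a mixture of both?  The design is the classical
six-generation family of a biparental cross — the parents P1 and P2,
their hybrid F1, the selfed F2, and the two first backcrosses BC1P1
(F1 × P1) and BC1P2 (F1 × P2).  `segjoint` implements the full
workflow for per-individual phenotype data from such a design
(developed around vitamin-C content in rapeseed seedlings, mg/100 g
fresh weight, but trait-agnostic): descriptive summaries, joint
maximum-likelihood fitting of 24 catalogued genetic models, AIC
ranking, suitability (goodness-of-fit) testing, and estimation of
genetic effects, variance components and heritabilities.

## The model

Under a mixed inheritance model, generation *g* is a finite normal
mixture

```
f_g(x) = Σ_c  π_gc · N(x; μ_gc, v_g)
```

* **Components** are major-locus genotype classes with Mendelian
  weights π (per locus: F2 1:2:1, BC1P1 1 AA : 1 Aa, BC1P2
  1 Aa : 1 aa; loci unlinked).  P1, P2 and F1 always have one
  component.
* **Component means** are linear in the genetic effects: the overall
  mean *m*, additive (*d_a*, *d_b*) and dominance (*h_a*, *h_b*)
  effects of up to two major genes, optional digenic epistasis
  (*i*, *j_ab*, *j_ba*, *l*), and collective polygene shifts — +[d]
  in P1, −[d] in P2, +[h] in F1, ½[h] in F2, ½([d]+[h]) in BC1P1,
  ½([h]−[d]) in BC1P2.
* **Variances**: one environmental variance σ²_e (the within-component
  variance of P1/P2/F1) plus, in models with a polygene part, a free
  polygenic variance σ²_pg(g) for each segregating generation, so
  v_g = σ²_e + σ²_pg(g).

Each of the 24 model codes (1MG-A … MX2-ADI-ADI) is a constraint set
applied to one generative rule; the registry can be exported to JSON
(`segjoint.registry_to_json`) for audit.  Fitting maximizes the joint
likelihood over all six generations by multi-start EM with closed-form
conditional maximization steps; models are compared by
AIC = −2 lnL + 2k.  The two lowest-AIC models advance to suitability
tests — three moment-based uniformity statistics U1², U2², U3²
(χ²(1)), the Cramér–von Mises nW² and the Kolmogorov Dn, applied to
the probability-integral transform of each generation through its
fitted mixture — and the winner is the candidate with the fewest
significant statistics, ties broken by fewer parameters, then by AIC.

Second-order parameters decompose each segregating generation's sample
phenotypic variance as σ²_p = σ²_e + σ²_mg + σ²_pg (major-gene variance
by subtraction, floored at zero) and report heritabilities
h²_mg = σ²_mg/σ²_p, h²_pg = σ²_pg/σ²_p as percentages.

## Worked example

The package bundles generative presets for two published rapeseed
vitamin-C crosses ("A" and "B": two additive major genes plus
additive–dominance polygenes, published effect sizes and sample
sizes).  Simulate cross A, refit the generating model, and report its
genetic parameters:

```python
import segjoint as sj
from segjoint.genpar import second_order_table

dataset = sj.simulate(sj.cross_config("A", seed=7))
fit = sj.fit(dataset, "MX2-A-AD", sj.FitConfig(n_starts=5, seed=0))

print(f"model {fit.model_name}: lnL {fit.loglik:.2f}, AIC {fit.aic:.2f}")
for name, value in zip(fit.param_names, fit.theta):
    print(f"  {name:<7} = {value:8.2f}")
print(f"  sigma2_e = {fit.sigma2_e:.2f}")

vc = sj.second_order(fit, dataset)
print(second_order_table(vc).to_string(index=False))
```

prints

```
model MX2-A-AD: lnL -2523.38, AIC 5064.75
  m       =   108.15
  d_a     =    20.88
  d_b     =    -1.41
  poly_d  =    14.77
  poly_h  =    -1.60
  sigma2_e = 77.92
generation  sigma2_p  sigma2_e  sigma2_mg  sigma2_pg  h2_mg_percent  h2_pg_percent  h2_total_percent  env_fraction_percent
        F2    315.83     77.92     227.82      10.09          72.13           3.19             75.33                 24.67
     BC1P1    363.48     77.92     113.01     172.56          31.09          47.47             78.56                 21.44
     BC1P2    239.45     77.92     112.98      48.54          47.19          20.27             67.46                 32.54
```

The leading additive effect d_a ≈ 20.9 recovers the generating value
22.43 to within sampling error; the small second-gene effect is only
weakly identified at these sample sizes (see `docs/methods.md`).  The
F2 row says ~72% of F2 phenotypic variance is attributable to the two
major genes and ~25% to environment.  `examples/` contains one short
script per capability (summaries, model ranking, suitability tests,
genetic parameters, full pipeline).

## Command line

A thin CLI wraps the same workflow:

```sh
segjoint simulate --preset A --seed 42 --out sim.csv
segjoint summarize --input sim.csv
segjoint analyze --input sim.csv --out report/ --seed 1
```

`analyze` writes CSV tables (summary, model ranking, suitability
tests, first/second-order parameters), a `fits.json` with full fit
metadata, and a human-readable `report.txt`.  Input CSV needs columns
`generation,value` (optionally `cross`); `--sep '\t'` reads TSV.

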