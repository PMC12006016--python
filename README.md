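# trajgex

Longitudinal gene-expression trajectory analysis for repeated-measures
cohorts: which genes change with age, what shapes those changes take, how
much variance each covariate explains, and which gene categories are
enriched among the changing genes.

The motivating design is early-childhood immune profiling: PBMC expression
measured every 3 months from age 3 to 36 months in a birth cohort, with
heavy visit missingness. Age-related expression changes in this window are
of particular interest for type 1 diabetes, whose islet-autoimmunity
incidence peaks around one year of age — genes with U-shaped or late-rising
trajectories mirror those clinical curves. The package is aimed at
statistical genomicists analyzing such dense longitudinal designs, and at
methodologists who want a fully simulated, ground-truthed test bed for
spline-based temporal differential expression.

## The model

Per gene *g*, log2 expression of subject *i* at sample *s* is

    y_gis = beta_0 + f_g(age_is) + gamma_sex + gamma_season + b_gi + e_gis

with `f_g` a natural cubic spline in age (3 df, boundary knots at the
observed age range, interior knots at age terciles), a subject random
intercept `b_gi` handled as a consensus compound-symmetry correlation rho
followed by per-gene GLS, and empirical-Bayes moderation of the residual
variances (scaled inverse chi-square prior `(d0, s0^2)` fitted by moment
matching on `log s_g^2`). Temporal change is tested with a moderated F on
the three spline coefficients, `F(3, d0 + d_g)`; a gene is called
differentially expressed when its BH-adjusted p < 0.05 **and** the
peak-to-trough fold change of its fitted trajectory is >= 1.10.

Flagged genes are clustered on the Kendall distance `1 - tau` between
Z-scored fitted trajectories (average linkage, cut at k = 24) and each
cluster is assigned one of six shape archetypes — decreasing, U-shaped,
increasing, inverted-U, stable, late rise — by a deterministic rule
cascade. Variance partitioning fits per-gene variance-components models
(REML via Henderson's mixed-model equations) for individual, season, sex
and HLA genotype plus the fixed age spline. Enrichment uses two-sided
Fisher exact tests with sample and conditional-MLE odds ratios, genomic
region filters (1-based inclusive coordinates), and upper-tail
hypergeometric over-representation for GMT gene sets.

See `docs/methods.md` for assumptions, estimators and numerical choices.

## Worked example

```python
import trajgex as tg

# 40 subjects scheduled every 3 months from 3 to 36 months, 50% visit
# retention, 2000 genes of which 10% carry a planted trajectory shape
sim = tg.simulate_dataset(tg.SimulationConfig(seed=1))

res = tg.run_de(sim.expression, sim.samples)
print(f"rho={res.rho:.3f}  n_de={res.table.de_flag.sum()}")

assign = tg.cluster_trajectories(res.trajectories.loc[res.de_genes], k=24)
print(assign.labels["archetype"].value_counts().to_string())
```

prints

```
rho=0.496  n_de=171
INCREASING    44
DECREASING    35
INVERTED_U    35
U             34
LATE_RISE     23
```

The consensus within-subject correlation (0.496) recovers the simulated
intraclass correlation of 0.5; 171 genes are flagged, close to the 167
genes planted with a dynamic shape at amplitude 1 log2 (the planted
"stable" shapes are flat and correctly not flagged), and the archetype
labels recover the planted shapes. Enrichment of a gene category among
the flagged genes:

```python
t1d = set(sim.annotation.index[sim.annotation.is_t1d])
r = tg.fisher_exact_2x2(
    tg.build_contingency(set(res.de_genes), t1d, set(sim.expression.index))
)
print(f"OR={r.odds_ratio:.2f} CI=({r.ci_low:.2f}, {r.ci_high:.2f}) p={r.p:.3g}")
```

```
OR=1.90 CI=(0.55, 6.56) p=0.241
```

— with only 20 category genes in this small simulation the interval is
wide; the category flags are drawn independently of the planted dynamics,
so no real enrichment exists.

The same stages are available from the shell:

```bash
trajgex simulate --outdir run/ --seed 1
trajgex de --expr run/expression.tsv --samples run/samples.tsv --out run/de.tsv
trajgex cluster --trajectories run/de.tsv --k 24 --out run/clusters.tsv
trajgex run-all --outdir run/ --seed 1      # full pipeline + manifest.json
```

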