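# wolbiome

Statistical machinery for asking how a spreading, maternally inherited
endosymbiont (*Wolbachia*) restructures the bacterial communities of its
insect host — built for 16S OTU count tables from multi-population
surveys of the small brown planthopper type, and driven by a synthetic
community generator so the full pipeline runs and is testable without
any sequencing download.

It is aimed at microbial ecologists who have (or want to emulate) three
inputs: an OTU table (samples × OTUs with genus-level taxonomy), sample
metadata (population, latitude/longitude, annual mean temperature Bio1,
annual precipitation Bio12, infection status), and a pairwise
mitochondrial F<sub>ST</sub> matrix.

## What it computes

**Heavy-tail abundance characterization.** OTU abundances x above a
threshold x′ are modeled with a power-law density p(x) = a·x^(−ε),
fitted by continuous maximum likelihood, ε̂ = 1 + n / Σ ln(x_i/x′),
with x′ chosen by minimizing the Kolmogorov–Smirnov distance between the
empirical and fitted tail CCDFs. The exceedance function
P(X ≥ x) = (x/x′)^(1−ε) summarizes each population's community, and ε is
classified by its moment implications (ε ≤ 2: mean and variance
infinite; 2 < ε < 3: mean finite, variance infinite; ε ≥ 3: both
finite). Pairwise community structure is then distilled into a
symmetrized Kullback–Leibler divergence
J(p,q) = ½[D(p‖q) + D(q‖p)], D(p‖q) = Σ p ln(p/q), between
histogram densities of pooled population abundances on shared log bins.

**Standard community statistics around it.** Rarefaction (single
multivariate-hypergeometric draw to the shallowest sample), genus
aggregation with "others" pooling, alpha diversity in the mothur/QIIME
conventions (Sobs, natural-log Shannon, finite-sample Simpson
*dominance* Σn(n−1)/(N(N−1)), ACE, bias-corrected Chao1, Good's
coverage), Bray–Curtis distances, PCoA with negative-eigenvalue
reporting, one-way PERMANOVA, Spearman Mantel tests, a distance-based
recursive path model (geography/climate → F<sub>ST</sub> → community
distance, all variables as lower-triangle vectorizations of matched
population-level matrices), and the infected-vs-uninfected battery
(Welch t on diversity, exact/tie-corrected Mann–Whitney per genus,
symbiont-exclusion re-rarefaction).

Mantel and PERMANOVA both provide exhaustive-enumeration modes on small
designs, where the permutation p-value is exact.

## Worked example

```python
import wolbiome as w
from wolbiome.datasets import sap_alpha_diversity

# published per-individual diversity for the one infection-polymorphic
# population: 10 infected (w+) vs 9 uninfected (w-) females
df = sap_alpha_diversity()
inf, uninf = df[df["infected"]], df[~df["infected"]]
for col in ("shannon", "simpson"):
    r = w.welch_t(inf[col], uninf[col], unit=col)
    print(f"{col}: t = {r.statistic:+.2f}, p = {r.p:.2e} {r.stars}")
```

prints

```
shannon: t = -6.51, p = 8.59e-05 ***
simpson: t = +8.46, p = 2.21e-07 ***
```

— infected individuals have far lower Shannon diversity and far higher
Simpson dominance: the symbiont's read share collapses community
evenness. On synthetic data the same machinery recovers the collapse as
a near-perfect rank correlation:

```python
table, meta = w.simulate_dominance_gradient(n_samples=60, max_prop=0.95, seed=17)
alpha = w.alpha_diversity_table(table)
print(w.diversity_vs_proportion(alpha[["shannon", "simpson"]],
                                meta["symbiont_prop_true"]))
```

```
                r              p
shannon -1.000000   0.000000e+00
simpson  0.999944  2.230970e-116
```

## The analysis chain

`analysis/01_simulate_survey.py` … `06_infection_comparison.py` run the
full narrative on a synthetic 17-population survey (51 samples, 314
taxa, 34135 reads/sample): simulate → rarefy/alpha → Bray–Curtis, PCoA,
PERMANOVA → power-law fits and the KL matrix → Mantel battery and path
model → infection comparisons. Small summary tables land in `results/`;
bulky regenerable intermediates (the simulated tables, distance
matrices, exceedance curves) in `scratch/`. The same stages are
available as a CLI (`wolbiome simulate|rarefy|alpha|beta|pcoa|permanova|
powerlaw|kl|mantel|pathmodel|compare-groups|run`) and as a single
config-driven pipeline (`wolbiome run --config cfg.yaml`) that writes a
manifest with parameters, seeds and output hashes.

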