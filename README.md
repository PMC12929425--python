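# plonet

Ploidy-aware structural analysis of plant–pollinator interaction networks.

Whole-genome duplication (polyploidy) is ubiquitous in flowering plants and
reshapes floral traits, mating systems and ecological niches. `plonet` asks
the community-level question: **do plant–pollinator networks with more
polyploid plant species look structurally different?** It provides a tested
pipeline for relating the per-network frequency of polyploids (%PP) — along
with the frequencies of self-compatible (%SC) and restrictive-flowered
(%Restrictive) plants and bioclimatic context — to four structural indices
of weighted bipartite networks, and for asking whether trait composition
mediates those relationships.

## What it computes

For each plant × pollinator visit-count matrix:

- **Connectance** — realized links / possible links (on presence/absence).
- **Nestedness** — weighted NODF: for row (and column) pairs with strictly
  decreasing marginal totals, the share of the poorer member's positive
  cells strictly exceeded by the richer member's, in [0, 100].
- **Modularity** — Barber's bipartite
  `Q = (1/m) Σ_ij (w_ij − r_i c_j / m) δ(g_i, g_j)`, maximized by seeded
  weighted label propagation with agglomerative merging (exact exhaustive
  search available for small networks).
- **Robustness** — area under the extinction curve: plants are removed
  sequentially (random or ploidy-targeted order) and a pollinator goes
  secondarily extinct when it loses its last partner.

Each index is **delta-standardized**: `Δindex = raw − mean(null)`, with
nulls drawn by Patefield's fixed-marginal contingency-table algorithm, so
structure is measured beyond what network size and marginal totals imply.

Trait frequencies are computed over the species with *known* state only, and
networks enter the analysis cohort when they have ≥ 6 pollinator taxa, ≥ 6
ploidy-classified plants, ploidy coverage ≥ 1/3, and climate data.

Downstream statistics: univariate OLS of each Δindex on each predictor
(reporting Pearson r, the t statistic `t = r√(n−2)/√(1−r²)` and its p),
Moran's I on residuals for spatial autocorrelation, and a **piecewise
structural-equation model**

```
%PP ~ B15          %SC ~ %PP + B15         %Restrictive ~ %PP + B15
NS  ~ B15          Δindex ~ %PP + %SC + %Restrictive + B15 + NS
```

(B15 = log precipitation seasonality, NS = log network size), with model
adequacy via d-separation (Fisher's `C = −2Σ ln p`, chi-square with 2k df)
and decomposition of the %PP effect into direct and mediator paths (each
indirect path is the product of its standardized coefficients; the total is
the sum).

A synthetic-community generator (Gaussian niche-overlap kernel with Poisson
visit counts, ploidy-dependent niche breadth κ, trait–ploidy covariation,
climate effects and realistic missing-trait masking) provides complete
studies with known ground truth, so every stage is testable end to end.

## Worked example

```python
import plonet

cfg = plonet.SyntheticConfig(n_networks=40, seed=7)          # kappa = 3: broad polyploid niche
networks, traits, covariates, truth = plonet.generate_study(cfg)

bundle = plonet.analyze_study(networks, traits, covariates,
                              plonet.RunConfig(n_null=25, seed=1))
row = bundle.regressions.query("predictor=='pct_pp' and response=='delta_nestedness'")
print(row[["r", "t", "p", "n"]].to_string(index=False))
fit = bundle.sem_fits["nestedness"]
eff = plonet.decompose_effects(fit)
print(f"direct={eff.direct:.3f} total={eff.total:.3f} adequacy_p={fit.adequacy_p:.3f}")
```

prints (seeds fixed as above):

```
       r        t        p  n
0.277596 1.781223 0.082871 40
direct=0.150 total=0.229 adequacy_p=0.201
```

i.e. in this broad-niche scenario polyploid-rich communities trend toward
higher nestedness (r = 0.28 over a small 40-network study, p = 0.08 — at the
~300-network scale of a real cohort the same effect size is decisive), part
of the total effect flows through the trait mediators, and the
non-significant adequacy p says the five-equation diagram is consistent with
the simulated data.

The same stages are available as a CLI:
`plonet simulate | filter | metrics | nulls | robustness | regress | sem | run-all`.

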