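# metacommunity

Metacommunity structure analysis for ecosystems organised along strong
environmental gradients — built for benthic macroinfauna surveys along
estuarine salinity gradients, applicable to any site-by-taxon data with
replicated sampling in space and time.

Community composition can change along a gradient in qualitatively
different ways: species-poor sites may be subsets of species-rich ones
(nested subsets), species may replace each other individualistically
(Gleasonian) or in blocks (Clementsian), ranges may be spaced more evenly
than chance, pairs may exclude each other (checkerboards), or there may be
no structure at all. This package identifies which idealized structure a
metacommunity fits, and then quantifies how much of the compositional
variation is driven by environmental filters, by space, and by time.

## What it computes

**Elements of metacommunity structure (EMS).** The incidence matrix is
ordered by its first correspondence-analysis axis, then three hierarchical
metrics are tested against null models:

* *coherence* — embedded absences (interruptions inside species ranges and
  site compositions) vs. a fixed-row, proportional-column (r1) null with
  every simulated matrix independently re-ordinated;
* *turnover* — species replacements between site pairs on the range-filled
  matrix vs. a null that shifts entire ranges to random positions;
* *boundary clumping* — Morisita's index
  `I = n Σ f_i(f_i − 1) / (F(F − 1))` over range-endpoint counts per site
  position, with a chi-square test against uniformity.

A decision tree over the three results assigns checkerboard, random,
nested (clumped / random / hyperdispersed species loss), evenly spaced,
Gleasonian or Clementsian, with quasi- variants when coherence is
significant but turnover is not.

**NODF nestedness** (overlap and decreasing fill) with fixed-fixed swap or
r1 null models, as an independent check on the nested branch.

**Predictors and variation partitioning.** Spatial predictors are PCNM
eigenvectors (principal coordinates of the truncated distance matrix,
positive eigenvalues only); environmental predictors (salinity + eight
grain-size fractions) are z-scored and pruned to VIF < 3; sampling
occasions enter as dummies. After a global RDA gate and forward selection
with the double-stopping criterion, the Hellinger-transformed community is
partitioned into pure and shared adjusted-R² fractions of environment,
space and time by partial RDA (`adj R² = 1 − (1 − R²)(n − 1)/(n − m − 1)`),
with Freedman–Lane permutation tests for the pure fractions.

**Synthetic data.** Generators realize each idealized structure as an
incidence matrix and simulate Gaussian-niche communities along a
salinity-like gradient (Poisson counts, AR(1) sediment fractions, period
effects), including the full three-estuary study design (270 site-samples,
13 campaigns).

## Worked example

```python
import metacommunity as mc

inc = mc.generate_structure(mc.StructureSpec("nested_clumped", 20, 40, 0.5, seed=11))
res = mc.EMS(inc, iterations=1000).fit(seed=2024)
print(res.summary())
```

```
Elements of Metacommunity Structure
===================================================
Matrix: 18 sites x 40 species   alpha = 0.05
---------------------------------------------------
                observed  null mean       z       p
Coherence              0      220.7  -12.94  0.0000
Turnover               0      866.3   -3.51  0.0005
Clumping I          7.79             177.88  0.0000
---------------------------------------------------
Structure: Nested (clumped species loss)
```

Zero embedded absences against a null mean of ~221 is strongly positive
coherence (z is negative because the observed count lies below the null
mean); zero replacements against ~866 is significantly negative turnover,
so the metacommunity is nested; Morisita's I of 7.8 with a significant
chi-square marks the species loss as clumped — the generated structure is
recovered. Two sites dropped out as empty (18 of 20 remain).

Variation partitioning on a simulated four-campaign estuary:

```python
from metacommunity import VariationPartitioning
# y: Hellinger-transformed site x period community; envz: VIF-pruned z-scores;
# spa: selected PCNM eigenvectors; td: sampling-occasion dummies
vp = VariationPartitioning(y, envz, spa, td).fit(n_perm=999, seed=5)
print(vp.summary())
```

```
Variation partitioning (adjusted R2)
============================================
n = 80 rows; predictors: env=5, spa=13, time=3
--------------------------------------------
Pure environment [a]     0.0045   P = 0.0010
Pure space       [b]     0.1448   P = 0.0010
Pure time        [c]     0.0225   P = 0.0010
Env & Spa shared         0.7799
Env & Time shared       -0.0019
Spa & Time shared       -0.0098
Triple shared           -0.0287
Residual                 0.0887
--------------------------------------------
note: negative fractions reported as computed (not truncated)
```

Because salinity (and the sediment series) are themselves spatially
structured, most explained variation sits in the environment-with-space
shared fraction — the signature of an environmental gradient that is
arranged in space.

## Command line

```bash
metacom simulate --out data/ --seed 1            # write a synthetic CSV bundle
metacom run --species data/species.csv --env data/environment.csv \
    --coords data/coordinates.csv --out results/ --seed 1
metacom ems ... / varpart ... / adequacy ...     # individual stages
```

Inputs are three CSVs: long-format species records
(`estuary,period,station,site,taxon,count`), environmental measurements per
station or site, and coordinates. All flags have YAML-config equivalents
(`--config run.yml`).

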