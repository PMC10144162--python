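# floralint

Phylogenetic comparative analysis of floral phenotypic integration and
pollinator trait matching, built around the honeysuckle (*Lonicera*) study
system: ~11 co-occurring species whose flowers are visited by pollinator
guilds spanning a 16.8-fold range of proboscis lengths (small carpenter
bees at 2.45 mm to hawkmoths at 41.15 mm).

It is aimed at researchers in pollination biology and phylogenetic
comparative methods who want a tested, scriptable implementation of the
full chain from raw flower measurements and visitation records to a
selected causal path model.

## What it computes

**Integration index (INT).** For a species with `T` floral traits measured
on `N` flowers, INT is the variance of the eigenvalues `λᵢ` of the trait
Pearson correlation matrix:

    INT = Var(λᵢ) − (T − 1)/N,      %INT = 100 · INT / T

using the sample variance (divisor `T − 1`), under which the maximum — all
traits perfectly correlated — equals the number of traits `T`. The
`(T − 1)/N` term removes most of the finite-sample bias; uncertainty comes
from a percentile bootstrap over flowers (default 5000 resamples).

**Composite proboscis length (PLa).** Guild visitation rates
`VFᵢ` (visits · flower⁻¹ · period⁻¹) weight the guild mean proboscis
lengths `PLᵢ`:

    PLa = Σᵢ PLᵢ · VFᵢ / VFₙ,      VFₙ = Σᵢ VFᵢ

so PLa is a proper weighted mean lying within the guild range.

**PGLS.** Generalized least squares whose residual covariance follows the
phylogeny under Brownian motion (`C_ij` = shared root-to-ancestor path),
Pagel's λ (off-diagonals scaled by λ ∈ [0, 1]) or a stationary
Ornstein–Uhlenbeck process (`corr_ij = exp(−α d_ij)` in patristic
distance). Structural parameters are profiled by maximum likelihood and
models compared by AIC.

**Phylogenetic piecewise SEM.** Candidate causal structures over
(PLa, corolla tube, stigma height, upper/lower lip) with correlated-error
pairs are evaluated by Shipley's d-separation test: each implied
conditional independence is tested by PGLS, the claim p-values combine
into Fisher's `C = −2 Σ ln pᵢ` (χ² with 2k df), and admissible models
(p > 0.05, no significant missing path) are ranked by `AIC = C + 2K`.

A synthetic-data module generates the whole study design — Yule tree,
species means with planted path coefficients, individual flowers,
visitation records — with known ground truth for every recovery test.

## Worked example

```python
import numpy as np
import floralint as fl

bundle = fl.make_dataset("lonicera-like", seed=1)   # 11 species, full design

res = fl.bootstrap_integration(
    bundle.traits.species_matrix("sp01"), n_boot=5000, seed=1, species_id="sp01")
print(f"sp01: percent INT = {res.percent_int:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}, N={res.n_individuals}, T={res.n_traits})")

asm = fl.species_assemblages(bundle.observations, bundle.proboscis)
print(f"sp01: PLa = {asm['sp01'].pla:.2f} mm over {asm['sp01'].n_guilds} guilds")

ints = {sp: fl.integration_index(bundle.traits.species_matrix(sp)).percent_int
        for sp in bundle.traits.species()}
order = tuple(sorted(ints))
y = np.array([ints[sp] for sp in order])
x = np.array([asm[sp].pla for sp in order])
X = np.column_stack([np.ones_like(x), x])
best, table = fl.compare_evolutionary_models(y, X, bundle.tree, tip_order=order)
print(f"INT ~ PLa: model={best.model}, b={best.coef[1]:.3f} +/- {best.se[1]:.3f}, "
      f"t={best.t[1]:.2f}, p={best.p[1]:.4f}")
```

prints

```
sp01: percent INT = 38.73 (95% CI 24.59-53.48, N=30, T=8)
sp01: PLa = 41.96 mm over 5 guilds
INT ~ PLa: model=PL, b=0.706 +/- 0.154, t=4.59, p=0.0013
```

sp01 is this seed's hawkmoth-visited species: its assemblage proboscis
length is ~42 mm and its flowers are strongly integrated (39% of the
maximum). Across the 11 species, integration increases with assemblage
proboscis length (Pagel-λ PGLS slope 0.71 percent-INT per mm, p ≈ 0.001),
the qualitative pattern the generator plants.

The same analyses are available from the shell:

```sh
floralint simulate --seed 1 --out data/
floralint pipeline --seed 1 --out results/    # integrate → pla → pgls → psem
```

`results/report.json` then holds per-species INT with bootstrap CIs, PLa
per species, the single-predictor PGLS screen (with the non-phylogenetic
OLS fits alongside), and the fitted candidate path-model ranking with the
selected model's standardized coefficients and R².

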