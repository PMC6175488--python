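# beakrates

Rate heterogeneity in landmark-based trait evolution on phylogenies.

`beakrates` is a tested, reusable implementation of a comparative pipeline
for asking *which lineages evolve fast, and why* when the trait is a
multivariate shape measured by 3D landmarks (the motivating system is the
avian beak). It chains four stages:

1. **Geometric morphometrics** — quality control of crowd-sourced multi-user
   landmark configurations (inverted left/right tomial edges, disordered
   curve semi-landmarks, discrepant users at between-user Procrustes
   distance ≥ 0.2), user averaging, Generalized Procrustes Analysis, sliding
   of semi-landmarks along curve tangents to reduce thin-plate-spline
   bending energy, and PCA / phylogenetic PCA with selection of the axes
   explaining 99% of shape variance.
2. **Variable-rates Brownian inference** — a multivariate Brownian-motion
   model `vec(X) ~ N(1 ⊗ α, Σ ⊗ C)` whose per-edge rates are multiplied by
   strictly positive scalars placed on single branches or whole clades,
   sampled by reversible-jump MCMC (log-uniform scalar prior, Poisson shift
   count); per-branch posterior **median rates** and species **tip rates**;
   maximum-likelihood **relative clade rates** for monophyletic groups with
   ≥ 5 species; Gelman–Rubin PSRF (< 1.1) and effective sample size (≥ 200)
   convergence diagnostics.
3. **Correlates** — species ages (terminal branch lengths), a co-occurrence
   competition index on an equal-area grid (confamilial species sharing diet
   and foraging class, averaged over occupied cells), range/island/climate
   summaries, clade morphospace distinctiveness (Euclidean distance of the
   clade centroid to the grand centroid), and PGLS regressions with ML
   Pagel's λ, categorical interactions, and variance inflation factors.
4. **Synthetic data** — every input above can be generated with known ground
   truth: birth–death trees, traits with planted rate shifts, noisy/corrupted
   multi-user markups of a template beak, predictor tables with a known
   regression structure, and gridded ranges with guild labels. This makes
   each stage verifiable by invariants and parameter recovery.

The likelihood is evaluated by a pruning (independent contrasts) pass —
never a dense `np` × `np` inversion — with the trait covariance Σ and
phylogenetic mean α profiled at their conditional ML values, so a 200 000
iteration chain on a 128-tip tree runs in seconds.

## Worked example

Plant a 20× rate scalar on a 12-tip clade of a 64-tip simulated tree,
sample the variable-rates posterior, and summarize branch rates:

```python
import numpy as np
from beakrates import simulate, rates

tree = simulate.simulate_tree(n_tips=64, birth=1.0, death=0.0, seed=7)
internal = [i for i in range(tree.n_nodes) if tree.children[i] and i != tree.root]
target = min(internal, key=lambda e: abs(len(tree.clade_tips(e)) - 12))
truth = rates.RateScalarConfiguration([(target, "clade", 20.0)])
params = simulate.MVBMParams(alpha=np.zeros(2), sigma=np.eye(2))
traits = simulate.simulate_traits(tree, truth, params, seed=7)

post = rates.variable_rates_mcmc(
    tree, traits, rates.McmcSettings(n_iterations=200_000, thin=100, seed=2)
)
summary = rates.summarize_rates(post)
inside = set(tree.subtree_nodes(target).tolist())
print(summary.loc[summary.edge.isin(inside), "median_rate"].median())
print(summary.loc[~summary.edge.isin(inside), "median_rate"].median())
print(post.acceptance_rate, post.shift_count.mean())
print(rates.effective_sample_size(post.loglik))
```

prints (to the digits shown)

```
22.28    # median effective rate on edges inside the shifted clade
1.00     # median effective rate elsewhere (background convention: rate 1)
0.42 2.1 # MH acceptance rate; posterior mean number of shifts
978      # ESS of the log-likelihood trace (>= 200: converged)
```

i.e. the sampler recovers the planted 20× clade shift (rates are relative,
so the background sits at 1 and the clade near the true scalar), with an
economical posterior (~2 shifts) and a comfortably converged chain.

## Command line

The same stages are exposed as subcommands:

```bash
beakrates simulate-tree --n-tips 64 --seed 1 -o tree.nwk
beakrates simulate-markups --n-specimens 10 -o markups.csv
beakrates qc --markups markups.csv -o qc_report.csv
beakrates align --markups markups.csv -o aligned.csv
beakrates shapespace --markups aligned.csv --cum-var 0.99 -o shapespace/
beakrates rates-mcmc --tree tree.nwk --scores shapespace/scores.csv -o rates/
beakrates diagnostics --trace chain1.csv --trace chain2.csv
beakrates pipeline -c config.yaml --seed 1 -o run/
```

`pipeline` chains everything from a YAML config (any key overridable with
`--set key=value`) and writes a manifest with seeds, parameters, and
convergence warnings; PSRF ≥ 1.1 or ESS < 200 warn rather than abort.

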