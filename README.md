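# fpdemog

Do phylogenetically and functionally distinct alien plants suffer less
from competition with their resident communities?  `fpdemog` implements
the full inference chain needed to ask that question with demographic
field experiments, plus a synthetic-data generator with known ground
truth so every stage can be validated at desk scale.

The chain, stage by stage:

1. **Demography.** Individual census records from control and
   competitor-removal plots are fitted as stage-structured matrix
   population models (MPMs; transition frequencies plus per-capita
   fecundities) or size-structured integral projection models (IPMs;
   logistic survival, Gaussian growth and log-linear fecundity
   regressions, discretized by the midpoint rule with 500 meshpoints).
   The population growth rate λ is the dominant eigenvalue of the
   projection matrix.
2. **Effect size.** The demographic effect of competition for species
   *i* is the log response ratio
   `effect_i = ln((λ_i,removal + 0.5) / (λ_i,control + 0.5))`,
   with the +0.5 guarding against growth rates near zero.
   Uncertainty comes from resampling individuals with replacement
   within species × treatment and re-fitting everything, 1000 times.
3. **Distinctiveness.** On a rooted ultrametric phylogeny (grafting
   missing species next to congeners, pruning to the species pool,
   square-root-transformed cophenetic distances), each focal species
   gets MPD (mean pairwise distance), NND (nearest-neighbour
   distance) and their abundance-weighted versions, at two spatial
   grains: its plot community (rarefied to k = 11 members, 1000
   resamples) and the whole regional pool.
4. **Traits.** A modified Gower distance combines continuous,
   circular-month, binary and categorical traits on a common [0, 1]
   scale; phylogenetic signal is diagnosed with Blomberg's K
   (continuous), the Fritz–Purvis D statistic (binary) and Mantel
   tests (distance matrices).
5. **Regression and the a-sweep.** Effect sizes are regressed on a
   distinctiveness metric and z-scored competitor biomass (OLS);
   bootstrap effect-size draws propagate demographic uncertainty into
   percentile CIs.  Functional and phylogenetic distances are blended
   as `FPD = sqrt(a·PD² + (1−a)·FD²)` and the weight *a* is swept from
   0 to 1 in 0.025 steps, recording adjusted R² at each value.

## Worked example

```python
from fpdemog import ScenarioConfig, simulate_scenario, cophenetic_matrix
from fpdemog.experiments import recovery_run

run = recovery_run(seed=3)
print(f"small-grain slope {run.slope_small:+.3f}  "
      f"95% CI [{run.ci_small[0]:+.3f}, {run.ci_small[1]:+.3f}]")
print(f"adjusted R^2 {run.adj_r2_small:.3f}")
```

prints

```
small-grain slope -0.085  95% CI [-0.113, -0.058]
adjusted R^2 0.650
```

The scenario planted a slope of −0.07 between community-level
distinctiveness and the effect of competitor removal: the small-grain
regression recovers a negative coefficient whose bootstrap CI excludes
zero, i.e. the more distinct the alien, the less removing its
neighbours helps it.

The same machinery runs on real delimited data through the CLI:

```bash
fpdemog simulate --out scenario/ --seed 1     # or bring your own files
fpdemog run --config pipeline.yml --seed 1
fpdemog report results/run/
```

`run` writes per-species λ and effect-size tables, distinctiveness at
both grains, signal tests, Table-style regression summaries with
bootstrap CIs, and the per-*a* sweep; `report` renders coefficient
histograms and the adjusted-R²-vs-*a* curve.

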