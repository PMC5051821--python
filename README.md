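# cladediv

Clade-level diversification analysis for dated, family-level phylogenies.

Why are some plant families species factories while others have idled for a
hundred million years as a single species?  Given an ultrametric tree whose
tips are families (terminally unresolved clades) and per-family species
richness, `cladediv` runs the standard comparative toolkit for that
question:

* **Richness estimation** from taxonomic evaluation counts — accepted
  names S_A, rejected synonyms S_R, unevaluated names S_U — via
  S = S_A + S_A·S_U/(S_A+S_R), extrapolating the acceptance rate to the
  unevaluated pool.
* **Net diversification rates** per clade with the Magallón–Sanderson
  stem-age estimator r̂ = ln[S(1−ε)+ε]/t at bracketing relative-extinction
  values ε = 0 and ε = 0.9 (r = λ−μ, ε = μ/λ).
* **Age-window regressions** of ln S on stem age within adjacent 10-My
  windows after pruning nested clades (both removal directions), with a
  joint Benjamini–Hochberg correction — the time-for-speciation test.
* **Rate–richness regression** plus a permutation null showing how much of
  that correlation is built in (r̂ is a function of S).
* **Stepwise rate-shift detection**: birth-death models with geometric
  richness probabilities for unresolved tips, greedy exhaustive break-point
  search under a selection-corrected AICc stopping rule.
* **Synthetic data** for all of the above: birth-death tree simulators with
  planted shifts, time-slice family collapse, taxonomic-count simulation,
  and an exact sampler for the unresolved-family likelihood.

The statistical background, numerical choices and known limitations are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a 40-family tree carrying one five-fold diversification-rate shift,
then ask the search to find it:

```python
import cladediv as cd
from cladediv.simulate import simulate_unresolved_yule_tree_with_shift

tree, richness, true_clade = simulate_unresolved_yule_tree_with_shift(
    0.15, 5.0, seed=3, root_age=60,
)
print(true_clade)                      # F0016+22  (shifted 22-family clade)

config = cd.stepwise_shift_search(tree, richness)
print(config.break_nodes)              # ['F0016+22']
print([(m.kind, round(m.r, 3)) for m in config.models])
# [('yule', 0.141), ('yule', 0.728)]
print([round(a, 1) for a in config.aicc_trace])
# [1125.0, 748.8]
```

The search accepts exactly one break-point, at the true shifted branch: the
background clade fits a pure-birth rate of 0.141/My and the shifted clade
0.728/My — a ratio of ~5.2 against the planted 5× — and the break improves
AICc by 376 units.  The per-clade rate table for the same data:

```python
records = cd.enumerate_clades(tree, richness)
table = cd.rate_table(records)         # one row per clade × ε
print(cd.summarize_rates(table).round(4))
#  epsilon  r_min  r_max  r_mean  ...
#      0.0    0.0 0.9105  0.4372
#      0.9    0.0 0.6237  0.3121
print(cd.top_rank_overlap(table, 10))  # 7
```

Monotypic clades sit at exactly r = 0 under both extinction regimes, rates
shrink as assumed extinction rises, and 7 of the 10 fastest clades keep
their top-10 rank across the two regimes.

The same stages are available from the shell:

```sh
cladediv simulate --out demo --seed 4 --n-families 48
cladediv rates demo/tree.nwk demo/richness.csv -o demo/rates.csv
cladediv windows demo/tree.nwk demo/richness.csv -o demo/windows.csv
cladediv run-all --tree demo/tree.nwk --richness demo/richness.csv \
    --out demo/results --seed 1
```

`run-all` writes every result table (richness, clades, rates + summary,
windows, rate–richness regression + permutation null, shift models and
branch map) plus a `manifest.json` recording the seed, configuration and
per-stage timings; identical configuration and seed reproduce every file
byte for byte.

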