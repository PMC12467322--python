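# beenet

Tools for asking a field question in pollination ecology: **when a managed,
super-abundant generalist pollinator (the western honeybee, *Apis
mellifera*) is introduced into a natural plant community, which native bee
species decline, and by how much?**

`beenet` is aimed at community ecologists working with paired designs —
plots near apiaries versus plots far from them — with three data streams:

* individual **pollen loads** (one row per captured bee × pollen morphotype,
  with grain counts),
* **sweep-net counts** of bee abundance (plot × survey round × species),
* **flower-abundance surveys** (plot × survey round × plant species).

From these it builds quantitative pollen-transport networks, measures each
native bee's diet overlap with the honeybee, and models how overlap and
rarity predict abundance decline. A seeded synthetic-community generator
with known ground truth makes every stage testable without field data.

## The statistics at the core

**Pollen-transport network.** For each plot, entry `P[x, y]` counts the
individuals of bee species *x* that carried ≥ 3 grains of plant *y*'s
pollen; `A[x]` is the number of captured individuals of *x* (including
those below threshold). Species without partners are pruned.

**Perceived apparent competition (PAC)** uses Müller's index. For a
quantitative matrix `a` (consumers × resources),

```
d_ij = Σ_k  (a_ik / Σ_l a_il) · (a_jk / Σ_m a_mk)
```

— the share of consumer *i*'s use flowing through resources also used by
*j*, weighted by *j*'s share of each resource; every row of `d` sums to 1.
Because the raw index is abundance-sensitive, interaction strengths are
first equalized per capita, `N_xy = P_xy / A_x`, and the index is evaluated
on a two-row matrix holding only the focal native bee and the honeybee, on
diet proportions (equal abundances). PAC ranges from 0 (no shared plants)
to 0.5 (identical diets). **PAC_C** pairs the native's nearby-plot diet
with the honeybee; **PAC_D** pairs the native's distant-plot (undisturbed)
diet with the honeybee's profile, which is injected into distant networks
where honeybees are absent.

**Abundance models.** Per species, a negative-binomial GLM (log link) of
per-plot-per-survey counts on plot type; its coefficient is the log ratio
of nearby to distant mean abundance. Across species, Gaussian linear models
regress the relative change `(distant − nearby) / distant` (1 = lost near
apiaries) on PAC_D, PAC_C, baseline abundance, and abundance × PAC_D.

**Diet shifts.** Per-sample diet proportions are compared with Bray–Curtis
dissimilarity; a seeded one-way PERMANOVA (pseudo-F, 999 label
permutations) tests nearby-vs-distant differences, and nonmetric MDS
(Kruskal stress-1) draws the ordination. The same machinery checks that
flowering composition is homogeneous across plots.

## Worked example

`examples/02_perceived_apparent_competition.py` simulates a small community
(8 native bees, 30 plants) and recovers diet overlap from pollen loads:

```
PAC table (NaN pac_c = species never seen near apiaries):
             pac_c  pac_d  n_plots_c  n_plots_d
bee_species
Native_01      NaN  0.013          0          3
Native_02    0.162  0.164          3          3
Native_03      NaN  0.214          0          3
...
Native_08      NaN  0.289          0          3

Estimated PAC_D vs the generator's true diet overlap:
             pac_d  true_overlap
Native_01    0.013         0.025
Native_02    0.164         0.136
...
Native_08    0.289         0.357
```

`Native_01` is an extreme specialist (PAC_D ≈ 0.01: almost no diet shared
with the honeybee) and was never captured near apiaries, so its PAC_C is
missing — the same pattern the paired field design produces for rare
specialists. Generalists sit near 0.3, and estimated PAC_D tracks the
generator's true overlap up to pollen-sampling noise.

The other examples cover network construction (`01`), abundance GLMs and
change regressions (`03`), the diet-shift PERMANOVA/NMDS (`04`), and the
full pipeline with its output CSVs and run manifest (`05`). A thin CLI
wraps the same stages:

```bash
beenet simulate --seed 1 --out simdata
beenet run-all simdata/pollen_records.csv simdata/sweep_counts.csv \
    simdata/flower_surveys.csv --out results
```

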