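# facomp — compositional-noise analysis of multiplexed focal-adhesion imaging

Focal adhesions assemble from dozens of integrin-adhesome proteins by
self-organization, and the stochastic realization of alternative binding
options injects *noise* into each adhesion's molecular composition.
Multiplexed (cyclic immunofluorescence) imaging measures the densities of
many components in thousands of individual adhesions — but the variance of
those densities mixes noise with *diversity*, the real biological
variation among adhesions driven by local cues and maturation.  `facomp`
implements a complete, synthetically validated analysis chain that
untangles the two, for cell biologists and image analysts working with
multiplexed adhesion data:

* **assembly_sim** — stochastic simulators of adhesion assembly
  (competitive, noncompetitive, multistep binomial recruitment) used to
  validate the inference rules on ground truth;
* **synthetic_data** — a desk-scale surrogate of a six-dataset study
  (3 repeats × 2 antibody labeling orders), both density tables and
  rendered multi-channel image stacks with exact truth;
* **imaging** — registration (subpixel Fourier cross-correlation),
  high-pass background subtraction, watershed segmentation, density /
  area / eccentricity measurement, backward tracking, age and
  assembling/stationary/disassembling classification;
* **preprocess** — Box-Cox transformation (per-dataset maximum-likelihood
  λ), z-scoring, Tukey outlier removal, and multilevel-Otsu
  categorization by area, eccentricity and internal density;
* **noise_infer** — the central statistic;
* **highorder** — a neural-network subset screen for high-order
  compositional relations.

## The statistic

For two adhesion categories (e.g. small vs big), per dataset and
component the package computes the coefficient of variation CV = σ/μ of
each component's density, and per component pair the squared Pearson
correlation r².  Averaging `log(CV₂/CV₁)` and `r₂² − r₁²` over datasets
(≥ 5 adhesions per group) and then over components/pairs gives
`Δlog(CV₁,CV₂)` and `Δ(r₁²,r₂²)`, whose joint signs decide:

| Δlog CV | Δr² | verdict |
|---|---|---|
| − | + | noise lower in category 2 |
| + | − | noise lower in category 1 |
| + | + | diversity higher in category 2 |
| − | − | diversity higher in category 1 |

A mean smaller in magnitude than its between-dataset standard error is
insignificant, making the comparison inconclusive.  The logic rests on
diversity being a common factor across components (raising correlations)
while noise is component-independent (diluting them); the simulators in
`assembly_sim` verify the rules recover imposed changes under every
modeled topology.

The high-order screen asks a complementary question: is a component's
density tuned by *integrating* multiple other components?  All 511 input
subsets of the other 9 components feed a three-hidden-layer perceptron;
subsets become nodes of a lattice whose edges point toward significantly
better predictors (F-test), and each node's position score
L = L1/(L1+L2) — edge distance to the closest single-input node over the
sum with the distance to the closest prediction optimum — flags
high-order relations when L > 0.7 reproduces across datasets and
labeling orders.

## Worked example

Generate the six-dataset synthetic study, preprocess it, and compare
small against large adhesions:

```python
from facomp.synthetic_data import SyntheticStudyConfig, generate_density_tables
from facomp.preprocess import preprocess_study
from facomp.noise_infer import compare_categories

tables = generate_density_tables(SyntheticStudyConfig(seed=1))
pre = preprocess_study(tables)
print("area thresholds (um^2):", [round(float(t), 2) for t in pre.area_thresholds])
print(compare_categories(pre.tables, "area_cat", "S", "L").summary())
```

prints

```
area thresholds (um^2): [3.41, 7.79]
{'axis': 'area_cat', 'category1': 'S', 'category2': 'L',
 'delta_log_cv': -0.2869638851500321, 'delta_log_cv_sem': 0.07853415707370888,
 'delta_r2': 0.4839457626940275, 'delta_r2_sem': 0.038054827294396104,
 'verdict': 'noise_lower_in_2', 'n_datasets': 6}
```

Pooled Otsu thresholding splits the adhesions at 3.41 and 7.79 µm² into
small/medium/large.  Going from small to large, the mean CV drops by a
factor `exp(−0.287) ≈ 0.75` while the mean pairwise r² rises by 0.48;
both magnitudes exceed their between-dataset SEMs, so the verdict is
that compositional noise is lower in the large adhesions — exactly the
noise-area coupling the generator plants (see `docs/methods.md`).

The same analysis runs from the shell:

```sh
facomp run --seed 1 --out my_run          # full pipeline + report.json
facomp generate --seed 1 --out tables/    # just the synthetic tables
facomp infer tables/*.csv --axis area_cat --cat1 S --cat2 L
facomp highorder tables/*.csv --target paxillin --sessions 50
```

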