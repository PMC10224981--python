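# cbmex — context-specific metabolic model extraction and evaluation

`cbmex` builds **context-specific constraint-based metabolic models** from a
generic template and a transcriptomics cohort, and evaluates how well they
capture the metabolic functions the data supports. It is aimed at systems
biologists who have a genome-scale (or toy) stoichiometric model, a gene ×
sample expression matrix, and a list of metabolic tasks, and want to compare
what different extraction algorithms do with the same evidence.

## What it computes

A constraint-based model is a stoichiometric matrix *S* with flux bounds;
steady-state fluxes satisfy *S v = 0*, *lb ≤ v ≤ ub*, and flux balance
analysis (FBA) maximizes one flux (biomass). Expression is turned into
evidence in two steps:

- **Gene scores.** Each gene gets a threshold equal to the 90th percentile of
  its expression across samples, floored at the 25th percentile of the
  pooled distribution, and a score
  *score = 5 ln(1 + expression / threshold)*,
  so a gene exactly at its threshold scores **5 ln 2 ≈ 3.466** — the
  activity cutoff used everywhere.
- **Reaction activity levels (RAL).** Each reaction's RAL is the maximum
  score over the genes in its gene-protein-reaction (GPR) rule.

Six **model-extraction methods** (MEMs) reduce the template to a
context-specific submodel per sample: GIMME (growth-constrained penalty LP),
iMAT and INIT (mixed-integer programs over reaction on/off indicators),
FASTCORE (compact flux-consistent core superset), MBA (randomized greedy
pruning with high/medium-confidence cores), and mCADRE (evidence-ranked
pruning). The biomass reaction is protected in all of them and its lower
bound is fixed at a nominal 1 h⁻¹.

**Metabolic tasks** (bounded input → required output conversions with all
exchanges closed) measure function: binary task scores are *inferred* from
expression (mean RAL over the reactions a task uses on the template,
thresholded at 5 ln 2) and *predicted* by each extracted model (task
feasibility). The **normalized Hamming distance** between the two vectors is
the functional-accuracy measure; the generic template (which performs every
filtered task) is the baseline. PCA on reaction-presence matrices with
per-factor R² (max squared Pearson correlation over factor-level orderings)
attributes variance to extraction method, life stage, and feed.

A synthetic-data generator produces templates with redundant pathways and
accessory branches, context-structured expression under an unbalanced
two-factor design, task lists, and the ground truth needed to validate the
whole pipeline without any downloads.

## Worked example

```python
from cbmex import (RunConfig, run_study)

results = run_study(RunConfig(methods=("GIMME", "iMAT", "INIT"), seed=1),
                    write=False)
print(results.distances.groupby("method")[["distance", "template_distance"]]
      .mean().round(3))
```

prints

```
          distance  template_distance
method
GIMME        0.198              0.505
INIT         0.198              0.505
iMAT         0.198              0.505
```

On the standard synthetic design (4 pathway modules with 2 redundant routes
each, effect size 10, 28 samples in a freshwater/saltwater × feed design),
every context-specific model disagrees with the expression-inferred task
scores on ~20% of tasks, while the generic template disagrees on ~50% —
the extracted models are about 2.5× functionally closer to the data than
the template they came from. The same `StudyResults` object carries model
contents (gene/reaction/metabolite counts), relative growth, relative
parsimonious-FBA flux, task-feasibility matrices, PCA variance and factor-R²
tables, and per-extraction provenance.

The command line mirrors the library:

```bash
cbmex simulate --outdir synthetic --seed 1     # model + expression + tasks
cbmex run --outdir results --seed 1            # full study
cbmex evaluate --results results               # distance summary
```

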