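# adikit

Composite applicability-domain scoring for (Q)SAR predictions.

A (Q)SAR model is only trustworthy for chemistry that resembles what it was
trained on. Regulatory frameworks (REACH, the OECD (Q)SAR principles)
therefore require every prediction to come with an applicability-domain (AD)
assessment. Rather than a binary in/out verdict, `adikit` computes a
continuous 0–1 **Applicability Domain Index (ADI)** for each query compound,
in the style popularized by the VEGA platform: a product of per-component
reliability subscores that a user (or a batch filter) can act on, together
with the ranked similar training compounds and explicit warnings that
explain *why* a prediction is or is not trustworthy.

It is model-agnostic: wrap any predictor in a `ModelAdapter` (a `predict`
callable plus optional descriptor, structural-alert and outlier-fragment
capabilities), build a `KnowledgeBase` from its training SMILES with
experimental values, and every prediction can be qualified.

## The index

For a query compound *q* with nearest training neighbors
*n₁ … n_k* (by Tanimoto similarity *s* over Morgan/2048 fingerprints,
*k* = 2 by default), the raw components are

| component | regression | classification |
|---|---|---|
| similarity | mean of *s(q, nᵢ)* over top *k* | same |
| accuracy | mean \|ŷ(nᵢ) − y(nᵢ)\| (log units) | fraction of top *k* predicted correctly |
| concordance | mean \|y(nᵢ) − ŷ(q)\| | fraction whose label equals the predicted label |
| max error | max \|ŷ(nᵢ) − y(nᵢ)\| | similarity of the best-ranked misclassified neighbor |
| ACF index | weighted fraction of the query's atom-centered fragments known to the training set | same |
| sensitivity | max \|Δŷ(q)\| under ±1% descriptor perturbation | same |

Each raw value is mapped onto [0, 1] by a model-specific piecewise-linear
threshold function (1 at-or-beyond *t_good*, 0 at-or-beyond *t_bad*), and

```
ADI = ∏ subscoreᵢ × 0.6^(#failed boolean checks)    ∈ [0, 1]
```

where the boolean checks are the descriptor/MW range check against the
training ranges and the presence of declared outlier-associated fragments.
The ADI is bucketed into **high** (> 0.85, ★★★), **moderate**
(0.75–0.85, ★★) and **low** (< 0.75, ★) reliability categories; all
thresholds and boundaries are per-model configuration (YAML/JSON).

## Worked example

Build a knowledge base from a small training CSV (`id,smiles,experimental`)
around a toy k-nearest-neighbor predictor, then assess two queries:

```bash
adikit build-kb --input train.csv --out kb.json
adikit assess --kb kb.json --smiles "CCCO" --id propanol
```

```
ADI assessment: propanol  (CCCO)
Predicted value           1.245

ADI                       1.000  [high, ***]
Similarity index          1.000
Accuracy index            0.045
Concordance index         0.045
Max error index           0.045
Descriptors range check   True
ACF index                 1.000
Sensitivity index         0.011

Similar compounds (6):
  1. a2  similarity 1.000  experimental 1.200  predicted 1.245
  2. a2b  similarity 1.000  experimental 1.200  predicted 1.245
  3. a3  similarity 0.583  experimental 1.400  predicted 1.577
  ...
Warnings: none
```

The query is structurally identical to an accurately predicted training
compound, every fragment is well known, all descriptors are in range — all
subscores saturate and the ADI is 1.000 (high, three stars). A nitrosamine
query against the same alcohols-only knowledge base instead gets

```
ADI                       0.000  [low, *]
Similarity index          0.167
...
ACF index                 0.167
Warnings:
  - similarity index below ideal (raw 0.167, subscore 0.000)
  - ACF index (rare/unknown fragments) below ideal (raw 0.167, subscore 0.167)
  - descriptor range check failed: heteroatoms outside training range
```

— the N–N=O environment is unknown to the training set and the low ADI says
so explicitly.

Batch mode writes one row per input compound (errors included, order
preserved) and can filter by reliability:

```bash
adikit batch --input queries.csv --kb kb.json --out scored.csv --min-adi 0.85
adikit evaluate --kb kb.json --test test.csv --out-prefix perf   # AD-stratified accuracy/R²
adikit simulate --seed 0 --out-dir bench/                        # synthetic end-to-end benchmark
```

`evaluate` reports per-stratum metrics (accuracy for classifiers; R², RMSE,
MAE for regression) for the high / moderate / low categories, which is the
standard way to demonstrate that an AD tool actually separates reliable
from unreliable predictions. The `simulate` command generates a synthetic
chemical space with designed in-domain, edge and out-of-domain test subsets
(see `adikit.synthetic`) and runs the whole pipeline on it.

## File formats

* compounds: CSV (`id,smiles[,experimental]`), SDF (V2000; id from the
  title line, value from a named property tag), or one-SMILES-per-line
  lists;
* knowledge base: a single versioned JSON document (canonical SMILES,
  values, predictions, fragment counts, descriptor ranges);
* per-model config: YAML/JSON (`task_type`, `k`, `n_display`, per-component
  `thresholds`, category boundaries, `bool_multiplier`,
  `perturbation_delta`);
* outputs: CSV/TSV batch tables, text/JSON per-compound reports, tidy
  CSV + JSON stratified-performance summaries, optional SVG/PNG charts.

## Scope

`adikit` scores the reliability of an *existing* model's predictions; it
ships only toy k-NN predictors for testing and examples, and makes no claim
of numerical identity with any specific platform's internal ADI formula —
the aggregation rule, fingerprint and fragment definitions are documented
choices (see `docs/methods.md`).
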