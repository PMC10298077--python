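# Methods

This note documents the model behind `adikit`'s applicability-domain
scoring, the choices made where the published descriptions of
ADI-style tools leave the details open, and what the synthetic benchmark
does and does not demonstrate.

## The assessment model

A (Q)SAR prediction is qualified along three axes:

* **chemistry** — is the query close to the training set? Three components:
  mean top-*k* neighbor similarity, the atom-centered-fragment (ACF)
  rarity index, and a range check of the query's descriptors (always
  including molecular weight) against the training min/max;
* **endpoint** — does the model get the query's neighborhood right? Three
  components: the accuracy index (errors of the model on the query's
  nearest training compounds), the concordance index (agreement of the
  query's *prediction* with the neighbors' *experimental* values — the
  read-across cross-check), and the max-error index (a single badly
  predicted close neighbor is a warning even when the mean looks fine);
* **algorithm** — is the prediction numerically stable? The sensitivity
  component perturbs each descriptor by ±1% (relative; absolute when the
  value is 0), re-predicts through the adapter's descriptor head, and
  records the largest shift.

Components whose prerequisites the adapter does not provide (no
descriptors, no alerts, no declared outlier fragments) are *excluded* from
aggregation, never imputed as perfect or failed. The structural-alert
cross-check never enters the score numerically: its outcome
(concordant / target-only / neighbor-only / none) is reported as a warning,
because a neighbor-only alert is precisely the case where a user may
legitimately disregard that neighbor. When the target and its neighbors
carry disjoint non-empty alert sets, the outcome is classified target-only
(the target's own alert is the primary signal) and the neighbor alerts are
still listed in the warnings.

## Similarity and fragments

The similarity measure is the Tanimoto (Jaccard) coefficient over Morgan
circular fingerprints, radius 2, folded to 2048 bits. This satisfies the
contract an ADI needs — symmetric, in [0, 1], and 1.0 exactly for
structures identical at the fingerprint's resolution — and is the de facto
standard in cheminformatics. An optional blended mode mixes in the Jaccard
coefficient of the two ACF key sets with a configurable weight (default 0);
the hook exists so a platform-specific similarity can be substituted
without touching the rest of the pipeline. No claim is made that these
values numerically match any particular platform's similarity.

An ACF key encodes one heavy atom: element, formal charge, aromaticity
flag and total hydrogen count at the center, plus the canonically sorted
list of (bond order, neighbor element, neighbor aromaticity) pairs.
Hydrogens are implicit — shells contain heavy neighbors only, with the
center's hydrogen count made explicit — so keys are independent of
H-addition conventions. Radius 1 is the default; radius 2 nests each
neighbor's radius-1 key and is available per config. One canonical
aromatic-perception pass (RDKit's, at parse time) applies to knowledge-base
and query molecules alike, so like is always compared with like.

The ACF index over the query's *distinct* keys: weight 1 when at least
`f_known = 3` KB molecules contain the key, `w_rare = 0.5` when it is
present but rarer, 0 when absent; the index is the mean weight.
Distinct-fragment (not multiplicity) weighting and the (3, 0.5) defaults
are this package's choices — the published descriptions distinguish "rare
or unknown" fragments without quantifying — and both are per-model config.
Counting is molecule-level: a fragment occurring five times in one training
compound is still known to only one molecule.

Multi-fragment SMILES (salts, mixtures) are rejected by default because AD
semantics for mixtures are undefined; an explicit flag keeps the largest
fragment instead.

## Aggregation

Each raw component maps onto [0, 1] through a piecewise-linear function of
its model-specific thresholds (1 at-or-beyond `t_good`, 0 at-or-beyond
`t_bad`, linear between, monotone for either orientation). The overall ADI
is the **product** of the applicable subscores, times `bool_multiplier`
(default 0.6) once per failed boolean check. A product was chosen over a
sum or minimum because it reproduces the two behaviors a composite AD score
must have: it saturates at 1.000 only when *every* check is clean, and a
single bad component drags the score down hard without the others masking
it. The 0.6 multiplier makes a lone failed range check decisive on its own
(caps the ADI at 0.6, below the low boundary). These are design decisions
of this package, not a claim about any platform's internal formula.

Default thresholds (regression, log-unit endpoints): similarity
higher-better (0.9, 0.6); accuracy lower-better (0.5, 1.5); concordance
lower-better (0.5, 1.5); max error lower-better (0.75, 2.0); ACF
higher-better (1.0, 0.0); sensitivity lower-better (0.1, 1.0).
Classification replaces the error components with fractions (higher-better
(1.0, 0.5-style bands)) and defines the max-error analogue as the
similarity of the best-ranked misclassified neighbor — an invented but
conservative semantic: a very close misclassified neighbor is the
strongest possible warning a classifier's neighborhood can give.

Categories: high > 0.85 (three stars), moderate in the closed interval
[0.75, 0.85] (two stars), low < 0.75 (one star). The boundary values are
inclusive to moderate; both are configurable per endpoint.

Components are measured on the `k = 2` most similar compounds by default
(`k = 3` for some endpoints), while `n_display = 6` neighbors are shown.
Neighbors with missing experimental values are skipped by the
endpoint-dependent indices and the next-ranked neighbor is promoted, so *k*
usable neighbors are always sought; a "fewer than k" warning is attached
when even that fails. Neighbor ties are broken by knowledge-base insertion
order, making every ranking deterministic.

The knowledge base holds the training set only by default
(`scope=training_only`): evaluating held-out compounds against a KB that
contained the test set would let a query find itself among its neighbors
and inflate every endpoint component. `training_plus_test` exists for
read-across-style use and must be requested explicitly.

## Stratified evaluation

`evaluate_model` excludes test compounds whose *canonical SMILES* occurs in
the KB (structural, not id-based, duplicate detection), assesses the rest,
and reports per-stratum metrics: accuracy (plus sensitivity, specificity
and MCC for binary tasks) for classifiers; R² as the coefficient of
determination 1 − SSres/SStot (primary), squared Pearson correlation
(secondary), RMSE and MAE for regression. Strata below a minimum size
(2 for classification, 3 for regression) report not-available rather than
a meaningless number, and MCC is not-available whenever a marginal of the
confusion table is zero. The metrics are implemented from their closed
forms so these degenerate cases are explicit; the test suite cross-checks
them against scikit-learn.

## The synthetic benchmark

`adikit.synthetic` generates a self-contained chemical space from short
hard-coded scaffold and substituent SMILES libraries: benzenes, pyridines,
cyclohexanes, chains and phenols for training; substituents never used in
training (halogens, CF₃, amides…) decorate the same scaffolds for the
*edge* subset; nitrosamine, organophosphate and sulfonamide scaffolds —
whose core ACFs are absent from training by construction — form the *out*
subset. The simulated property is a smooth function of heavy-atom count,
heteroatom fraction and molecular weight plus Gaussian noise (σ = 0.2 log
units; 0.6 for the out subset, emulating the harder-to-measure chemistry an
out-of-domain compound typically brings). Default sizes: 200 training and
120 test compounds (50 in / 40 edge / 30 out); a single seeded NumPy
generator drives every draw, so runs are bit-reproducible.

The toy predictor is a similarity-weighted 3-NN regressor over the same
fingerprint space (thresholded at the training median for classification),
with a least-squares linear descriptor head so the range and sensitivity
checks are exercisable. Its benchmark configuration lowers the similarity
thresholds to (0.7, 0.3): Morgan/2048 Tanimoto between close analogs of
small molecules rarely exceeds ~0.8, and thresholds are model-specific by
design — a platform calibrates them per model in exactly this way.

What the benchmark demonstrates: the pipeline assigns systematically lower
ADI to designed out-of-domain chemistry than to held-out in-domain
chemistry, and prediction error (RMSE) is larger in the low stratum than in
the high one, averaged over repeated seeds. What it does not demonstrate:
anything about real endpoints. The generator has no QSPR fidelity — the
property surface is smooth and low-dimensional, real experimental noise is
not homoscedastic, and real out-of-domain failure modes include activity
cliffs the generator does not model. Passing tests show the machinery is
correct and the score behaves monotonically with the evidence, not that
any particular real model's AD is well calibrated.

## Numerical details and edge cases

* All component computations are deterministic; no randomness exists
  outside the synthetic generator.
* `score_component` requires `t_good ≠ t_bad`; equal thresholds are a
  config error, not a silent step function.
* The ADI is clamped to [0, 1] after the boolean multipliers.
* A query with no applicable components at all (every capability absent
  and no similarity computable) raises rather than emitting a vacuous
  score.
* Reports render not-applicable entries as "-", three-decimal fixed point
  in text, full precision in JSON; the JSON form reloads and re-renders to
  byte-identical text.
* KB JSON embeds a short fingerprint digest per record; reload re-derives
  structures from canonical SMILES and verifies the digest, so a corrupted
  or hand-edited KB fails loudly.

## Known limitations

* The similarity, ACF definition and aggregation formula are documented
  stand-ins for platform-internal definitions that are not public;
  component *semantics* and the 0.75/0.85 category boundaries are faithful,
  individual numeric values are not comparable across implementations.
* Stereochemistry, tautomers and 3D structure are out of scope; mixtures
  are handled only by largest-fragment reduction.
* The uncertainty-of-the-model component that some platforms attach to
  specific endpoints has no general definition and is not implemented;
  the adapter's capability surface covers the remaining components.
* Exhaustive neighbor search is the implementation (and the oracle); KBs
  beyond ~10⁴ compounds would want an ANN index, which is deliberately
  out of scope.
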