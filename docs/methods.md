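# Methods

## The model

The pipeline treats a cohort of patients and their clinical descriptors as
a bipartite relation and analyses it as a simplicial complex before any
supervised learning.

**Augmented vertex set.**  Every retained clinical variable *x* becomes a
vertex/antivertex pair of boolean descriptors: `x[1]` is true when the
observed value lies in the variable's risk range, `x[0]` when it lies in
the non-risk range, and a missing observation leaves both false.  The
ranges are clinical data, kept in an editable YAML map
(`src/neuralhypernet/data/thresholds.yaml`), with one pair per variable
(e.g. `Age[0] = {Age ≤ 64}`, `Age[1] = {Age ≥ 65}`; `Shockindex[0] =
{0 ≤ SI ≤ 0.89}`, `Shockindex[1] = {SI ≥ 0.9}`).  The ⟨0,0⟩ encoding keeps
"observed normal" distinct from "not observed", which is the whole point:
deletion would discard most of a 24 %-missing MNAR table and imputation
would bias it.

From the 28 cohort columns, 19 analysis variables are retained: the
identifier is dropped, Troponin/PAS/PAD/PAPS are dropped as redundant or
nearly unobserved, the three clinical prediction rules (Wells, Revised
Geneva, Wicki) are dropped because they already encode physician judgement,
and the final diagnosis is held out as the label.  Discretization therefore
yields 38 feature descriptors, plus the diagnosis pair (items 39–40 of the
range map) which is appended *only* for the Q-analysis view and never
enters a classifier input space.

**Q-analysis.**  A descriptor exhibited by *n* patients is an
(*n*−1)-simplex whose vertices are those patients.  The shared-face matrix
is S[i,j] = |patients(i) ∩ patients(j)| − 1, with the simplex dimension on
the diagonal.  Two descriptors are q-near when S[i,j] ≥ q and q-connected
when chained by q-nearness; a simplex participates at level q only when its
own dimension is ≥ q, and survivors without q-near neighbours count as
singleton components.  The structure profile evaluates the q-connected
components at every q from 0 to max dim; the *plateau* anchored at
`Final diagnosis[1]` is the longest consecutive q-interval on which that
anchor's component keeps identical membership with size ≥ 2, ties broken
toward the higher interval (the stability zone of interest is the
high-dimensional one).  Plateau members minus the diagnosis pair form the
connected higher-dimensional set; the remaining feature descriptors the
unconnected set.  Backcloth membership means "common to many patients",
not "discriminative" — hence the classifier is trained on each set and on
their union.

**Classifier.**  A single-hidden-layer feed-forward network with sigmoid
activations throughout, trained by full-batch gradient descent with
momentum on the mean-squared error, the output read as the probability of
disease.  Defaults: learning rate 0.5, momentum 0.9, weights initialised
uniformly in [−0.5, 0.5], decision threshold 0.5.  The hidden width is
selected by the mean AUC over stratified k-fold cross-validation (the
sweep default spans widths 1–77; any candidate list may be supplied), ties
going to the smallest network.  The number of epochs is selected by an
internal stratified 10 % slice of the training pool: the weights from the
epoch with minimal slice MSE are restored.  Model selection and training
see only the 85 % training side of a stratified holdout; all reported
metrics come from the untouched 15 % validation side.

**Metrics.**  AUC is the Mann–Whitney midrank statistic (ties get average
ranks), identical to trapezoidal integration of the empirical ROC; the
Jaccard coefficient compares the positive-decision sets of the network and
of the reference diagnoses, with J(∅, ∅) defined as 1 (an all-negative
cohort with no positive calls on either side is perfect agreement).  A
per-patient simple-matching agreement is provided as a non-default variant.

## The synthetic generator

No public accession of the clinical cohort exists, so the generator
emulates its structure; its defaults are the package's study conditions.

- 1427 patients, 58 % positive prevalence enforced as an exact rounded
  count (deterministic class balance).
- Continuous indicators are class-conditional normals whose means are
  placed so the risk-threshold crossing probability equals a configured
  baseline shifted by a per-variable log-odds effect for positives
  (integer-valued indicators use a half-step threshold so rounding
  preserves the probability).  Count indicators are zero-inflated Poisson,
  symptom flags Bernoulli.
- A latent **typical presentation**: with probability 0.75 a positive
  patient (0.45 a negative — the cohort is emergency-room pre-screened, so
  negatives also look PE-like) exhibits the canonical polarity on eleven
  presentation variables at once (elderly, elevated d-dimer, tachycardic,
  dyspneic, PO2 above 60, without cough / chest pain / hemoptysis /
  palpitations / shock / previous DVT).  Wrong-side continuous values are
  reflected across the threshold so the conditional shape is preserved.
  This co-presentation is what gives the complex a stable mid-q backcloth;
  without it, independence given the label spreads the pairwise shared
  faces smoothly and the longest stability zone degenerates to the bottom
  of the q-range.
- **MNAR missingness** applied after value generation by masking: each
  variable has a marginal missing rate (defaults patterned on the clinical
  table, from ~0 % on age and diagnosis to ~86 % on PAPS, ~24 % overall),
  and a boost factor ≥ 1 multiplies the rate when the realized value lies
  in the non-risk range — unremarkable findings go unrecorded more often.
  The two conditional rates are renormalised so the marginal rate is
  preserved.
- Everything is drawn from a single seeded generator; output is
  byte-reproducible.

What the generator does **not** emulate: correlation structure beyond the
outcome effects and the single presentation class, temporal dynamics,
measurement error, inter-site variation, and label noise in the reference
diagnoses.  Passing tests on these cohorts show that the pipeline recovers
planted structure under realistic prevalence and missingness — not that it
attains any particular performance on real patients.

## Numerical and design choices

- **Risk-side precedence.**  The printed WBC ranges overlap at exactly
  10000; membership is evaluated risk-range first, so the boundary value
  maps to `WBC[1]`.
- **Gap values.**  Values covered by neither range (FC < 50, WBC < 2000,
  PCO2 < 35, PH < 7.3, Shockindex in (0.89, 0.9) or negative) carry no
  usable risk information; they encode to ⟨0,0⟩ with a warning rather than
  forcing a side.
- **PO2 direction.**  The range map keeps `PO2[1] = {PO2 > 60}` as listed,
  although clinically low oxygen tension is the alarm sign; an
  `invert_po2` switch swaps the pair.
- **Profile computation.**  The q-sweep runs top-down with a union-find:
  a vertex activates at its own dimension, an edge at its shared-face
  value, so the whole profile costs one pass over the sorted edges.  Its
  contract — identical output to independent per-level recomputation
  (a networkx connected-components build) — is enforced by tests against
  brute-force closure oracles.
- **Plateau ties** break toward the higher q-interval; the maximal
  component on a tie is the lexicographically first member set
  (determinism only — any choice is structurally valid).
- **Clustering** of the shared-face rows (for the heatmap view) uses
  average linkage under Euclidean distance; the linkage method is a
  parameter.
- **Sweep bookkeeping.**  The same stratified fold assignment is reused
  for every hidden width, so widths are compared on identical splits.  One
  published account counts "76 combinations … from 1 to 77"; the sweep
  range here is simply a configurable list, 1–77 inclusive by default.
- **Degenerate inputs.**  Single-class training labels, empty cohorts,
  out-of-range q, mismatched feature counts and invalid configuration
  fields are rejected with messages naming the offending field; an anchor
  that is everywhere isolated yields an explicitly flagged empty plateau.
- **Reproducibility.**  The pipeline derives per-stage seeds (generation,
  holdout, sweep, training) from the single configured seed; identical
  config + seed reproduces every artifact byte-for-byte.

## Problem sizes used by the test suite and acceptance script

The test suite exercises the Q-analysis oracles on hundreds of random
incidences up to 12 patients × 10 descriptors (where exhaustive closure is
cheap), planted-effect recovery on 1000-patient cohorts over five seeds,
and end-to-end determinism on 200–250-patient cohorts.  The acceptance
script runs the full default cohort (1427 patients) with a 7-point hidden
sweep under 5-fold cross-validation per feature set; these sizes keep a
complete run in the order of seconds while leaving every quantity
measured, not assumed.

## Known limitations

- The plateau definition assumes a single meaningful stability zone; on
  cohorts without co-presentation structure the longest constant interval
  can sit at the bottom of the q-range and select every descriptor.
- Jaccard agreement is computed between positive-decision sets only; it
  ignores agreement on negatives by construction.
- The MSE/sigmoid network is intentionally the era-faithful architecture;
  no regularisation, calibration or deep variant is provided.
- Threshold ranges are treated as exact clinical knowledge; no data-driven
  discretization is attempted.
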