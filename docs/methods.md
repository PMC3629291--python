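# Methods

## Data model

A disease is a map from clinical parameter to prevalence in percent of
reported patients, a group label (`positive` reference group, `negative`
controls, `test`), a patient count, and optionally the mean and standard
deviation of the age of onset in years. Parameter names are lower-cased
and trimmed at load; collisions after normalization are rejected rather
than merged silently, because "Ataxia" vs "ataxia " is almost always a
curation error worth surfacing. The dense phenotype matrix spans the union
of parameters, with absent parameters stored as 0 % — required so that
vector operations over the union are defined; row order follows the input
file and column order is first-appearance order, so a given database file
always produces the same matrix, clustering leaf order and network layout
inputs.

When several source studies describe one disease, they are pooled by
patient weighting: the merged prevalence of a parameter is
`Σ nᵢ pᵢ / Σ nᵢ` with a non-reporting study contributing prevalence 0 for
its patients — the pooled prevalence among the combined cohort. This
treats "not reported" as "not observed", which is the conservative reading
for prevalence data aggregated from cohort papers; a `reporting_only`
flag restricts each parameter's denominator to the studies that report it
for users who prefer the optimistic reading.

## Similarity and clustering

The default disease-to-disease measure is uncentered similarity (cosine
without mean-centering), turned into the distance `1 − s ∈ [0, 2]`.
Uncentered similarity is the natural choice for prevalence vectors: the
zero point is meaningful (parameter absent), so mean-centering (Pearson)
discards information, and scale-invariance makes the measure insensitive
to how florid a disease's overall presentation is. Pearson, Spearman,
Kendall, their absolute-value variants (distance `1 − |r|`), Euclidean and
city-block are available for sensitivity analyses. An all-zero symptom
vector under a correlation-type metric raises an error rather than
returning a silent 0: an empty phenotype is a data error, not a datum.

Agglomeration (average, single, complete, centroid linkage) is implemented
directly with Lance–Williams updates. The O(n³) pair scan is irrelevant at
database scale (tens of diseases) and buys an explicit tie-break — equal
minimum distances are resolved toward the smallest (oldest, oldest) node
pair — so merge sequences are identical across platforms. On tie-free
input the results match `scipy.cluster.hierarchy` to machine precision
(asserted in the tests, where scipy serves as the independent oracle).
Centroid linkage operates on squared distances and may produce height
inversions; the reducible linkages are guaranteed monotone.

Cophenetic correlation — the Pearson correlation between the n(n−1)/2
original distances and the heights of each pair's lowest common merge —
validates a clustering; it equals 1 exactly when the input is ultrametric.
It is undefined (error) below 3 leaves or under zero variance. Cutting a
tree into k clusters removes the k−1 highest merges, with ties resolved by
merge order; cluster ids are assigned by first-leaf order, so partitions
are deterministic. Trees serialize to Newick with branch lengths equal to
parent–child height differences; parsing (via dendropy) reconstructs
topology and cophenetic structure to 1e-9, with leaf order following the
serialized tree rather than the original matrix.

## The overlap kernel: network, barcode, score

One kernel serves three tools: the overlap of diseases A and B is
`Σ_shared p_A p_B / 10⁴`, a sum over parameters positive in both, each
term in [0, 1] and maximal at 100 %/100 %. The product form rewards
parameters that are *frequent in both* diseases, which is what shared
pathophysiology predicts, and it is exactly the barcode's tint rule, so
the qualitative (barcode, network) and quantitative (score) tools agree
by construction. The kernel is isolated behind single functions so it can
be swapped wholesale.

- **Network**: nodes carry group labels; an edge exists iff at least one
  parameter is positive in both endpoints, weighted by the kernel and
  annotated with the shared parameter list. Visualization thresholding
  keeps edges at or above a weight cutoff without dropping nodes. The hub
  coefficient (mean within-group / mean between-group edge weight)
  restates "the positive group forms a tight hub" as a testable number;
  it errors when no between-group edge exists and returns 0 when the
  group has no internal edge. Graph containers and GraphML I/O are
  networkx; the shared-parameter list is flattened to a `|`-joined string
  in GraphML, which has no list type.
- **Barcode**: one bar per (database disease, shared parameter), ordered
  by group (positive, negative, test), disease name, tint descending,
  then parameter name — the order is not semantically meaningful, it just
  makes output deterministic and groups visually contiguous. Scoring a
  disease against a database containing itself yields bars of tint
  `(p/100)²`, a useful self-consistency check.
- **Overlap score**: `100 · O₊/(O₊+O₋)` with `O±` the *mean* kernel value
  over each reference group. Means rather than sums, so an imbalance in
  group sizes (31 vs 25 in the motivating database) does not bias the
  score; the score is in [0, 100] and exceeds 50 exactly when the
  positive-group overlap is larger. A test profile overlapping neither
  group returns the maximally uninformative 50 with a `no_overlap` flag
  instead of erroring — sparse test profiles are normal in clinical use.

## Linear SVM classifier

Epsilon-insensitive support-vector regression with a linear kernel
(scikit-learn's libSVM binding), trained on the reference diseases with
targets +1/−1 from the group labels and used as a margin classifier.
Defaults are the libSVM defaults, cost 1 and epsilon 0.1, both exposed;
prevalences are fed unscaled (0–100) by default with an optional
divide-by-100 switch. The trained model is reduced to its explicit linear
form — feature names, weight vector, bias — and persisted as JSON, so
scoring is a dot product and models are portable and inspectable.
Parameters unknown to a model are projected to zero, making scores
invariant to irrelevant additions to a test profile.

The cumulative-prevalence filter keeps parameters whose prevalence summed
over the reference diseases (test diseases deliberately excluded, so the
feature space cannot leak information from the profiles being judged)
reaches a threshold; thresholds form nested feature sets by construction.

Cross-validation uses stratified folds, shuffled from an explicit seed:
at 56 reference diseases, unstratified 11-fold splits can produce
single-class training sets. Reported metrics pool all held-out
predictions: mean squared error against ±1, Pearson correlation, and
separation = percentage of predictions whose sign matches the label. When
k exceeds the minority class size (e.g. leave-one-out) plain shuffled
folds are used; a fold assignment that still yields a single-class
training split is redrawn up to 5 times before erroring. Reports are
bit-reproducible for a fixed seed.

## Age-of-onset model

The onset of a parameter is modelled as a Gaussian mixture over the
diseases showing it, with weights proportional to the parameter's
prevalence in each disease — prevalence is the only available linkage
between parameter and disease-level onset. Components with zero standard
deviation are point masses: they contribute to the closed-form mixture
mean but are excluded from grid evaluations of the density. Densities are
not truncated at age 0; inputs are means ± SD of reported onsets, and
truncation would break the closed-form mean identity `E[T] = Σ w_d μ_d`
used for validation. The early/late split assigns diseases with onset
mean strictly below the cutoff (default 20 years) to the early matrix,
the rest to late; diseases without onset are excluded with a warning. The
early/late correlation is the Pearson correlation of the two groups'
mean-prevalence profiles over the full parameter union, symmetric in the
groups and invariant to parameter order.

## Synthetic databases

The generator produces the statistical structure the tools exploit, at
the reference scale of 31 positive, 25 negative and 6 test diseases:

- **Positive diseases** carry every one of `core_size` (default 20)
  shared core parameters at high prevalence, Beta(5, 2) rescaled to
  percent (mean ≈ 71 %) — a group with frequent, overlapping features.
- **Negative diseases** carry disease-private parameters nobody else has
  (`private_size` = 5, Beta(2, 2), mean 50 %) — a heterogeneous control
  group — plus each core parameter with probability `background_rate` at
  low prevalence (Beta(2, 5)). Positive diseases carry private
  parameters too.
- **Common parameters** (`common_size` = 8, Beta(4, 8), mean ≈ 33 %) are
  carried by *every* disease, mimicking nonspecific findings such as
  fatigue. They are group-agnostic, hence carry no class signal, but they
  matter structurally: without them the control group is mutually
  orthogonal, every control-control and control-positive distance ties at
  exactly 1, and dendrogram structure above the positive cluster becomes
  arbitrary — an artifact real clinical data does not show.
- **Test profiles** blend `test_sources` = 3 randomly chosen reference
  diseases of the requested regime (parameter union, prevalences averaged
  and jittered by a truncated normal, SD 10 points). This emulates the
  realistic use case — a disease phenotypically akin to the database's
  groups — and gives negative-regime tests genuine overlap with the
  control group rather than an empty intersection. The true regime is
  returned out of band (sidecar file), never inside the profile.
- Onset means draw from an early (uniform 0.5–15 y) or late (25–65 y)
  component per `onset_early_fraction`; SDs uniform 1–8 y; patient counts
  uniform 20–500.

`background_rate = 0` makes the core — the only group-identifying
structure — disjoint between groups: clustering, CV separation and both
scores then recover the planted labels exactly (the capability the
acceptance tests assert). `core_size = 0` removes it entirely, leaving
the groups exchangeable: CV separation drops to chance (the residual
≈53 % reflects the 31:25 class imbalance pulling the regression bias
positive) and overlap scores centre on 50 on average. What passing these
tests does *not* show: real databases have correlated parameters, shared
aetiology across groups, curation noise and missing prevalences, none of
which the generator emulates; results on synthetic data demonstrate the
machinery, not clinical accuracy.

`generate_studies` partitions a disease's cohort into studies (each ≥ 1
patient) with binomially resampled prevalences, so the patient-weighted
merge of the studies is an unbiased estimate of the source profile — the
property the merging tests check.

## Numerical and interface choices

- Distances are clamped at 0 after `1 − s` to absorb −1e-16 cancellation.
- Prevalence validity is [0, 100] inclusive; TSV matrices round-trip to
  ≤ 1e-9 relative (6-decimal cells), JSON databases bit-exactly.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; identical seeds give byte-identical databases and CV reports.
- The CLI is a thin layer over the library: JSON-first output, `-o` for
  files, exit codes 0/1/2 (success/validation/usage), options logged at
  INFO with the library version.
- Problem sizes in tests and the acceptance script (56-disease reference
  databases, 20-seed null averages, ≤ 6-leaf oracle cases, 100-instance
  oracle sweeps) were chosen to exercise every code path at the scale the
  tools target while keeping the whole suite near-instant.

## Known limitations

- The overlap kernel is a design reconstruction; published scores from
  curated databases (e.g. specific diseases scoring 100 or 70) depend on
  database contents this package does not ship and are not reproduced.
- Spearman/Kendall distances use straightforward rank/concordance
  definitions; no tie-correction subtleties beyond scipy's defaults.
- Centroid linkage can invert; the Newick writer emits the tree as built,
  so inverted branches get negative lengths.
- The onset mixture ignores within-disease dependence between parameter
  onset and prevalence (unavailable in prevalence-only databases).
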