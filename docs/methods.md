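# Methods

## Scope and data model

gatescribe annotates cytometry expression matrices (cells × protein
markers, continuous intensities assumed compensated and
variance-stabilized upstream; `arcsinh_transform` with cofactor 5 is
offered as an explicit opt-in for raw mass-cytometry counts). The central
object is the marker table: per cell type an ordered list of marker
tokens, each a marker plus a level symbol (`+`, `m`, `-`, `*`) and a
combinator. Consecutive tokens suffixed `|` form an inclusive-or group
(at least one token holds), tokens suffixed `^` an exclusive-or group
(exactly one holds — for more than two tokens we read "exactly one", the
natural extension of the two-token case); unsuffixed tokens are
conjunctive. Markers of the universe absent from an entry are implicit
wildcards, since curated tables routinely omit uninformative markers. The
`hi`/`mid`/`lo` spellings are accepted and normalized to `+`/`m`/`-`.

## Level calling

Each marker is modeled independently by a univariate Gaussian mixture
p(x) = Σ φᵢ 𝒩(x|μᵢ,σᵢ) with G = 2 components, or G = 3 when any table
entry declares a medium level for the marker. Two variance
parameterizations: **E** (one shared σ, appropriate when the positive and
negative populations have similar spread) and **V** (per-component σᵢ).

EM details (all deliberate, documented choices — they make the fit fully
deterministic, so a seed is accepted only for interface uniformity):

- initialization: component means at the (i − 0.5)/G sample quantiles,
  uniform weights, all σᵢ at the pooled standard deviation;
- E-step in log space (`logsumexp`), M-step with a σ floor of 10⁻⁶ of the
  pooled σ to avoid variance collapse on near-duplicate data;
- convergence when the relative log-likelihood change falls below 10⁻⁸,
  capped at 500 iterations (non-convergence returns the best iterate with
  a warning — typical for unimodal noise channels, harmless in practice);
- components reported sorted by mean; numerically tied means are nudged
  apart by 10⁻⁹ to preserve the strict ordering invariant.

Cells are assigned to the component maximizing φᵢ𝒩(x|μᵢ,σᵢ); exact
posterior ties go to the lower-mean component (conservative toward `-`).
For equal weights and variances the G = 2 decision boundary is the
midpoint of the means, which the tests verify in closed form. The fit is
cross-checked against scikit-learn's `GaussianMixture` (`diag`/`tied`
covariances) in the test suite; the EM here is the implementation, the
sklearn fit only an independent oracle.

## Ranked set sampling

Cytometry channels are often strongly skewed, which drags EM components
into the heavy tail. As an optional preconditioner we build the fitting
sample by ranked set sampling with set size m = 2: per cycle, four points
are drawn **with replacement** (valid even when 4·n_cycles exceeds the
cell count), arranged into two ranked sets of two; the minimum of the
first set feeds the leftmost stratum, the maximum of the second the
rightmost. The stratum opposite the skew is used for fitting: rightmost
when the sample skewness g₁ = m₃/m₂^{3/2} (biased moment convention) is
positive, leftmost otherwise — skewness exactly 0 selects leftmost.
Defaults: n_cycles = min(N, 50 000), keeping the procedure O(N); ranking
uses exact values with stable order (no jitter). The mixing weights
estimated on the tail-biased sample are applied unchanged when scoring
all cells; we do not recalibrate them, accepting a weight bias that the
MAP boundary tolerates at the separations where RSS helps. RSS defaults
to on under variance mode V and off under E, where it is
counterproductive; both couplings are overridable.

## Dictionary matching

The table compiles to an ordered dictionary. Entry priority is the tuple
(number of `+`/`m` tokens, number of non-wildcard tokens, table order):
the first component is the substantive tie rule — prefer the annotation
asserting more expressed markers — and the remaining two are
deterministic tie-breakers added by this package. Expansion to concrete
signatures is lazy (entries are evaluated as predicates, vectorized over
all cells); full materialization, used by the brute-force test oracles,
is limited to ≤ 12 free markers because enumeration grows as 3ᵏ. A level
fixed outside a marker's domain (an `m` token on a two-level marker)
admits no signature, and empty expansions are reported, not fatal.

## Training

Signatures are computed for all markers; a marker is modeled with G = 3
iff some base population appears under all three labels
`<base>_<M>-`, `<base>_<M>mid`, `<base>_<M>hi`. Unordered cell-type pairs
are visited in lexicographic name order (the update rule makes output
order-dependent; fixing the order makes mining reproducible). Per pair, a
`DecisionTreeClassifier` (Gini, depth ≤ 3, min leaf 5 — shallow trees
suffice for 3-level ordinal features) is fitted on the ordinal encoding
`-` < `m` < `+`, and the marker with the largest total impurity decrease
wins. Markers with identical columns are perfect surrogates of one
another and receive equal credit, so redundant-marker ties resolve to the
first marker in matrix order; surrogate contributions beyond exact
duplicates are omitted. The winner enters whichever of the two entries
does not already constrain it, at the modal level of that type's cells
(modal ties break toward `+` over `m` over `-`); an existing symbol is
never overwritten. Updating each entry that lacks the marker — rather
than skipping the pair whenever either entry has it — is required for
three-variant designs (`-`/`mid`/`hi` populations of one base type over a
single marker): under the stricter guard the middle variant's entry would
stay empty forever, and its medium level would never be registered.
Reference cells labeled `unknown`/`unclassified` are excluded by default.
Cell types below a 20-cell floor trigger a warning, and pairs no marker
separates are reported as indistinguishable.

## Annotation

Pipeline order: simple random sample (default 10% with a 500-cell floor —
the floor is this package's safeguard for tiny inputs); dictionary build;
signature matrix on the sampled cells only; matching; refinement. Without
the reject option, matched cells train a k-NN (k = 10, Euclidean distance
over the table's markers in intensity space — not signature space) that
labels unmatched and unsampled cells; vote ties break to the label of the
single nearest neighbor. With the reject option, mutual nearest neighbors
(each cell in the other's k-neighborhood, k = 10) between matched (A) and
unmatched-but-sampled (U) cells define the confident sets: a matched cell
with more than k/2 MNN pairs into U is ambiguous and gets re-queried; an
unmatched cell with zero MNN pairs into A is a confident unknown, keeps
the reserved label `unknown`, and joins the k-NN training set. Unsampled
cells are pure k-NN queries; they do not participate in the MNN stage.
The > 0.5 ambiguity proportion and k = 10 are this package's defaults
(configurable); determinism is guaranteed per seed, with per-marker RSS
substreams derived by offsetting the seed.

When every cell is sampled and matched, refinement has an empty query set
and the output equals direct signature matching exactly.

## Evaluation

Accuracy is the percentage of exactly matching labels; precision, recall
and F1 are one-vs-rest per reference label with 0 substituted for
zero-denominator fractions (the conservative convention); the summary
statistic is the median per-label F1, reported both with and without the
`unknown`/`unclassified` class since either convention is defensible.

## Synthetic data

The generator inverts the annotation model: cell type ~ stated
proportions, a concrete signature uniform over the type's expansion (so
wildcard and operator branches are all exercised), marker values Gaussian
per level. Standard conditions used across the tests and the acceptance
script: 4 types (T/B/monocyte/NK) at 40/30/20/10% over 6 markers (two of
them pure wildcards), adjacent level means 6σ apart (σ = 0.3), n = 20 000
for the training and end-to-end checks, n = 5 000 for single-marker
mixture recovery, and a planted population at ≥ 8σ on one marker (10% of
cells) for reject-option checks. At 6σ separation a midpoint-threshold
oracle recovers the generating labels to ~99.8% (the residual is boundary
mass), which is what makes the ≥ 95%/≥ 99% test thresholds meaningful
rather than noise-dominated.

What the generator does not emulate: spillover, doublets, debris,
acquisition drift, batch effects, or the raw-scale skewness removed by
upstream transforms. Passing tests therefore demonstrate correctness of
the algorithms under the stated mixture model, not performance on any
particular instrument's output.

## Known limitations

- G per marker is driven by the table (or label suffixes), never
  estimated from the data.
- The variance mode (E vs V) must be chosen by the user per dataset.
- FCS support is read-mostly and minimal: float/double list mode,
  no integer bit masks, no keyword preservation on write.
- The wide table dialect cannot express `|`/`^` groups; use the compact
  dialect for conditional entries.
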