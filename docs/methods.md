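# Methods

## Problem and model

`sigpath` predicts which of *d* signaling pathways each protein belongs to,
links the predictions into pathway networks through experimental
protein-protein interactions (PPIs), and summarizes pathway overlap as
static cross-talk maps.

A protein may belong to several pathways at once, so the task is
multi-label. We use the **label-combination (label powerset)** reduction:
every distinct label set observed in training — e.g. {TCR, BCR} — becomes
one class of an ordinary multi-class problem, and a single classifier is
trained over these combination codes. The alternative binary reduction
would need *d* classifiers and cannot represent label correlations; the
powerset method captures them directly at the cost of never being able to
emit a combination unseen in training (an inherent property of the method,
not a bug: the classifier's output space is exactly the observed
combinations).

Each protein is described by up to two **instances** over one binary
GO-term feature space:

- the *target instance* encodes the protein's own GO annotations;
- the *homolog instance* encodes the pooled GO annotations of its sequence
  homologs (harvested with a permissive E-value cutoff of 10, so even
  remote homology contributes terms).

The feature vocabulary *S* is the union of both term sets over all training
proteins, sorted lexicographically for determinism; component *k* of an
instance vector is 1 iff term *k* belongs to the chosen term set. Both
instances enter training as independent examples carrying the same
combination code — this is the transfer-learning channel: homolog
annotations act as extra, noisier views of each class. Proteins with
neither own nor homolog annotations carry no signal and are removed
(the removal rule). At test time the two instances are scored separately,
since combining two predicted label *sets* into one has no canonical rule;
downstream stages accept either kind (or their intersection).

The classifier is a soft-margin SVM with the Gaussian kernel
`k(x, y) = exp(-gamma * ||x - y||^2)`. On binary vectors the squared
distance is the Hamming distance, so the kernel is a smooth monotone
function of annotation disagreement.

A reserved class *others* (label *d*+1, mutually exclusive with pathway
labels) makes the classification complete for proteins in none of the
modeled pathways. Its training examples are sampled without replacement
from annotated non-members, capped at the size of the largest pathway class
to limit imbalance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `gamma` | 1/\|S\| | Gaussian-kernel width; scaling by vocabulary size keeps typical kernel values in a useful range as \|S\| grows |
| `C` (`cost`) | 1.0 | SVM soft-margin cost |
| `evalue_cutoff` | 10 | maximum E-value for a retained homolog hit |
| `folds` | 10 | cross-validation folds |

Neither kernel hyperparameter is prescribed by the method itself; both are
exposed on every estimator and the defaults were chosen once as the
standard uninformed choices for RBF SVMs on high-dimensional sparse binary
data.

## Evaluation

Multi-label performance uses three metrics over the pooled out-of-fold
predictions (pooled, not averaged per fold, so each number is a single
ratio over all proteins):

- **exact match ratio** — fraction of proteins whose entire predicted label
  set equals the true set;
- **macro-average F** — unweighted mean of per-label F-measures;
- **micro-average F** — F-measure of counts pooled over all labels.

A label with neither true nor predicted positives has an undefined (0/0)
F-measure; such labels are *excluded* from the macro average rather than
scored 0 or 1, so classes absent from a small test set do not distort the
mean. Cross-validation folds are drawn at the **protein** level (seeded
uniform shuffle, contiguous split): both instances of a protein share a
fold, because instance-level splitting would leak a held-out protein's
annotations into training. Stratification by combination code is not
attempted since rare combinations are often singletons.

## Linking and cross-talk

A predicted component is linked to a pathway through experimental PPIs,
yielding two kinds of novel signaling PPIs: predicted–known (kind 1) and
predicted–predicted (kind 2). Linking is per-pathway and independent, so
one interaction may become a signaling PPI of several pathways — exactly
the overlap the cross-talk map measures. The cross-talk ratio of two
pathways is the Jaccard overlap of their element sets — component
accessions, or canonical (lexicographically ordered) edge pairs so an
interaction is never double-counted across orientations. The empty/empty
case is defined as 0. GO enrichment of a predicted set is the raw
percentage of the set annotated with each term (per ontology aspect,
top-10 reported by default); it is a descriptive proportion, deliberately
not a hypergeometric test against a background.

## Synthetic data

The generator plants the structure the method assumes and nothing more.
Each pathway owns a disjoint block of `n_signature_terms` signature GO
terms. A pathway protein carries each signature term of its pathway(s)
with probability `p_signal`, each of `n_background_terms` background terms
with probability `p_noise_term`, and with probability `p_multilabel`
belongs to one extra pathway (acquiring its signatures too). Every protein
has exactly one synthetic homolog (`H_<accession>`) whose annotation set is
the target set with per-term dropout `homolog_dropout` plus background
noise `homolog_noise` — evolutionary divergence as independent term noise.
PPI edges are Bernoulli draws: probability `ppi_within` inside a pathway,
`ppi_between` elsewhere. Background proteins carry only background terms
(at least one, so every record passes the removal rule) and form the
negative-class pool. `n_heldout_per_pathway` optionally plants *novel*
components: signaling proteins excluded from the membership table, the
synthetic analogue of candidate proteins whose pathway roles are not yet
curated; their planted labels are kept as ground truth for evaluating the
prediction stage.

Defaults (6 pathways × 100 proteins, 40 signature terms per pathway,
`p_signal` 0.9, `p_noise_term` 0.02, `p_multilabel` 0.2, `homolog_dropout`
0.2, 200 background proteins) describe a strongly but not perfectly
separable regime with a realistically degraded transfer channel. What the
generator does **not** emulate: the GO term dependency graph (real
annotations co-occur along ancestor paths), annotation depth imbalance
across proteins, multiple homologs of varying divergence, scale-free PPI
degree distributions, and correlated (rather than independent) annotation
noise. Tests passing on this corpus therefore demonstrate that the
implementation recovers planted structure under the model's own
assumptions — not that the method attains any particular accuracy on real
curated pathways.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical corpora, folds, negative samples and outputs.
- Prediction ties over combination codes resolve by the highest
  one-vs-rest decision value, then the lowest code — deterministic.
- Vocabulary, codebook and pathway label indices are ordered
  lexicographically; nothing depends on dict insertion order.
- Test-time GO terms unseen in training are dropped (the vocabulary is
  fixed by the training set); an all-zero projected vector is still scored
  and yields some trained code rather than an error.
- The homolog term set is not made disjoint from the target set: if a
  homolog shares the protein's own terms, the homolog instance legitimately
  repeats them.
- Undirected PPIs, self-interactions excluded; "NOT"-qualified GAF rows
  skipped per GAF semantics.
- Problem sizes in the test suite and the acceptance run (hundreds of
  proteins, a few hundred features, 10-fold CV) were chosen as the smallest
  sizes at which class structure, multi-membership and both instance
  channels are all exercised with stable statistics.

## Known limitations

- The powerset classifier cannot predict label combinations absent from
  training; rare true combinations in test data are necessarily missed.
- Metrics for the homolog instance are computed only over proteins that
  have homolog annotations (likewise for target); the two columns of a
  metrics report may therefore describe slightly different protein sets.
- The CLI does not persist fitted kernel state; `predict`/`run-all` refit
  from the (seeded, cheap) inputs, which keeps every artifact plain text
  and byte-reproducible.
- Cross-talk maps are static set overlaps; no temporal or spatial dynamics.
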