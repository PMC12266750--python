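# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `polygero`. It records design rationale; every
empirical number cited here is computed by the test suite or by
`scripts/acceptance.py`, never asserted from memory.

## Activity ingestion

A bioactivity record links a compound to a protein target with a pChEMBL
value, the negative base-10 logarithm of a molar potency (IC50, Ki, Kd,
EC50); pChEMBL 7 corresponds to 100 nM. Ingestion applies, in order:

1. **Potency floor** — records with pChEMBL < 5 (weaker than 10 µM) or with
   no pChEMBL at all are dropped. The bound is inclusive.
2. **Assay filter** — only binding (B) and functional (F) assays survive,
   restricted to inhibition-style standard types. The named types are Ki,
   IC50 and Kd; the allow-list is open-ended in practice, so the default
   set {Ki, IC50, Kd, EC50, Km, pA2} is a documented, configurable choice.
3. **InChIKey matching** — compounds match records on the full 27-character
   InChIKey of the compound or of its desalted parent; only when neither
   yields anything is a relaxed match on the 14-character connectivity
   skeleton used. Full-key matches always suppress relaxed matches.
4. **Cluster aggregation** — within each target cluster, the *minimum*
   pChEMBL over member-target records is taken, then binarized at
   pChEMBL ≥ 7 (inclusive). Cells with no surviving records are *missing*,
   a third state kept distinct from *inactive*.

Min-aggregation is conservative: a compound potent on one cluster member but
weak on another is scored inactive for the cluster. This sits oddly beside
the modeling assumption that binding one member implies engaging the
cluster; we implement min as specified and expose `max` as a config option
without claiming it is the intended semantics.

For prediction the ternary matrix is collapsed to 0/1 with missing → 0 by
default (unobserved activity treated as non-binding); the policy is recorded
in the output metadata and swappable, since the ternary state is preserved
internally.

## Target clustering

Targets are clustered at 0.5 pairwise sequence identity. Identity is
computed from a global alignment (match 1, mismatch 0, gap −1) as identical
positions divided by alignment length including gap columns — one fixed
convention, stated here because production clusterers offer several. The
clusterer is greedy and representative-based: sequences are processed
longest-first (lexicographic id tie-break), each joins the first cluster
whose representative it matches at ≥ threshold, else founds a new cluster.
This is deliberately not a reimplementation of a k-mer prefiltered
production tool: at desk scale (tens to hundreds of targets) exact pairwise
alignment is affordable, and real cluster tables can be imported via
`load_cluster_map` when fidelity to an external clustering matters.

## Rule models

Let `x_ic ∈ {0,1}` be the binarized activity of compound *i* on cluster
*c*, and `y_i ∈ {0,1}` its lifespan label (LS+/LS−). The three predictor
families are:

* single-cluster: `ŷ_i = x_ic` for one chosen *c*;
* count-threshold: `ŷ_i = 1[Σ_c x_ic ≥ N]`, N swept over 2…20. The wording
  "exceeds a threshold" is read inclusively (≥ N) for consistency with the
  inclusive potency thresholds; a strict mode exists;
* combination ("m in M"): `ŷ_i = 1[Σ_{c∈S} x_ic ≥ m]` for a cluster set S
  of size M (2…5 by default), all 1 ≤ m ≤ M. `m = M` is the conjunction.

Models are scored by precision, recall and the Matthews correlation
coefficient; MCC is the ranking criterion because lifespan screens are
heavily imbalanced (few LS+). Metrics with zero denominators are reported
as 0 with a degenerate flag rather than NaN. Ranking ties are broken by
precision, then recall, then the lexicographic cluster tuple, then m — a
fixed order chosen purely for reproducibility.

Exhaustive search over all clusters is combinatorially infeasible for
hundreds of clusters at M = 5 (~10⁹ rules), so the default pipeline first
selects geroprotector-target (GT) clusters — the top k = 10 clusters by
single-cluster MCC among those with at least `min_support = 3` active LS+
compounds — and enumerates combinations over those (2 550 rules for k = 10,
milliseconds of work). "Top-k by MCC with minimum support" operationalizes
a prominence criterion that is otherwise qualitative; it is our choice, and
an unrestricted search over all clusters remains available behind an
explicit budget override.

## Synthetic data

The generator plants a known "m in M" rule (default "2 in 3" over
{drd2, hrh1, htr6}) in a compounds × clusters matrix:

* activity on the rule's own clusters: Bernoulli(`rule_active_prob`,
  default 0.35). This parameter makes the planted LS+ base rate realistic
  (~28% for 2-in-3 at 0.35) — with only background activity the positive
  class would nearly vanish;
* activity elsewhere: Bernoulli(`background_active_prob`, default 0.1);
* the true label is the rule applied to the full activity row, then flipped
  with probability `label_noise_eps` (default 0.05), emulating biological
  and assay noise in lifespan calls;
* each cell is then observed with probability `observe_prob_rho`
  independently; unobserved cells are missing, the simplest faithful model
  of untested compound–target pairs. Labels are computed before masking, so
  partial observation creates exactly the incomplete-profiling regime that
  motivates the binding classifier.

Activity-record generation inverts ingestion: active cells emit one record
in [7, 10] per member target, inactive cells at least one record in [5, 7)
(extras anywhere in [5, 10) are harmless under min-aggregation), missing
cells none; decoy records that the filters must drop are mixed in. Only the
binarized state matters downstream, so uniform values within each band
suffice. Sequence families are built by per-position substitution (no
indels) from one random ancestor per family, so member–ancestor identity is
exactly `within_identity` and pairwise within-family identity is at least
`2·within_identity − 1`; this keeps ground-truth identity computable
positionally, independent of the aligner. SMILES libraries are enumerated
from a scaffold × substituent × tail template set and validated by RDKit at
generation time.

What the generator does **not** emulate: real pChEMBL value distributions,
assay heterogeneity, correlated missingness (real profiling is biased
toward popular targets), or real chemical space. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated noise model, not performance on real ChEMBL extracts.

## Masked multi-task classifier

The classifier head maps a standardized descriptor vector to per-target
binding probabilities. Hidden layer k receives the concatenation of the
input and all preceding hidden layers (DenseNet-like wiring); the output
layer sees everything. The loss is mean binary cross-entropy over observed
label cells only — missing cells contribute nothing to loss or gradient —
with probabilities clipped at 1e−7. The network is a compact numpy
implementation (manual backpropagation, Adam, full determinism from one
seed); its gradients are verified against finite differences in the test
suite. A graph-network molecular encoder is intentionally out of scope: the
head accepts externally computed embeddings concatenated to the
descriptors.

Defaults: two hidden layers of 64, Adam at 1e−3, 200 epochs, batch 128,
He-style initialization. These are ordinary choices for a small tabular
head. The RDKit descriptor panel (24 descriptors spanning size,
lipophilicity, polarity, flexibility, shape) is pruned by greedy removal of
pairs with |Pearson r| > 0.95 (zero-variance columns dropped first); Pearson
at 0.95 is our documented default where no canonical value exists.

Splitting is scaffold-aware: Butina clusters at Tanimoto 0.8 (Morgan radius
2, 2048 bits — the fingerprint scheme is tagged and swappable since no
canonical choice exists) are assigned whole, largest first, to whichever
partition is furthest below its 0.8/0.1/0.1 target. Grid search selects by
mean-over-tasks ROC-AUC on the **validation** partition by default;
selection on test scores is available behind an explicit flag because it
leaks held-out information into model choice — we reproduce it rather than
silently correct it, and say so here.

## Screening funnel

Stages run in fixed order: probability binarization (inclusive at 0.5;
cluster bit = max over member-task bits) → known-compound exclusion
(14-character InChIKey skeletons, salt/stereo-insensitive) → the
polypharmacology rule (≥ 2 of {drd2, hrh1, htr6}) → QED floor (default
0.5; QED itself is delegated to the published desirability-function
implementation) → Butina diversity selection of k = 16 picks, one
representative per cluster in descending cluster size, the representative
being the member with the highest mean predicted probability over the
required clusters (ties by id). The probability threshold, the QED cutoff
and the within-cluster representative rule are all documented proxies: the
upstream selection they emulate involved unstated cutoffs and human
judgment, so the funnel exposes its accounting (the per-stage survivor
ledger) rather than claiming to reproduce a manual curation.

Exclusion and the polypharmacology rule are per-compound predicates, so
their order cannot change the final selection; a test asserts this
commutativity.

## Numerical conventions and degenerate inputs

* All thresholds (pChEMBL 5 and 7, identity 0.5, Tanimoto 0.8, probability
  0.5, count N, rule m) compare inclusively.
* Tanimoto of two empty fingerprints is defined as 1.0.
* A metric with a zero denominator is 0.0 plus a degenerate flag.
* A loss over zero observed cells is 0.0 plus a degenerate flag.
* Butina tie-breaks: initial neighbor-count order, then input order.
* Sort stability: all rankings use mergesort and fully specified keys, so
  output files are byte-identical across runs at a fixed seed.

## Problem sizes

Tests and the acceptance script run at desk scale chosen to exercise every
code path with comfortable statistical margins: rule recovery at 800
compounds × 30 clusters × 20 replicates; noise sweeps at four levels × 20
seeds; the classifier at 500 compounds, 10 descriptors, 4 tasks; splits and
funnels on 100–150-molecule template libraries. The full suite runs in well
under a minute.

## Known limitations

* The greedy identity clusterer is order-dependent by design (deterministic,
  but not the fixed point of any global objective); import real cluster
  tables when that matters.
* No statistical significance testing of MCC differences between rules and
  no multiple-testing correction over the combinatorial search — the
  ranking is descriptive, and with thousands of rules the top MCC on small
  label sets is optimistically biased.
* The classifier head sees descriptors only; without a learned structural
  encoder it cannot be expected to match graph-network accuracy on real
  data, and no such claim is made.
* ADMET properties are outside the funnel entirely.
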