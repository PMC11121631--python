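# Methods

## Model

The predictor is a deep N-to-1 convolutional neural network. An input
sequence of N positions, each a D-dimensional feature vector, passes
through:

* an **input kernel**: at every position *i*, the flattened window of
  2c + 1 position vectors (zero vectors beyond either end) is mapped
  through two dense layers — (2c+1)·D → H → S — with a sigmoid after
  each. Weights are shared across positions (convolutional weight tying);
  the second layer is a kernel of size 1.
* **k hidden kernels** of the same two-layer form over windows of
  2γ + 1 intermediate state vectors: (2γ+1)·S → H → S. The k kernels
  share their width hyperparameters but not their weights.
* **average pooling**: the element-wise mean of the last kernel's S-wide
  outputs over exactly the N true positions (padding never enters the
  mean). This is the step that makes the output independent of N.
* a **fully connected head**: S → F (sigmoid) → 8 (softmax).

Layer accounting: the two kernel layers plus the fully connected hidden
layer give 3 hidden layers at k = 0; each hidden kernel adds 2, i.e.
3 + 2k in total.

All arithmetic is float64 numpy. Gradients are exact and analytic;
backpropagation distributes the pooling gradient as 1/N to every
position and scatters window gradients back through the zero-padded
convolution. A trace/parameter version fingerprint rejects gradients
computed from a stale forward pass. Correctness is checked against
central finite differences (h = 1e-5); per-element relative errors use a
denominator floor of 1e-4 because below that scale the comparison is
dominated by finite-difference round-off (absolute noise ~1e-10), not by
the gradient itself.

The loss is the relative entropy between the one-hot target and the
softmax output, which reduces to cross-entropy −log p[target]; p is
floored at 1e-12.

## Encodings

The residue alphabet has 21 symbols: the 20 standard amino acids plus
`X`, to which every ambiguity/nonstandard code (B, Z, J, U, O, `*`, and
any unknown letter) collapses on input. One-hot encoding is therefore 21
wide. Profile encoding is 22 wide: per query position, the frequency of
each of the 21 residue symbols plus the gap frequency over all MSA rows,
after which the query's own residue column is *clipped* to 1. Clipping
guarantees the query signal at full strength while homolog information
is preserved in the remaining (un-renormalized) frequencies, so every
entry stays in [0, 1]. Profiles are indexed by query positions: columns
where the query is gapped (homolog insertions) are dropped. When a run
mixes records with and without MSAs, one-hot matrices gain a zero gap
column so all inputs share width 22.

## Dataset protocol

1. **Validity filter**: keep records that carry a localization label and
   are at least 30 residues long (shorter chains behave like peptides).
2. **Homology reduction**: greedy scan in input order; each surviving
   record eliminates every later record whose pairwise e-value is ≤ the
   threshold (default 0.001). Exact duplicate sequences are always
   removed. The scan order is the documented, deterministic input order.
   The built-in similarity backend scores a Smith–Waterman alignment
   (BLOSUM62, gap open 11, extend 1, via Biopython) and converts the
   score S to a Karlin–Altschul e-value E = K·m·n_db·exp(−λS) with the
   published gapped-BLOSUM62 parameters λ = 0.267, K = 0.041 and a
   database-size term n_db = set size × mean length. An adapter over
   tabular output of an external all-vs-all BLAST run is provided for
   real corpora; the built-in scorer is not BLAST and its e-values are
   desk-scale approximations, adequate for enforcing and auditing the
   threshold on small sets (an exhaustive all-pairs audit utility is
   included).
3. **Interleaved 3:1:1 split**: position i goes to training when
   i mod 5 ∈ {0, 1, 2}, to test when 3, to validation when 4. For
   n = 11,825 this gives exactly 7095/2365/2365. The split is
   deterministic in the post-reduction record order.

Multi-location proteins are out of scope: every record carries at most
one label, and the label parser accepts only the eight canonical class
names (case-insensitive, spaces/underscores interchangeable).

## Training and model selection

Per-example SGD (minibatch size 1 by default) with a constant learning
rate, epoch-wise reshuffling from a seeded stream, and a validation
checkpoint every `checkpoint_every` epochs (default 10). The default
schedule of 5000 epochs yields exactly 500 checkpoints. The selection
metric is overall accuracy Q on the validation set; `select_best` takes
the n highest-accuracy checkpoints with ties broken toward the earlier
epoch. Momentum, weight decay and minibatching are exposed with inert
defaults (0, 0, 1). Runs are bitwise reproducible from the seed: the
parameter init and the shuffle stream are spawned from one SeedSequence.

The deployed predictor is an unweighted probability-averaging ensemble of
the selected checkpoints of several architectures — canonically the 6
best from each of 4 configurations, 24 members. Majority voting is
available as an alternative rule. Argmax ties always resolve to the
lowest class index in the frozen order (Other, Cytoplasm, GolgiApparatus,
Membrane, Mitochondrion, Nucleus, Plastid, Secreted).

Defaults: learning rate 0.015 (the 0.01–0.02 range is typical for this
architecture family), input semi-context c = 5, hidden semi-context
γ = 8, H = S = F = 8. Grid search over (architecture, schedule) cells is
provided; each cell is independently seeded and cell failures are
recorded without aborting the grid.

## Evaluation

From the 8×8 confusion matrix Z (rows observed, columns predicted), each
class i gets one-vs-rest counts TP = Z_ii, FP = Σ_{j≠i} Z_ji,
FN = Σ_{j≠i} Z_ij, TN = rest, and the metric set Spec = TP/(TP+FP),
Sens = TP/(TP+FN), Acc = (TP+TN)/total, MCC, F1 = 2·Spec·Sens/(Spec+Sens).
Note that "Spec" in this tool family's reports is precision (positive
predictive value), not textbook specificity; the latter, TN/(TN+FP), is
additionally reported as `specificity_tn`. Any metric whose denominator
is zero is defined as 0. Overall accuracy is Q = trace(Z)/ΣZ, which
equals Σ_i TP_i / total.

## Synthetic data

The generator stands in for a real annotated corpus. Each class carries a
short planted motif on an i.i.d. background (uniform over the 20 standard
residues by default); mock MSAs are point-mutated copies of the query
(substitution rate μ, gap rate μ/4, no insertions, query unmutated as row
0); near-duplicate planting with a ground-truth map exercises homology
reduction. All streams derive from a single seed via named SeedSequence
children, so each artifact is independently reproducible.

Defaults were chosen once to make the planted signal realistic *and*
recoverable at desk scale: 4 classes × 50 sequences, lengths 30–45,
8-residue motifs built from disjoint residue pairs (W/C, H/M, F/Y, P/G,
K/R, D/E, N/Q, T/S — A, I, L, V remain background-only), motif noise
ε = 0, 8 MSA rows at μ = 0.1. An 8-mer motif on a 30–45-mer occupies
roughly a fifth of the sequence; with 5-mer motifs on longer sequences
the signal-to-background ratio is too low for the small-budget trainings
used in the test suite to converge reliably.

What the generator does **not** emulate: realistic amino-acid
composition, positional dependence, domain structure, evolutionary
covariation between MSA rows (rows are independent mutations of the
query), or the heavy class imbalance of real localization corpora.
Consequently, a passing learnability test shows that the architecture,
gradients, training loop, selection and ensembling work end-to-end on a
signal that genuinely requires windowed convolution — it says nothing
about accuracy on real proteins.

## Demonstration scale and numerical choices

The canonical demonstration (`n1loc.workflows.learnability_experiment`)
trains four minimal-depth configurations (c = 2…5, k = 0, H = S = F = 16)
for 200 epochs with learning rate 0.1 and momentum 0.9, keeps the 6 best
checkpoints of each and averages the 24 members. These sizes were chosen
so the whole run takes tens of seconds on one CPU while the ensemble
reliably exceeds 90% validation accuracy across seeds. Two numerical
facts shaped the choices:

* With sigmoidal units, small (Glorot-style) initialization and mean
  pooling, signal variance shrinks roughly an order of magnitude per
  two-layer kernel; the minimal k = 0 architecture therefore learns far
  faster at small scale than deeper stacks, and momentum markedly
  shortens the initial plateau. Deeper stacks (k ≥ 1) train correctly
  (their gradients are exact) but need epoch budgets closer to the full
  5000-epoch schedule to break through.
* Class signal must be carried by motifs, not composition, for context
  windows to matter; the test suite includes a composition-identical
  two-class setup (motifs WWC vs CWW) under which a γ = 0 network is
  provably capped at chance.

Initialization is uniform in [−r, r] with r = √(6/(fan_in+fan_out)) and
zero biases. Softmax is computed with max-subtraction; sigmoids use the
numerically stable piecewise form. Model files (`.npz`) round-trip every
float64 bit-exactly and carry a format-version tag that is checked on
load.

## Known limitations

* The built-in pairwise scorer approximates BLAST statistics; on real
  corpora an external BLAST run through the tabular adapter is the right
  backend.
* Training is single-threaded pure numpy: adequate for the desk-scale
  experiments here, not for a 11,825-protein corpus at 5000 epochs.
* Multi-location proteins, GO-term mapping from free-text annotations,
  and PSI-BLAST profile generation are out of scope; profiles are
  accepted from externally produced alignments.
* The 5-fold cross-validation driver assigns folds by the same
  interleaving rule but no fold-level results on real data are claimed.
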