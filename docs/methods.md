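# Methods

## Problem and model

`capsmhc` predicts whether a short peptide (8–15 residues) binds a given
MHC class I molecule, taking both sequences as input (a pan-specific
model: one network covers all alleles). The architecture has four stages:

1. **Encoding.** Each sequence is encoded per residue with a substitution
   matrix (BLOSUM62 by default; BLOSUM80 and min–max-normalized variants
   are selectable). The alphabet is fixed at 23 symbols — the 20 standard
   amino acids in the conventional BLOSUM publication order, then B, Z, X;
   the stop column of published 24-column tables is dropped. Peptides
   become 23 × 15 matrices and MHC sequences 23 × 385 matrices; columns
   beyond the true sequence length hold an all-zero padding vector
   (zeros are neutral under the summed convolutions that follow; an
   "encode-as-X" padding mode is exposed for comparison). Sequences longer
   than the fixed width are truncated at the C-terminus. The MHC width of
   385 is a configurable constant: the package does not prescribe which
   MHC region the allele table should contain, only that the table be
   internally consistent.

2. **Feature branches.** Two independent, pooling-free convolution–
   attention stacks map the encoded inputs to 20 × 11 latent tensors.
   The peptide branch is one valid 1-D convolution (width 3, stride 1,
   32 channels), a position-wise attention unit, then two more
   convolutions (widths 2/2, landing on 20 channels × 11 positions);
   the MHC branch is two strided convolutions (width 5/stride 5, width
   5/stride 3), attention, then two more convolutions (3/2 and 2/1).
   The 20 × 11 latent contract is the invariant; the kernel geometry is
   configuration, not architecture. Attention computes one score per
   position from a learned linear map over channels, softmaxes over
   positions (nonnegative weights summing to 1 per sample) and rescales
   the features. The score map is initialized to zero so attention starts
   exactly uniform — in practice this markedly stabilizes training across
   random initializations, because no peptide position is starved of
   gradient before the map is learned.

3. **Capsule fusion.** The two flattened latents form two input capsules
   u_0, u_1 ∈ R^220. Learned matrices W_ij produce prediction vectors
   û_{j|i} = W_ij u_i for each of J output capsules (J = 16, dimension
   D = 16 by default). Dynamic routing with r = 3 iterations combines
   them: logits b_ij start at zero; each iteration takes couplings
   c_i· = softmax_j(b_i·), forms s_j = Σ_i c_ij û_{j|i}, squashes
   v_j = (‖s_j‖²/(1+‖s_j‖²)) · s_j/‖s_j‖, and updates
   b_ij += û_{j|i}·v_j (no update after the final iteration; the returned
   couplings are the ones that produced the returned v). The squash norm
   is stabilized by dividing by (‖s‖ + ε), ε = 1e-8, so s = 0 maps to
   v = 0. With r = 1, routing reduces to uniform couplings 1/J; with
   J = 1 it is vacuous — both serve as closed-form test oracles, alongside
   an independently written triple-loop reference implementation.

4. **Predictor.** The output capsules are flattened and passed through
   three fully-connected layers (128/64/32, ReLU) and an output layer.
   Sigmoid output is the default; softmax (two units, probability of the
   binder class) and tanh (affinely rescaled by (t+1)/2) are selectable so
   every activation shares the [0, 1] scoring range that AUC and the
   500 nM threshold operate on.

Ablation switches: `routing=False` keeps the capsule transform but uses
uniform couplings throughout; `fusion="concat"` feeds the 440-dim
concatenated latents directly to the predictor; `fusion="conv"` runs one
width-3 convolution over the position-concatenated latents (20 × 22 →
20 × 20) before the predictor. A structural assertion verifies no pooling
operation exists in any assembled graph.

## Training

The network and its gradients are implemented on a small in-package
reverse-mode autodiff engine over numpy arrays (`capsmhc/_autodiff.py`);
every primitive is verified against central-difference numerical
gradients. Optimization is adaptive-moment gradient descent (Adam,
lr 1e-3 default; the synthetic study below uses 2e-3), Glorot-uniform
initialization with a configurable seed, zero biases, batch size 100.
Losses: mean squared error on transformed affinities for IC50-valued
data, binary cross-entropy for labelled data (`loss="auto"` picks by
target type). Optional early stopping monitors a held-out fraction of
the training set with patience 20.

Affinity handling follows the IEDB benchmarking convention (a convention,
not a finding): regression targets y = 1 − log(IC50)/log(50000) clipped
to [0, 1], binder labels IC50 < 500 nM (strict). The five-fold protocol
shuffles once with a seed, splits into folds whose sizes differ by at
most one, fits on four folds and evaluates the fifth, and reports the
arithmetic mean of per-fold metrics as the headline number, followed by
an optional independent-test evaluation of a final model fitted on all
training records.

Undefined metrics (zero denominators, single-class strata, n < 2) are
reported as NaN and propagated as missing, never coerced to zero.
Spearman correlation uses the tie-free shortcut 1 − 6Σd²/(n(n²−1)) when
ranks are unique and rank-averaged Pearson otherwise; AUC is the
tie-corrected Mann–Whitney statistic, which equals trapezoidal ROC
integration exactly.

## Synthetic study conditions

The generator emulates anchor-driven class I binding: each synthetic
allele has a random 385-residue MHC sequence and three preferred residues
(weight 1) at peptide position 2 and at the C-terminal position
(optionally also P1). Peptide backgrounds are uniform over the 20
standard amino acids; lengths are uniform over 8–14. The latent score of
a peptide is its mean anchor weight plus Gaussian noise (sd 0.1 by
default); a per-allele offset maps the (1 − binder_fraction) score
quantile to the 500 nM target score (plus a 1e-6 margin so boundary
records fall strictly inside the binder class), making the realized
binder fraction match the request under continuous noise. IC50 values
are 50000^(1 − score), so the affinity transform inverts the generator
exactly and labels derived from IC50 agree with the latent scores.

Default study scale: 2 alleles × 1000 peptides, binder fraction 0.4,
noise sd 0.1. At this scale a 60-epoch fit takes under a minute on one
CPU and reaches held-out AUC above 0.90 (typically 0.90–0.97 depending
on the seed), and the permutation-importance profile ranks the two true
anchors top-2 for every peptide length. What
passing shows: the architecture can extract pairwise peptide–MHC binding
rules from sequence alone and the importance procedure recovers known
ground truth. What it does not show: performance on real immunopeptidome
data, whose motifs are softer, allele-imbalanced, length-biased and far
more numerous; the generator makes no attempt at realistic length or
abundance distributions.

## Interpretability

Permutation importance is computed within each peptide-length stratum:
for one position, the residues at that position are permuted across
records (then re-encoded — shuffling residues rather than encoded
columns keeps the shuffled data valid sequences; the two are equivalent
for a deterministic encoder), the records are rescored, and the score is
baseline AUC minus mean shuffled AUC over n_repeats = 10 seeded repeats.
The sign is kept (no absolute value), so a shuffle that helps shows as
negative. A constant column's permutation is an identity and scores
exactly zero. Heatmaps expose the fusion layer: the J × D output-capsule
matrix (with the full routing state u, W, û, b, c, s, v retained so v
can be re-derived from s through the squash), the reshaped 440-entry
concatenation latent, or the final conv-fusion feature map.

## Numerical and design choices

- Gradients flow through all routing iterations (no stop-gradient on the
  couplings), matching the original capsule-network formulation.
- Softmax is computed with a detached max shift (shift-invariance makes
  the gradient exact).
- BCE scores are clamped to [1e-7, 1 − 1e-7] inside the loss only.
- Routing iterations default to 3 and capsule counts to J = D = 16; all
  are configurable, and none of the published sources fix them.
- Unknown or ambiguous residues (U, O, J, *) are rejected by default to
  surface data errors early; a permissive mode maps them to X.
- Allele names are canonicalized to the `HLA-A*01:01` style; names that
  do not look like two-field HLA identifiers pass through upper-cased.
- Checkpoints are single `.npz` archives holding every parameter array
  plus the full estimator configuration and seed.

## Known limitations

- The one-CPU numpy engine is adequate for the synthetic study scale
  (thousands of records) but not for full benchmark corpora (hundreds of
  thousands); the architecture and protocol support such data, the
  compute budget here does not.
- The attention unit is the simplest position-wise form consistent with
  its convolution–attention lineage; richer attention variants are
  deliberately out of scope and the unit is documented as replaceable.
- With very few records per allele the per-allele calibration quantile is
  coarse, and with noise_sd = 0 ties can push the realized binder
  fraction away from the request (a warning is emitted beyond 0.1).
- Capsule outputs are not L2-normalized before the predictor; their norms
  already lie in [0, 1) by the squash bound.
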