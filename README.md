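# capsmhc

Pan-specific prediction of peptide binding to MHC class I molecules from
sequence alone, built around a capsule-network fusion of peptide and MHC
representations, with a synthetic anchor-motif data generator and a
permutation-importance interpretability procedure.

## Who this is for

Immunoinformaticians working on epitope discovery who want a binding
predictor that (a) takes the MHC sequence as input, so one model covers
all alleles including rare ones, (b) models the peptide–MHC *complex*
rather than concatenating independently learned features, and (c) can
explain which peptide positions its predictions rely on.

## The model

Peptides (8–15 residues) and MHC sequences are encoded per residue with
BLOSUM62 over a fixed 23-symbol alphabet into 23 × 15 and 23 × 385
matrices. Two pooling-free convolution–attention branches map these to
20 × 11 latent tensors. The flattened latents become two input capsules
u_i ∈ R²²⁰ that are fused into J = 16 output capsules of dimension 16:

    û_{j|i} = W_ij u_i
    s_j     = Σ_i c_ij û_{j|i}
    v_j     = (‖s_j‖² / (1 + ‖s_j‖²)) · s_j / ‖s_j‖

where the coupling coefficients c_ij are learned per example by dynamic
routing (softmax over agreement-updated logits, 3 iterations). A
three-layer fully-connected head with sigmoid output turns the capsules
into a binding score in [0, 1]. Scores are thresholded at the standard
IC50 < 500 nM binder convention; regression targets use
y = 1 − log(IC50)/log(50000). See `docs/methods.md` for the full account.

Ablation switches reproduce the model variants: `routing=False`
(uniform couplings), `fusion="concat"` (plain concatenation baseline),
`fusion="conv"` (convolutional fusion baseline), alternative encodings
(`blosum80`, normalized variants) and output activations
(softmax, tanh).

## Worked example

```python
import numpy as np
from capsmhc import (
    AlleleTable, CapsNetMHC, auc, generate_alleles, generate_dataset,
    importance_profile,
)
from capsmhc.model import records_to_Xy
from capsmhc.simulate import allele_table_entries

# two synthetic alleles with anchors at P2 and the C-terminus
models = generate_alleles(2, seed=42, noise_sd=0.1)
data = generate_dataset(models, n_per_allele=1000, binder_fraction=0.4,
                        noise_sd=0.1, seed=42)
table = AlleleTable(allele_table_entries(models))
pairs, y, labels = records_to_Xy(data.records)

rng = np.random.default_rng(42)
idx = rng.permutation(len(pairs))
train, test = idx[:1600], idx[1600:]

est = CapsNetMHC(allele_table=table, loss="bce", epochs=60, lr=2e-3,
                 random_state=42)
est.fit([pairs[i] for i in train], labels[train].astype(float))
scores = est.predict([pairs[i] for i in test])
print(f"held-out AUC = {auc(scores, labels[test]):.3f}")
```

```
held-out AUC = 0.967
```

The model separates binders from non-binders on unseen peptides (AUC
0.967 against the 500 nM labels; 0.5 would be chance). Asking which
peptide positions the model relies on recovers the generator's anchors:

```python
from capsmhc import BindingRecord
from capsmhc.interpret import top_positions

test_records = [BindingRecord(data.records[i].peptide, data.records[i].allele,
                              "binary", float(labels[i])) for i in test]
profile = importance_profile(est, test_records, n_repeats=10, seed=42)
for k in sorted(profile["length"].unique()):
    print(k, top_positions(profile, k, 2))
```

```
8 [2, 8]
9 [2, 9]
10 [2, 10]
11 [2, 11]
12 [12, 2]
13 [2, 13]
14 [2, 14]
```

For every peptide length, the two most important positions are P2 and
the C-terminal position — exactly the anchors the generator planted.

A command-line surface wraps the same pipeline:

```bash
capsmhc simulate --seed 42 --out run/
capsmhc train --seed 42 --data run/dataset.anthem.tsv --dialect anthem \
              --alleles run/alleles.fasta --out run/model/
capsmhc explain --model run/model/model.npz --data run/dataset.anthem.tsv \
                --dialect anthem --out run/explain/
```

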