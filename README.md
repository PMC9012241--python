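# dattprot

Interpretable double-scale attention for protein sequence classification
(the DAttProt architecture), with a planted-motif synthetic benchmark.

## The problem

Enzyme function prediction assigns Enzyme Commission (EC) classes to protein
sequences. Beyond accuracy, one wants to know *where* and *at what length
scale* the evidence sits: functional motifs are variable-length
sub-sequences, and a classifier that can point at them is far more useful to
a biologist than a black box. `dattprot` is for researchers who want a
sequence classifier whose attention is a proper probability distribution
over (motif length scale, sequence position) — directly inspectable and
testable against annotations.

## The model

A transformer encoder trunk (pre-trainable with a masked-LM objective on
unlabeled protein sequences) produces per-position features
`F_global ∈ R^{l×f}`. 1-D convolutions at kernel sizes `S_k ∈ {5, 10, 20}`
extract features at several spatial scales. At each position `j`, a central
vector averages the global and all scale features,

    F_cent^j = (F_global^j + Σ_k F_{S_k}^j) / (N+1),

and each scale's *agreement* is the scaled dot product
`A_kj = F_{S_k}^j · F_cent^j / √f`. One joint softmax over all `N·l` scores
yields the **double-scale attention matrix** `W` with `ΣΣ W = 1`:
`W_kj = p(att_space = S_k, att_pos = j)`. Its column sums form the
positional margin `v_j = Σ_k W_kj`. Conditional weights `W_kj / v_j` mix the
scale features position-wise; a shared linear+softmax head gives positional
class distributions `C ∈ R^{l×M}`, aggregated by

    p_d = Σ_j C_jd · v_j .

Training minimizes `−log p_y` with AdamW. An annotated region *matches* the
attention matrix when the highest-attention kernel at its middle position is
the kernel closest to its length and its middle margin weight exceeds 1.5×
the sequence average — the motif-discovery criterion, scored against a
length-preserving permutation baseline.

## Worked example

```python
import numpy as np
from dattprot import (MaskedLMPretrainer, DAttProtClassifier,
                      two_class_benchmark, generate_dataset)
from dattprot.benchmark import pretrain_corpus_config

# unlabeled corpus for self-supervision, labeled planted-motif benchmark
corpus, _ = generate_dataset(pretrain_corpus_config(8))
records, split = generate_dataset(two_class_benchmark(seed=10))
X = [r.sequence for r in records]
y = np.array([r.class_label for r in records])
tr, te = split["train"], split["test"]

pre = MaskedLMPretrainer(max_epochs=3, peak_lr=1e-3, warmup_steps=100,
                         random_state=0)
pre.fit([r.sequence for r in corpus])
print(f"masked-LM held-out CE: {pre.heldout_loss(X[:200]):.3f}"
      f"  (uniform baseline ln 22 = {np.log(22):.3f})")

clf = DAttProtClassifier(max_epochs=8, initial_lr=1e-3,
                         early_stop_val_acc=0.98, val_every_batches=8,
                         pretrained_trunk=pre.trunk_state_, random_state=0)
clf.fit([X[i] for i in tr], y[tr],
        X_val=[X[i] for i in split["val"]], y_val=y[split["val"]])
print(f"test accuracy: {clf.score([X[i] for i in te], y[te]):.2f}")

obs, base = clf.match_rate([X[i] for i in te],
                           [records[i].annotations for i in te])
print(f"motif match rate {obs:.2f} vs permutation baseline {base:.3f}")
```

Typical output (seeded as above):

```
masked-LM held-out CE: 2.895  (uniform baseline ln 22 = 3.091)
test accuracy: 1.00
motif match rate 0.31 vs permutation baseline 0.011
```

The held-out cross-entropy below ln 22 shows the trunk learned real token
structure; the match rate far above its permutation baseline shows the
attention matrix concentrates on the planted motifs rather than random
positions.

A CLI mirrors the library: `dattprot simulate | pretrain | finetune |
predict | explain | evaluate` (see `--help`; configs under
`src/dattprot/configs/`, including the full-scale 6-layer setting).

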