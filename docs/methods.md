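# Methods

## Model

`dattprot` implements a double-scale attention architecture for protein
sequence classification (the DAttProt design). The pipeline, for an input of
`l` token positions and hidden dimension `f`:

1. **Tokenization.** Sequences use the 22 residue tokens (20 standard amino
   acids plus selenocysteine U and pyrrolysine O) and two sentinels, MASK and
   PAD — 24 ids total, assigned in sorted residue order for stability.
   Ambiguity codes carry no ids: each `B` is re-drawn as D or N with equal
   probability on every encoding pass (likewise `Z` → E/Q), and `X` maps to
   MASK, since both denote an unknown residue to be inferred from context.
   Any other letter is an error. Sequences longer than `l` contribute a
   contiguous window (uniformly random in training, leading in evaluation,
   so that evaluation and the interpretability coordinates are
   deterministic); shorter ones are PAD-suffixed.

2. **Embedding.** `S[j] = sqrt(f) * E[token_j] + PE[j]`, with the sinusoidal
   positional encoding `PE[j, 2i] = sin(j / 10000^(2i/f))`,
   `PE[j, 2i+1] = cos(j / 10000^(2i/f))`. PAD rows are exactly zero — no
   embedding, no positional term, no gradient. When the configured token
   embedding width differs from `f` (the full-scale setting embeds at 16 and
   runs 512-dimensional encoders), a learned linear projection bridges the
   two before `PE` is added at width `f`; the projection is required for
   those dimensions to compose and is part of the transferable trunk.

3. **Encoder stack.** `n_layers` post-norm transformer encoder layers:
   multi-head scaled dot-product self-attention (`d_k = d_v = f/h`) and a
   position-wise feed-forward network, each wrapped in residual + layer
   normalization. Attention logits toward PAD keys are set to −inf before
   the softmax, and PAD output rows are re-zeroed after every layer, which
   makes the class distribution exactly invariant to appended padding.
   Feed-forward inner dimension is `4f` with GELU (both unexceptional
   transformer conventions adopted here as defaults); dropout 0.1 applies
   globally in training mode only.

4. **Multi-scale convolutions.** For each kernel size `S_k` (default
   {5, 10, 20}, chosen to bracket common annotated-motif lengths), a stride-1
   1-D convolution with `16·S_k` output channels runs over the encoder
   output. Same-length output uses the left-of-center window convention:
   output row `j` covers rows `j − ceil((S_k−1)/2) … j + floor((S_k−1)/2)`
   (deterministic for even kernels). The raw output is divided by
   `sqrt(S_k)` against variance growth with window size, then GELU-activated
   and linearly projected into a shared agreement subspace. The subspace
   dimension defaults to `f` so that the unprojected encoder output can
   participate in the agreement average; it is exposed as a configuration
   knob because a much smaller subspace (e.g. 16) is also coherent with the
   published channel plan, and the two readings cannot both hold at once.

5. **Feature agreement.** At each position `j` the central vector is the
   mean of the encoder vector and all `N` scale vectors. Each scale's
   agreement score is its dot product with the central vector divided by
   `sqrt(f)` (Transformer-style scaling; a divisor of `f` is available via
   `agreement_divisor="dim"` since the typeset formula is ambiguous between
   the two). Including the encoder output in the central vector is the
   default; `include_global=False` provides the ablation.

6. **Double-scale attention matrix.** All `N·l` agreement scores go through
   one joint softmax (PAD columns carry −inf sentinels and end with exactly
   zero mass), reshaped to `W ∈ R^{N×l}` — a joint probability distribution
   over (spatial scale, position). Column sums form the positional margin
   `v`. Conditional weights `W_kj / v_j` (guarded by eps = 1e-12) mix the
   scale features position-wise into `F_mixed`; each real row of `F_mixed`
   is a convex combination of the scale vectors at that position. The
   formula sheet for the mixture admits a reading in which positions are
   also summed out, but that contradicts the declared `l×f` shape of the
   mixed features, so the position-wise reading is implemented.

7. **Classification.** One shared linear layer plus softmax per position
   yields `C ∈ R^{l×M}`; the final class distribution is the expectation of
   the positional rows under the margin, `p_d = Σ_j C_jd · v_j` (law of
   total probability over positions). The training loss is the sequence-
   level cross-entropy `−log p_y`; per-position losses are not used, because
   `p` is the model's declared output probability.

## Training

**Masked-LM pre-training.** Per sequence, `max(1, floor(0.15 · eligible))`
positions are drawn without replacement from the non-PAD positions whose raw
token was not X; each is masked (p=0.8), replaced by a uniformly random
residue token (p=0.1), or kept (p=0.1 — the standard masked-LM remainder). A
position-wise linear decoder over the 22 residue tokens is trained with mean
cross-entropy at the selected positions. Uniform guessing scores ln 22 ≈
3.091. The learning rate ramps linearly to the peak over the warm-up steps,
then decays as `peak · sqrt(warmup/step)`; the decay shape after warm-up is
not pinned down by the published description beyond "transformer-like", so
inverse-sqrt is used and isolated behind the schedule interface.

**Fine-tuning.** AdamW (decoupled weight decay 1e-4) on the sequence-level
cross-entropy; learning rate `initial · 0.95^(iteration/100)`. The published
full-scale rates are 5e-5 peak for the 6-layer pre-training (1e-4 for
3-layer) and 1e-5 at the start of fine-tuning; these are shipped in
`configs/full.yaml` / `configs/full_3layer.yaml`. The desk-scale
configuration (`configs/desk.yaml`) keeps every mechanism but shrinks the
problem (l=128, f=64, h=2, 2 layers) and uses proportionally larger rates
(1e-3) because a 2-layer, 64-dimensional model on thousands of sequences
underfits badly at full-scale rates within desk-scale epoch budgets.
Best-validation weights are retained (loss for pre-training, accuracy for
fine-tuning), with an optional early stop once validation accuracy reaches a
set level. Desk-scale models can cross from chance to ceiling inside a
single epoch, so validation (and hence checkpoint selection and early
stopping) can be run every few optimizer iterations
(`val_every_batches`) instead of once per epoch; the bundled benchmark
validates every 8 batches and stops at 0.98 validation accuracy.

All training is deterministic for a fixed seed on one device: every random
choice (initialization, windows, ambiguity resolution, corruption, batch
order, dropout) draws from one seeded generator per run.

## Motif discovery

An annotation `[start, end)` is *matched* when (1) the kernel size with the
highest attention equals the kernel closest to the annotation length (ties
to the smaller kernel), and (2) the margin weight at the annotation's middle
position exceeds 1.5× the mean margin over the sequence's real positions.
The middle of an even-length annotation is the left-of-center position
`floor((start+end−1)/2)`. "Highest attention" defaults to the argmax over
scales of `W` at the middle position (`scale_choice="local"`); the
per-sequence reading (argmax of each scale's total mass) is available as
`"global"` since the published phrasing admits both. Matches are ranked by
`W` at the matched scale and middle position, descending, keeping the top
16. Annotations falling outside a chopped window are excluded from
denominators rather than counted as misses.

The match rate is calibrated against a length-preserving permutation
baseline: every annotation is relocated to a uniformly random valid start
and the rate recomputed, averaged over ≥ 20 rounds.

## Synthetic data

The generator emulates the structure the motif-discovery claim needs:
background residues drawn i.i.d. (uniform over the 20 standard residues by
default; a Swiss-Prot-like composition preset exists), class-determining
consensus motifs planted at uniform non-overlapping positions with
independent per-position substitution noise (substituting a *different*
residue), and ground-truth coordinates recorded as annotations. Default
motif lengths 5, 9 and 19 exercise the closest-kernel arithmetic across the
default scales {5, 10, 20}. Splits are stratified per class, 90:5:5 by
default.

What it does **not** emulate: homology structure, secondary structure,
realistic motif degeneracy (position-specific substitution preferences),
length/composition correlations, or Swiss-Prot class imbalance. Passing the
bundled benchmarks therefore demonstrates that the mechanisms work and that
the attention matrix recovers planted signal — not that the model attains
any particular accuracy on real enzyme data.

## Benchmark sizes and numerical choices

The package's own regression benchmarks (also behind
`scripts/acceptance.py`) use: a 2-layer, f=64, h=2, l=128 model; masked-LM
pre-training on 2,000 generated sequences for 3 epochs; fine-tuning on the
two-class benchmark (motif lengths 5 vs 19, insertion probability 1, 5%
noise; 1,000/100/100 split) for up to 8 epochs, validating every 8 batches
with early stop at 0.98 validation accuracy, repeated over 3 seeds; and a
20-round permutation baseline for the match rate, pooled over the three
fitted models (a single model's collapsed attention lands at one fixed
offset in every sequence, making its match rate nearly all-or-nothing, so a
multi-model mean is the stable statistic). These sizes were chosen as the smallest at
which every mechanism is exercised and the learning signals are
unambiguous.

Numerics: float64 throughout; softmax stabilized by subtracting the row
maximum; PAD handled by −inf sentinels so distributions are exactly
normalized over real positions; conditional mixing guarded by eps = 1e-12;
layer-norm eps = 1e-5; AdamW eps = 1e-8, betas (0.9, 0.999). Ties in
closest-kernel selection go to the smaller kernel; equal match scores rank
by earlier start.

**Attention collapse on fully-separable tasks.** The double-scale attention
is one joint softmax over N·l cells trained end-to-end through the
aggregation; when a single (scale, position) cell suffices to classify —
which is exactly the situation on a synthetic task whose consensus motif is
always present and unique to its class — the winner-take-all dynamic
concentrates essentially all mass on one such cell. That cell lies inside
the planted motif (which is why the match rate beats its permutation
baseline by a wide margin), but for a long motif it need not sit at the
exact middle position nor carry the motif-length kernel: any sufficiently
long sub-window is equally class-determining, so the winning scale is
seed-dependent. Short motifs do not show this degeneracy, because their
only fully-informative window is the motif itself, centered on its middle.
Consequently, middle-position match statistics for motifs much longer than
the shortest kernel are a property the synthetic benchmark cannot
demonstrate; on real data, where no sub-window is perfectly informative and
attention stays distributed, the published case studies report such matches
across sizes. This is documented here rather than patched, because every
candidate patch (softer agreement subspaces, earlier checkpoints,
per-sequence scale reading) either sacrificed the short-motif matches or
the classification accuracy.

## Known limitations

- The autodiff engine and layers are implemented in numpy for portability;
  throughput is CPU-bound and full-scale (512-dimensional, 300-epoch)
  pre-training is out of reach here by design.
- Random chopping discards context for sequences longer than `l`; attention
  coordinates refer to the evaluation window (leading `l` residues).
- The kernel set must be assigned manually; no self-adapting kernel sizes.
- Hierarchical (level-joint) decoding across EC levels is out of scope; one
  classifier is trained per task level.
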