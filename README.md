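# harnet

Human activity recognition (HAR) from body-worn inertial sensors:
a hybrid classifier that couples **squeeze-and-excitation (SE) channel
attention** over raw sensor channels with a **Transformer encoder whose
self-attention is sparsified** by a union of sliding-band and random
attention. It is aimed at researchers working with multichannel
accelerometer/gyroscope time series (smartphone or wearable IMUs,
typically 6 channels at 50–100 Hz) who want an attention-based
classifier that is cheap enough to train and audit on a CPU.

## The model

A recording is standardised per channel and cut into fixed-length
windows (default length 100 samples, 50 % overlap; a window's label is
the majority per-sample label). Each `C × L` window then flows through:

1. **SE channel attention** — each channel is squeezed to its mean
   `s_c = (1/L) Σ_t x_{c,t}`, the vector `s` passes through a two-layer
   bottleneck `g = σ(W₂ · relu(W₁ s + b₁) + b₂)`, and channel `c` is
   rescaled by the gate `g_c ∈ (0, 1)`. Informative channels are
   amplified before any feature extraction.
2. **1-D convolutional embedding** — same-length convolutions map the
   gated window to a `t × d` sequence (`t = L`, `d = d_model = 64`).
3. **Sinusoidal positional encoding** —
   `PE(pos, 2i) = sin(pos / 10000^{2i/d})`,
   `PE(pos, 2i+1) = cos(pos / 10000^{2i/d})`, added after scaling the
   embedding by `√d`.
4. **Sparse-attention encoder** — multi-head self-attention
   `softmax(Q_h K_hᵀ / √d′) V_h` with `d′ = d/n_h`, restricted by a
   boolean mask `M ∈ {0,1}^{t×t}`: the union of a sliding band
   (`|q − k| ≤ w`, local sensitivity) and per-row random keys (cheap
   global context). By default 70 % of the `t²` query–key pairs are
   masked, so a sparse kernel performs ~30 % of dense attention's
   score/weighting FLOPs; the package's FLOPs accountant reports the
   exact ratio.
5. **Classifier head** — mean pooling over the `t` positions and a
   linear softmax layer; training minimises class-weighted cross-entropy
   (weights `w_k = N/(K·n_k)`) with Adam, learning rate 1e-4 decayed
   ×0.95 per epoch, batch 128, 40 epochs.

Evaluation reports accuracy, macro F1, macro sensitivity, confusion
matrices, and stratified 5-fold cross-validation aggregates (mean ± SD).

## Worked example

Six-class, six-channel synthetic benchmark at 50 Hz (each activity a
class-specific oscillation plus noise), one stratified fold held out:

```python
import harnet as h

windows = h.easy_benchmark(seed=0)                 # 660 windows of 100 samples
split = h.stratified_kfold(windows, folds=5, seed=0)
train_idx, test_idx = split.train_test_indices(0)

model = h.HARTransformer(windows.subset(train_idx))
result = model.fit(h.TrainConfig(seed=0))          # lr 1e-4, batch 128, 40 epochs

print(result.summary())
metrics = result.evaluate(windows.subset(test_idx))
print(f"held-out accuracy   {metrics.accuracy:.4f}")
```

Output (about two minutes on one CPU core):

```
Sparse-attention HAR Transformer
================================================
parameters               112,083
classes / channels  6 / 6
window length       100
d_model / heads     64 / 4
mask density        0.276
attention FLOPs     sparse/dense = 0.276
epochs trained      40
final train loss    0.3080
train accuracy      0.9735
train macro F1      0.9735
held-out accuracy   0.9470
```

`mask density 0.276` means the sparse pattern kept 27.6 % of the
100×100 query–key pairs (the 70 % mask setting), and attention
arithmetic shrinks by the same factor; the model still separates the
six activities at 94.7 % held-out accuracy.

The same pipeline is scriptable from the shell:

```bash
har simulate --seed 0 --out recording.csv
har segment  --data recording.csv --out windows.h5
har train    --data windows.h5 --out run/
har evaluate --ckpt run/model --data windows.h5
har cv       --data windows.h5 --folds 5
har flops    --t 100 --mask-fraction 0.7
```

Real datasets (e.g. CSV exports of public HAR corpora) enter through
`read_recording_csv`, with channel and label columns set per dataset.

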