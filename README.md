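# seqalignatac

Cell-type annotation for scATAC-seq, transferring labels from an annotated
reference to an unlabeled query dataset **within the same modality**, even
when the two datasets come from different platforms or batches.

scATAC-seq profiles chromatin accessibility per cell over hundreds of
thousands of peak regions. Annotating a new dataset against a labeled
reference is hard for two reasons: the cell-by-peak matrix is extremely
sparse and noisy, and platform differences introduce batch effects that a
classifier trained on the reference alone does not survive. This package
addresses both with a two-stage framework:

**Stage 1 — sequence-informed cell embeddings.** Each peak's DNA sequence is
embedded by a frozen feature extractor (a pluggable interface: load
precomputed embeddings from a DNA language model run elsewhere, or use the
built-in deterministic k-mer/random-projection embedder). A feedforward
network with batch-normalized hidden layers,

```
H⁽⁰⁾ = X,   H⁽ˡ⁾ = φ(BN⁽ˡ⁾(H⁽ˡ⁻¹⁾W⁽ˡ⁾ + b⁽ˡ⁾)),   Ŷ = H⁽ᴸ⁾W⁽ᴸ⁺¹⁾ + b⁽ᴸ⁺¹⁾,
```

maps the N×d peak-embedding matrix X to predicted per-cell accessibility
(one output unit per cell), trained with binary cross-entropy against the
binarized cell-by-peak matrix. Column w_c of the output weight matrix
W⁽ᴸ⁺¹⁾ ∈ R^{D×C} is the projection reconstructing cell c's accessibility
profile from peak-level latent features — it is taken as the embedding of
cell c. An LSI alternative (binarize → TF-IDF → truncated SVD) provides
cell embeddings without any sequence information.

**Stage 2 — graph domain adaptation.** kNN graphs G_s, G_t are built over
the reference and query cell embeddings. A weight-shared, asymmetric-depth
GCN classifies cells: the source path is shallow
(`Ŷ_s = Â_s·ReLU(ReLU(Â_s X_s W₁)W₂)·W₃`) to avoid over-smoothing under full
supervision, while the target path applies K extra propagation steps
(`Z_t = ReLU(Â_t^K (H_t W₂))`) to exploit neighborhood context where labels
are absent. Training minimizes

```
L_total = L_cls + λ·L_dom,   γ(e) = 2/(1 + exp(−10·e/E)) − 1,
```

where L_cls is the NLL of the source softmax predictions and L_dom is the
cross-entropy of a domain discriminator fed through a gradient reversal
layer with scheduled coefficient γ, adversarially aligning the two domains'
intermediate representations.

All neural components run on a small in-repo reverse-mode autodiff core over
numpy (`seqalignatac/_autograd.py`), gradient-checked against finite
differences in the test suite.

## Worked example

```python
import seqalignatac as sa

sim = sa.SimConfig(n_types=3, cells_per_type_source=50, cells_per_type_target=50,
                   n_peaks=500, batch_dropout=0.3, seed=11)
src, src_labels, query, query_labels, peaks, seqs = sa.simulate_pair(sim)

pred, probs, state = sa.annotate_query(
    src, src_labels, query, route="lsi", lsi_dim=32, k=15,
    gda_cfg=sa.GDAConfig(K=3, lam=1.0, epochs=200, seed=0))

report = sa.ground_truth_report(pred, query_labels)
print(f"query cells annotated: {len(pred.cell_ids)}")
print(f"accuracy:  {report['accuracy']:.3f}")
print(f"macro-F1:  {report['macro_f1']:.3f}")
last = state.log[-1]
print(f"final epoch: L_cls={last['L_cls']:.4f}  L_dom={last['L_dom']:.4f}  "
      f"gamma={last['gamma']:.4f}")
print("first prediction:", pred.cell_ids[0], pred.labels[0], probs[0].round(3))
```

prints

```
query cells annotated: 150
accuracy:  1.000
macro-F1:  1.000
final epoch: L_cls=0.0245  L_dom=0.6991  gamma=0.9999
first prediction: tgt_cell00000 type00 [0.988 0.007 0.006]
```

The simulated query carries a 30% extra dropout batch effect; the
adversarially aligned classifier still recovers every cell type. L_dom near
ln 2 ≈ 0.693 at the end of training means the discriminator can no longer
tell the domains apart — the distributions are aligned.

The same pipeline runs from the shell: `seqalignatac simulate` writes an
MTX/BED/FASTA/TSV fixture tree and `seqalignatac annotate` consumes it
(`--lsi`, `--embeddings`, or `--peaks` + `--genome` choose the embedding
route; see `--help`).

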