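# radpath

Cross-modal alignment of brain-tumor radiology and histopathology for
survival prediction when pathology is missing at inference time.

## The problem

Glioblastoma prognosis draws on two very different views of the same
tumor: multi-sequence MRI (T1, T1CE, T2, FLAIR volumes) and the
hematoxylin–eosin whole-slide image (WSI) of resected tissue. Most new
patients have MRI long before — or instead of — digitized pathology. This
package implements a retrieval-based workaround:

1. **Contrastive alignment.** For patients with *paired* data, an imaging
   encoder (3D CNN + global average pooling, or a precomputed-feature
   bypass) and a pathology aggregator (a padding-aware transformer with a
   learnable CLS token over the variable-length set of patch features
   p₁…p_N ∈ R^C) are projected by two-layer heads
   g(x) = W₂·ReLU(LayerNorm(W₁x)) into one d = 256 space and L2-normalized.
   Training minimizes the symmetric InfoNCE loss over the temperature-scaled
   cosine matrix S_ij = ê_img(i)·ê_path(j)/τ:

       L = ½·(L_img→path + L_path→img),
       L_img→path = −(1/N) Σᵢ log [ exp(S_ii) / Σⱼ exp(S_ij) ]

2. **Embedding library.** The frozen model embeds every paired patient
   once, storing (patient id, ê_img, ê_path) with exact pairing.

3. **Proxy retrieval.** An imaging-only query ê_img is answered by the
   pathology embedding of its most cosine-similar library entry
   (ê_path^proxy = argmax_k ê_img·ê_path^(k)); for k > 1 the top-k pathology
   embeddings are combined with similarity weights and re-normalized.

4. **Survival fusion.** The imaging feature is concatenated with the proxy
   and a small feed-forward head classifies 12-month overall survival
   (label 1 iff OS > 12.0 months, strictly).

Preprocessing operators for real slides are included: 256×256 tiling,
Otsu background rejection on the slide luminance histogram, and Macenko
stain normalization (OD-space SVD, angular-percentile stain vectors,
nonnegative least-squares concentrations) toward a fixed H&E reference.

Everything is exercised end-to-end on a synthetic paired cohort in which a
latent patient state drives both modalities and survival is mediated by
pathology-visible features (see `docs/methods.md`). All neural components
run on a small numpy reverse-mode autodiff core bundled with the package —
there is no deep-learning framework dependency.

## Worked example

```python
from radpath.pipeline import RunConfig, run_pipeline

results = run_pipeline(RunConfig(seed=1), outdir="scratch/demo")
print(f"selected tau           : {results['tau']}")
print(f"held-out recall@1      : {results['retrieval']['recall_at'][1]:.3f}")
print(f"random baseline r@1    : {results['retrieval_random_baseline']['recall_at'][1]:.3f}")
print(f"AUROC imaging only     : {results['survival']['imaging']['auroc']:.3f}")
print(f"AUROC + trained proxy  : {results['survival']['trained_proxy']['auroc']:.3f}")
print(f"AUROC + random proxy   : {results['survival']['random_proxy']['auroc']:.3f}")
```

Output:

```
selected tau           : 0.07
held-out recall@1      : 0.816
random baseline r@1    : 0.030
AUROC imaging only     : 0.685
AUROC + trained proxy  : 0.734
AUROC + random proxy   : 0.624
```

The run simulates 736 patients (98 + 38 paired for alignment, 600
imaging-only for survival), trains the contrastive model at τ = 0.07,
builds the 136-entry library, and trains the survival head in three input
modes. Held-out cross-modal recall@1 of 0.82 against the 1/38 ≈ 0.03
random level shows the two modalities were aligned; the trained proxy
lifts survival AUROC over imaging alone, while a proxy produced by a
randomly initialized (untrained) model does not — pathology retrieved by
*learned* similarity carries real prognostic signal.

The same stages are available from the shell:

```bash
radpath pipeline scratch/run --seed 1
radpath simulate scratch/cohort --seed 1
radpath train-align scratch/run --seed 1
radpath build-library scratch/run/alignment.npz scratch/cohort scratch/lib
radpath retrieve scratch/run/alignment.npz scratch/lib scratch/cohort scratch/ret.csv --k 5
radpath prep-wsi slide.png scratch/tiles --patch-size 256
```

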