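# sccase

Enhancement (denoising / imputation) of single-cell chromatin accessibility
(scCAS, e.g. scATAC-seq) data.

scCAS count matrices are extremely sparse and near-binary: most truly
accessible sites are recorded as zeros because each cell is sequenced
shallowly (dropout). This package enhances a peaks × cells matrix by coupling
non-negative matrix factorization to an iteratively optimized cell-to-cell
similarity matrix, and is aimed at anyone doing clustering, visualization or
peak-level analyses downstream of scATAC-seq.

## The model

After filtering peaks open in fewer than 1% of cells and TF-IDF reweighting
(`x_ij = (x̂_ij / Σ_k x̂_kj) · log(n / occurrence_i)`), the preprocessed matrix
**X** (m peaks × n cells) is modelled by

```
min_{W,H,Z ≥ 0}  F = ‖X(Z∘R) − WH‖²_F + λ‖Z − HᵀH‖²_F + γ₁‖W‖²_F + γ₂‖H‖²_F
```

where **Z** (n × n, columns summing to 1) is the cell-to-cell similarity
matrix, **R** a fixed binary Bernoulli mask that prevents similar cells from
collapsing onto identical profiles, **W** (m × k) the projection matrix whose
columns are peak programs, and **H** (k × n) the cell embedding. **Z** starts
from the Jaccard similarity of the binarized cells, (**W**, **H**) from
conventional NMF. The factors are updated by projected gradient descent with
*closed-form* step sizes for **W** and **Z** (their 1-D loss restrictions are
parabolas) and a backtracked step for **H**. The enhanced matrix is **X·Z**.

A reference-guided variant anchors the leading k₁ columns of **W** to a basis
**P** extracted by NMF from bulk or pseudo-bulk profiles over the same peaks,
via an extra penalty `α‖P − W₁‖²_F`; helpers build such references from
depth-scaled bulk counts, labelled companion datasets, or the target's own
Louvain clusters.

The package also ships the interpretation procedure (cell type-specific peaks
from the most active program of a cell group; background peaks closest to the
mean projection coefficient; BED export), the evaluation suite (Louvain with
binary-searched resolution, ARI/AMI/FMI, Pearson-distance silhouette,
cell-/peak-wise auPRC/auROC, imbalance degree) and a synthetic discrete-mode
scCAS generator with planted clusters, depth variation and dropout, so the
whole system is testable offline.

## Worked example

```python
import numpy as np
from sccase import *

spec = SimulationSpec(n_clusters=3, cells_per_cluster=60,
                      n_marker_peaks_per_cluster=200, n_shared_peaks=100, seed=7)
data = simulate_discrete(spec)
corrupted = corrupt_dropout(data.observed, rate=0.5, seed=8)

X = tfidf_transform(filter_peaks(corrupted))
res = fit(X, ModelParams(k=3, seed=0))
enhanced = enhance(X, res.Z)

kept = {str(p) for p in X.peaks}
idx = [i for i, p in enumerate(data.truth.peaks) if str(p) in kept]
truth = PeakByCellMatrix(data.truth.dense()[idx], [data.truth.peaks[i] for i in idx],
                         list(data.truth.barcodes), "truth")
before = auprc_auroc(X, truth, axis="cellwise").mean_auprc
after = auprc_auroc(enhanced, truth, axis="cellwise").mean_auprc
clust = louvain_binary_search(pca_reduce(enhanced, 50, seed=0), target_k=3, seed=0)
ari, ami, fmi = clustering_metrics(clust.labels, data.true_types())
```

This prints (via the f-strings in the example script):

```
converged=False after 100 iterations, loss 2228161.3453 -> 3.8826
mean cell-wise auPRC: corrupted 0.517 -> enhanced 0.525
clustering vs true types: ARI 1.000, AMI 1.000, FMI 1.000
```

Half of the observed signal was dropped out, yet the enhanced matrix ranks
the true accessible sites better than the corrupted input (higher mean
cell-wise auPRC) and clusters perfectly into the three planted cell types.
The loss falls steeply from its initial value and the trace is non-increasing
by construction; the run stops at the iteration cap rather than the 10⁻⁶
relative-change tolerance, which is typical at small scale.

The same workflow is available from the shell:

```bash
sccase simulate --out sim/ --dropout 0.5 --seed 1
sccase enhance --input sim/observed --labels sim/labels.tsv --outdir fit/
sccase evaluate --enhanced fit/enhanced --labels sim/labels.tsv --report report.json
```

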