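# gelnetx — network-regularized elastic nets for genomic prediction

High-dimensional genomic datasets routinely carry tens of thousands of
per-gene features for a few dozen samples, and sparse linear models fit to
them are notoriously unstable: many unrelated gene signatures predict
equally well, and the selected genes rarely form an interpretable
mechanism. `gelnetx` addresses this by folding prior knowledge about gene
relationships — an interaction network — directly into the regularizer of
the model.

The core object is the **generalized elastic net** penalty

&nbsp;&nbsp;&nbsp;&nbsp;R(**w**) = λ₁ Σⱼ dⱼ|wⱼ| + (λ₂/2) **w**ᵀP**w**,

where **d** ≥ 0 weights the L1 (sparsity) term per feature and P is any
positive semi-definite feature-pair *dissimilarity* matrix. With d = 1 and
P = I this is the classical elastic net; with P a graph Laplacian the L2
term becomes ½ Σᵢⱼ Aᵢⱼ(wᵢ − wⱼ)², which pulls the weights of interacting
genes together and steers selection toward connected subnetworks. Diffusion
penalties (I − e^{−tL}), the ridge/Laplacian blend I + βL, and
pseudo-inverses of arbitrary PSD kernels are also provided.

The package contains, for the p ≫ n regime:

* a coordinate-descent solver for penalized weighted least squares
  (statsmodels-style `GELnet(...).fit(...)` → results object with
  `summary()`, `predict()`, KKT diagnostics and TSV serialization);
* reductions for binary **logistic regression** (IRLS) and sparse
  **network-regularized PCA** (penalized ratio-of-quadratic-forms
  iteration with deflation);
* a **synthetic benchmark** coupling expression data to a scale-free gene
  network through a Gaussian graphical model, with a planted pathway
  driving the response;
* an **evaluation suite** — reconstruction error, leave-pair-out
  cross-validated RMSE, network dispersion — that compares a
  network-penalized model against a matched-sparsity elastic net over a
  λ-grid and decides whether the supplied network is *relevant* to the
  prediction task;
* a CLI: `gelnetx simulate|fit|logistic|pca|evaluate|sweep`.

See `docs/methods.md` for the model, the algorithms and all numerical
conventions.

## Worked example

Simulate a dataset in which expression follows a Gaussian graphical model
on a 500-gene scale-free network and the response is driven by a connected
50-gene pathway, then fit a GELnet with the network's normalized Laplacian
as the pair penalty:

```python
import numpy as np
from gelnetx import (SimulationConfig, simulate_dataset, GELnet,
                     build_laplacian, run_comparison, network_relevance)

cfg = SimulationConfig(p=500, n=50, seed=7)
ds = simulate_dataset(cfg, "GGM+")        # learner gets the true network

L = build_laplacian(ds.net_given, normalized=True)
model = GELnet(ds.y, ds.X, P=L)
res = model.fit(lambda1=model.lambda1_max() / 9, lambda2=10.0)
print(res.summary())
```

```
Generalized Elastic Net Regression Results
======================================================
No. samples:               50    lambda1: 0.670376
No. features:             500    lambda2: 10
Nonzero weights:          333    sweeps:  16
Converged:               True    KKT residual: 6.026e-05
Intercept:            1.25476    objective: 32.1777
------------------------------------------------------
  g150                           0.347491
  g192                           0.338493
  ...
```

The model keeps 333 of 500 genes at this (λ₁, λ₂) and satisfies the
subgradient optimality conditions to 6e−5. To ask whether the network
actually helped, compare against a matched-sparsity elastic net,
marginalizing all three metrics over the λ-grid:

```python
rep = run_comparison(ds, n_pairs=100, seed=11)
print(rep.summary())
print("network relevant?", network_relevance(rep))
```

```
GELnet vs Elastic Net comparison (GGM+)
========================================================
             reconstruction_error   rmse  dispersion
method
elastic_net               0.86538 9.1222      0.4886
gelnet                    0.78176 8.7452     0.40777
--------------------------------------------------------
% improvement of GELnet over elastic net:
  reconstruction_error          9.663 %
  rmse                          4.132 %
  dispersion                   16.542 %

network relevant? True
```

All three metrics are "lower is better". Here the GELnet recovers the
planted pathway more accurately (reconstruction error 0.78 vs 0.87),
predicts held-out samples better (leave-pair-out RMSE 8.75 vs 9.12, a
4.1% improvement), and selects genes that cluster on the network
(dispersion 0.41 vs 0.49). The decision rule — at least 2.5% RMSE or 5%
dispersion improvement — flags the network as relevant. Rerunning with a
scrambled network (`scenario="GGM-"`) erases the reconstruction advantage,
which is exactly the diagnostic the comparison is designed to provide.

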