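# tsdnet

Time-course differential-expression screening and linear-ODE gene
regulatory network (GRN) inference for temperature-dependent sex
determination (TSD) transcriptomes.

In TSD reptiles such as the American alligator, the incubation
temperature of the egg — not genotype — directs the bipotential gonad
toward testis (male-producing temperature, MPT) or ovary
(female-producing temperature, FPT). The canonical experiment incubates
eggs at FPT until the onset of the thermosensitive window (Day 0),
shifts a subset to MPT, and profiles gonadal expression at a series of
days in both arms: triplicates at Days 0–12 (Day 0 exists only in the
FPT arm, as the shared pre-shift baseline), single descriptive samples
at Days 18–36. `tsdnet` packages the full downstream analysis of such a
design, for computational biologists who want a tested, reusable and
fully simulatable version of it:

* **Differential expression** — per-gene moderated t-tests on
  log₂(FPKM+1) with Benjamini–Hochberg control, two-stage (FDR 0.05
  initial, FDR 0.01 screen);
* **Cross-comparison screens** — development-dependent DEGs (adjacent
  days within one arm), sex-dependent DEGs (MPT vs FPT at matched
  days), persistent dimorphism, immediate temperature-responsive genes
  (moved after the shift in the MPT arm only *and* dimorphic at Day 3),
  candidate sexual-development genes (development-dependent ∩
  dimorphic), dimorphism-timespan labels (Long/Short/Ambiguous), and
  z-scored hierarchical clustering of M−F log₂ fold changes;
* **Network inference** — a linear ODE model per gene set,
  dx/dt = A·x + b·u(t), with u a step input representing the
  temperature shift at Day 0, fitted by greedy prior-guided structure
  search on monotone-interpolated fold-change trajectories until the
  simulated trajectories match within `allowed_error`;
* **Robustness** — edge inclusion frequencies under repeated Gaussian
  perturbation of the data and random omission of 10 % of the prior;
  edges above 50 % in both tests are robust, above 80 % highly robust;
* **Synthetic data** — a generator that reproduces the temperature-shift design
  with planted gene classes and known regulatory systems, so every
  stage is testable against ground truth without any external data.

## The model at the core

For genes *i = 1…n* with log₂ fold-change trajectories *xᵢ(t)* relative
to the Day-0 baseline:

    dxᵢ/dt = aᵢᵢ xᵢ + Σⱼ aᵢⱼ xⱼ + bᵢ u(t),     x(0) = 0,
    u(t) = 0 for t < 0,  1 for t ≥ 0   (the temperature shift)

Regulators per target are chosen greedily: coefficients come from least
squares of the estimated derivative on candidate regressors, candidates
prior-listed in a gene-pair co-expression resource (confidence 0.25 by
default) are favoured, and selection stops when the simulated target
trajectory reaches mean squared error ≤ `allowed_error` (default 0.01)
or the in-degree cap (default 3). Robust edges are those that survive
1000 (configurable) re-inferences under noise (sd 0.05) and under 10 %
prior omission.

## Worked example

`examples/04_network_inference.py` simulates a known three-gene cascade
(temperature → g0 → g1 ⊣ g2), observes it daily and re-infers the
wiring:

```
true edges:     [('MPT', 'g0', 'input'), ('g0', 'g1', 'gene'), ('g1', 'g2', 'gene')]
inferred edges: [('MPT', 'g0', 'input'), ('g0', 'g1', 'gene'), ('g1', 'g2', 'gene')]
recovered exactly: True
fit error (mean squared trajectory deviation): 1.49e-05
inferred A (rows = targets):
[[-0.951  0.     0.   ]
 [ 0.784 -0.882  0.   ]
 [ 0.    -0.692 -1.088]]
inferred input weights: [0.857 0.    0.   ]
```

The inferred self-decays (diagonal), cross-edges and input weight land
within a few percent of the generating values (−1.0, 0.8, −0.7, 0.9);
the fit error is the mean squared deviation between the model's
simulated trajectories and the interpolated observations. The other
examples cover dataset simulation, DEG calling (50/50 planted 4-fold
genes recovered with 0 false positives at q < 0.01), the gene screens,
and the robustness consensus, each printing the counts it computes.

There is also a thin CLI: `tsdnet run --n-genes 200 --seed 1 --out-dir
out/` executes the whole pipeline (simulate → DE → screens → infer →
robustness) and writes every artifact plus a JSON report of counts;
`tsdnet fixtures`, `tsdnet de`, `tsdnet infer` and `tsdnet robustness`
expose the individual stages.

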