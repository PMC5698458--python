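# nfkbinfo

How many bits about TNF concentration does a single cell's NF-κB response
carry?  `nfkbinfo` is a Python package for quantifying information
transmission and dose discernibility along the TNF → TNFR → IKKK → IKK →
IκBα → NF-κB signaling pathway.  It combines

* a stochastic (Gillespie / tau-leaping) single-cell model of the two-feedback
  NF-κB network, simulated for heterogeneous cell populations across an
  8-dose TNF panel (0, 0.01, 0.03, 0.1, 0.3, 1, 3, 10 ng/ml),
* distribution-level statistics on the resulting single-cell readouts:
  the two-sample Kolmogorov–Smirnov distance with its decision-theoretic
  decomposition, and mutual information estimated with k-nearest-neighbour
  entropies and maximized over input priors (a channel-capacity estimate),
* the immunofluorescence quantification used to measure nuclear NF-κB in
  segmented confocal images (background-corrected, DAPI-normalized nuclear
  fractions) together with the cytoplasmic-interference correction, and
* synthetic-data generators (Gaussian dose panels, per-cell intensity tables
  with ground truth, an NF-κB pool-size distribution) so that every analysis
  can be validated without external data.

It is intended for computational biologists studying information processing
in signaling networks, and for anyone needing well-tested KS / capacity
machinery for discrete-dose, continuous-readout single-cell data.

## The statistics at the core

For two cell populations stimulated with doses `d` and `d₁`, with empirical
CDFs `F₁`, `F₂`,

    KS(P₁, P₂) = sup_x |F₁(x) − F₂(x)|,

and at the optimal decision threshold the miss and false-alarm probabilities
satisfy `p_m + p_f = 1 − KS`, giving the error probability
`p_e = (1 − KS)/2`.  For two equal-variance Gaussians the KS distance is
`erf(Δµ / (2√2 σ))`, so discernibility per unit standardized shift approaches
`1/√(2π) ≈ 0.398`.  Adjacent-dose discernibility is `C(d) ≈ KS/(ln d₁ − ln d)`.

Mutual information between the discrete dose `Y` (prior `p_i`) and the scalar
readout `X`,

    MI(X;Y) = Σ_i p_i ∫ p(x|d_i) log₂ [ p(x|d_i) / p(x) ] dx,

is estimated from samples with a radius-sharing k-nearest-neighbour
estimator (Kraskov-style, discrete-conditional form) and maximized over the
prior by steepest ascent on the simplex; a Blahut–Arimoto iteration and
Gaussian quadrature serve as independent cross-checks.

## Worked example

```python
import numpy as np
from nfkbinfo import nfkb_ssa as ns, infotheory as it

# simulate 500 cells per dose, receptor heterogeneity sigma = 0.3
panels = ns.run_dose_panel(n_cells=500,
                           noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.3),
                           seed=103)

nfkb = panels["nfkb_nuc_norm"]          # normalized nuclear NF-kB peaks
est = it.maximize_mi(nfkb, seed=1)
print(f"capacity at NF-kB: {est.mi_bits:.2f} bit")
ks = it.ks_distance(nfkb.samples[0], nfkb.samples[7])
print(f"KS(0 vs 10 ng/ml): {ks.ks:.2f}, error probability {ks.p_error:.3f}")
```

prints

```
capacity at NF-kB: 1.09 bit
KS(0 vs 10 ng/ml): 1.00, error probability 0.000
```

i.e. a single cell's 30-min nuclear NF-κB readout carries about one bit —
essentially whether TNF is present — even though unstimulated and saturating
doses are perfectly separable: the capacity is limited by the overlapping
intermediate doses, not by the extremes.  With the cytoplasmic-interference
observation model (`panels["nfkb_nuc_norm_ci"]`) the same extreme-dose
comparison drops to KS ≈ 0.94, reproducing the bias of confocal measurements.

The same analyses are available from the command line:

```bash
nfkb-info simulate-panel --n-cells 500 --sigma 0.3 --seed 103 --out run/
nfkb-info ks-matrix --input run/readouts_sigma0.3.csv --out run/ks.csv
nfkb-info mi --input run/readouts_sigma0.3.csv --node nfkb_nuc_norm --out run/mi.json
nfkb-info report --input run/readouts_sigma0.3.csv --out run/report.json
```

## Layout

```
src/nfkbinfo/infotheory.py     KS, discernibility, kNN MI, prior maximization
src/nfkbinfo/nfkb_ssa.py       stochastic pathway model + population panels
src/nfkbinfo/imaging_quant.py  nuclear-fraction quantification, CI correction
src/nfkbinfo/synthetic_data.py generators with ground truth
src/nfkbinfo/pipeline_cli.py   `nfkb-info` command-line pipeline
docs/methods.md                model, estimator and calibration notes
```
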