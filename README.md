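# glycoclam

Analysis pipeline for the statistics behind a structural-biology question:
do N-linked glycans shift NMDA-receptor ligand-binding domains (LBDs)
toward their closed "clamshell" conformation? The package implements, as
tested and reusable code exercised on synthetic data with known ground
truth:

* the clamshell order parameter *d* (marker-C&alpha; distance, residues
  507/701 in GluN1) and the glycan-to-opposite-lobe minimum heavy-atom
  distance *d*<sub>g-ol</sub>, from multi-model PDB ensembles;
* Markov state models on discretized *d* series — k-means clustering,
  sliding-window transition counts, reversible maximum-likelihood
  transition matrices, stationary distributions, and implied timescales
  t&#7522; = &minus;&tau;/ln &lambda;&#7522; — plus tICA timescales, over the
  estimator grid (99/6 clusters &times; 256/128 ns lags);
* MSM-reweighted probability densities of *d* and a per-bin percentile
  bootstrap (resampling whole trajectories) to flag significantly
  enriched/depleted conformational ranges at 95% confidence;
* glycan contact fractions and the joint (d, d<sub>g-ol</sub>) occupancy
  map, whose far-open/in-contact corner (d &gt; 5.2 nm,
  d<sub>g-ol</sub> &lt; 0.5 nm) must be empty when glycan-lobe contact
  occurs only in closed conformations;
* Hill-function fitting of glycine dose-response curves,
  I(c) = I<sub>max</sub>c&#691;/(EC50&#691; + c&#691;), and group comparison
  of per-curve EC50 between wild-type and glycosylation-deficient (N440Q)
  receptors.

A seeded synthetic-data module generates every input: scalar *d* ensembles
from an exact continuous-time two-state process (closed basin 3.7 nm, open
4.7 nm, known relaxation time and equilibrium populations), toy two-lobe
glycoprotein PDB fixtures with a tethered pseudo-glycan, and replicate
sigmoidal dose-response curves. See `docs/methods.md` for the models,
defaults and their rationale.

## Worked example

```sh
python analysis/01_simulate.py     # generate the study ensembles
python analysis/03_kinetics.py    # timescale table over the estimator grid
python analysis/04_distributions.py
python analysis/05_doseresponse.py
```

`03_kinetics.py` compares a "glycosylated" condition (equilibrium closed
fraction 0.65; 262 trajectories &times; 2000 frames at 0.2 ns) against a
"non-glycosylated" one (closed fraction 0.50; 196 trajectories), both
generated with a 333 ns relaxation time, and prints:

```
estimator  k  lag_ns  timescale_us_with_glycans  timescale_us_without  ratio
      MSM 99 256.000                      0.386                 0.317  1.217
      MSM 99 128.000                      0.344                 0.333  1.033
      MSM  6 256.000                      0.386                 0.317  1.217
      MSM  6 128.000                      0.344                 0.333  1.033
     tICA    256.000                      0.342                 0.287  1.192
```

All estimators scatter around the generating 0.33 &micro;s with ratios near
1: shifting the open/closed *equilibrium* does not change the exchange
*kinetics*, and the residual scatter reflects the ~10&sup2; transitions
actually sampled. `04_distributions.py` reports the bins where the
glycosylated density is significantly higher (the closed basin around
3.7 nm) or lower (the open basin around 4.7 nm); `05_doseresponse.py`
prints

```
wild-type: EC50 = 2.329 +/- 0.045 uM (n = 12)
mutant:    EC50 = 3.540 +/- 0.057 uM (n = 12)
change: +52.0% (t = -16.74, p = 5.3e-14)
```

recovering the generating 2.28/3.43 uM values and their 50% difference.
The same pipeline is scriptable through a CLI
(`glycoclam all --config cfg.yaml --outdir out --seed 1`) driven by a YAML
config with full default echoing and strict schema validation.

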