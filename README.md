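# dynetsim

Similarity indices, controlled simulators and group statistics for
**dynamic weighted networks** — ordered sequences of symmetric weighted
adjacency matrices over a fixed node set, as used in longitudinal brain
connectivity studies.

## What it provides

* **DNS** (dynamic network similarity): Pearson correlation of the two
  networks' concatenated "long vectors", multiplied by the min/max ratio
  of their standard deviations, affinely mapped to [0, 1]. Sensitive to
  both structural configuration and temporal evolution.
* **DNES** (dynamic network evolution similarity): the same
  correlation-times-SD-ratio similarity computed per corresponding edge
  time series and averaged over edges. Insensitive to purely structural
  differences by design.
* Traditional snapshot comparators (Dice, Jaccard, normalized-Laplacian
  spectral similarity, normalized Pearson) with a mean-over-timepoints
  dynamic extension.
* A **controlled-variable simulator** producing pairs of sine-evolving
  networks that differ in phase offset (`delta_phi`), amplitude ratio
  (`lam`), structural noise power (`alpha`) and strength scale (`beta`),
  plus general randomizations (additive noise, timing shuffles).
* Six **validation experiments** sweeping one variable at a time and
  summarizing the index response with Pearson r / p / RSS.
* A **group pipeline** from ROI time-series tables to Fisher-Z
  connectivity, paired-t edge selection, pairwise between-subject
  similarity, and Wilcoxon / Mann-Whitney / Cohen's-d statistics —
  together with a synthetic pre/post three-group cohort generator.

## CLI

All functionality is reachable through the `dynetsim` entry point:

```sh
# simulate a controlled pair and compare it
dynetsim simulate --seed 1 --delta-phi 1.0 --out-prefix pair
dynetsim compare --a pair_net1.dnt --b pair_net2.dnt --indices dns,dnes

# run validation experiment 2 (amplitude-ratio sweep, 200 replicates)
dynetsim experiment --id 2 --noise 0.001 --reps 200 --seed 7 --out exp2.tsv

# synthetic cohort + group pipeline
dynetsim synth-cohort --n1 6 --n2 5 --n3 7 --seed 11 --out cohort/
dynetsim group --cohort cohort/ --indices dns,dnes --out report.json
```

Dynamic networks are stored as stacked text (`.dnt`: a `n T` header
followed by `T` whitespace-delimited matrix blocks separated by blank
lines) or as per-timepoint matrices listed in a JSON manifest. ROI time
series are delimited tables with a header row of ROI names.

## API sketch

```python
import numpy as np
from dynetsim import SimulationSpec, make_network_pair, dns, dnes

pair = make_network_pair(SimulationSpec(delta_phi=0.5, noise_power=0.001, seed=1))
print(dns(pair.net1, pair.net2).value, dnes(pair.net1, pair.net2).value)
```

All stochastic entry points accept a seed and are fully deterministic
under it.
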