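# spinelab

Dendritic spines — the micrometre-scale protrusions that carry most
excitatory synapses — vary enormously in size, yet dendrites appear to
regulate them collectively: the summed postsynaptic density (PSD) area
per micrometre of dendrite scales with dendritic diameter, while the
ratio of PSD area to spine neck length stays roughly constant across
dendrites. `spinelab` implements the computational side of this line of
work as a tested, reusable pipeline:

* **Morphometry** of serial-section (FIB/SEM-style) spine
  reconstructions: head volume as Σ(contour area)·thickness, PSD area as
  Σ(trace length)·thickness (or an en-face area), spine density, PSD-area
  density, neck-length density, PSD/neck ratios, fold ranges and CVs,
  axon-coupled spine fractions, and ER-adjacency along dendrites.
* **A synthetic-data generator** that emulates the published per-region
  summary distributions (lognormal head volumes, truncated-Gaussian neck
  metrics, linear-with-noise PSD/head-volume coupling, diameter scaling
  of PSD density, axon-coupled pairs, ER-positive enrichment), so every
  downstream stage is testable without imaging data.
* **A two-layer model neuron**: each of N_branch = 20 dendritic branches
  receives N_syn = 250 Poisson synapses with lognormal weights
  W ~ exp(N(μ_e, σ_e²)) and integrates them as a leaky integrate-and-fire
  unit,

      dV_j/dt = −(V_j − V_rest)/τ_dend + Σ_i Σ_k W_ij δ(t − t_ijk),
      V_j > θ  ⇒  dendritic spike, V_j → V_reset,dend

  with V_rest = V_reset,dend = −75 mV, θ = −40 mV, τ_dend = 10 ms and a
  20-ms refractory lockout.  Dendritic spikes feed a somatic LIF unit
  (W = 20 mV per spike, τ_soma = 20 ms, V_reset,soma = −80 mV).
  Integration is event-driven and exact, with a numba-compiled kernel.
* **Mutual information** between 5-ms-binned, binarized sequences:
  MI(DS; SI) between the strongest synapse's input and the branch's
  dendritic spikes, and MI(SS; SI) against the somatic train, using the
  plug-in estimator MI = Σ p(x,y) log₂ p(x,y)/(p(x)p(y)).  Two synaptic
  scenarios are compared: case 1 (one common lognormal across branches)
  and case 2 (per-branch μ_e ~ N(−6, 0.4)).
* **Uncaging analysis**: uEPSP/uEPSC amplitude as the trial-averaged mean
  of a 2-ms window centred on the post-pulse extremum (baseline
  subtracted), the spine length/head-width ratio with its 0.2-µm minimum
  length rule, median-split neck groups, and shaft-normalised
  fluorescence intensities.
* **A normality-gated statistics layer**: Shapiro–Wilk at α = 0.05 gates
  Pearson vs Spearman and t/ANOVA vs Mann–Whitney/Kruskal–Wallis, with
  Bonferroni-corrected pairwise comparisons.

## Worked example

The numbered scripts under `analysis/` run the full study flow and write
their tables under `results/`. For example:

```
$ python analysis/04_mi_tuning_curves.py
case 1: dendritic MI peaks at 4.0 Hz (0.0480 bits/bin); somatic MI peaks at 1.0 Hz (0.00186 bits/bin)
case 2: dendritic MI peaks at 4.0 Hz (0.0483 bits/bin); somatic MI peaks at 1.0 Hz (0.00155 bits/bin)

at the case-1 somatic optimum (1.0 Hz): case-1 MI 0.00186 vs case-2 MI 0.00155 bits/bin (case 2 lower)
```

Dendritic information transfer is tuned: at low input rates branches
never spike (MI = 0), at moderate rates the many weak inputs help the
strongest synapse drive spikes (MI rises), and at high rates background
spiking swamps the signal (MI falls). Making synaptic strength
heterogeneous across branches (case 2) lowers somatic MI at the common
optimal frequency — branch-to-branch constancy of synaptic strength
supports dendro-somatic information transfer.

The morphometry flow is equally direct:

```
$ python analysis/01_generate_morphometry.py
CA1_PSR   :  1152 spines on 25 dendrites (mean head volume 0.047 um^3)
...
$ python analysis/02_morphometry_summaries.py
  region  n_spines  spine_density_mean  head_volume_mean  ...  axon_coupled_fraction
 CA1_PSR      1152               3.037             0.047  ...                  0.045
```

and `analysis/05_uncaging_groups.py` measures a 70-spine cohort through
the trace-quantification stage, splits it at the median length/width
ratio, and reports the short-neck group as significantly larger
(Student's t, p ≈ 1e-6).

As a library:

```python
import numpy as np
from spinelab import info, synthetic, twolayer

res = twolayer.run_simulation(twolayer.ModelParams(input_freq=4.0),
                              case=1, rng=np.random.default_rng(7))
print(info.mi_vs_dendrite(res).mean())   # bits per 5-ms bin
```

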