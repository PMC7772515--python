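# Methods

## Morphometry conventions

All measurements follow serial-section bookkeeping at a fixed section
thickness (0.04 µm in the emulated datasets). Head volume is
Σ(contour area)·thickness; PSD area is Σ(PSD trace length)·thickness for
cross-sectioned synapses and the single-section area for en-face
synapses (a stack carrying both representations is rejected as
ambiguous). Dendritic diameter is the mean of per-section widest-transect
widths. Spine density is spine count / dendrite length; PSD-area density
and neck-length density are the corresponding per-µm sums. The
dendrite-level PSD/neck ratio is Σ(PSD)/Σ(neck), not the mean of
per-spine ratios.

Handling of edge cases the measurement definitions leave open:

* Spines whose PSD could not be measured (neck leaving the imaged
  volume) are excluded from PSD-based aggregates but retained for spine
  density; every summary reports a QC count (`qc_missing_psd`).
* Stubby spines (no measurable neck) are excluded from ratio statistics;
  a zero neck length raises rather than silently producing infinities.
* Filopodia carry no synapse (`psd_area == 0` is enforced) and are not
  counted as spines in densities.
* ER adjacency (`er_hotspot_fraction`) is ordinal: among ER⁺ spines, the
  fraction whose immediate neighbour in positional order is also ER⁺.
  With fewer than two spines, or no ER⁺ spine, the quantity is undefined
  and NaN is returned. A distance threshold was deliberately not used —
  the underlying observation is about spines "next to" one another, and
  an ordinal rule has no free parameter.
* Branched spines contribute one record per head; each head has its own
  PSD.

## Synthetic-data generator

The generator emulates the *summary statistics* of per-region spine
populations, not images or segmentation error. Per dendrite, a length
(uniform 5–25 µm, the reconstructed-segment range) and diameter (uniform
over the region's diameter range, moment-matched to the reported
mean ± SD) are drawn; the spine count is round(density·length) with the
per-dendrite density a truncated Gaussian.

Distribution families, chosen as the simplest forms matching the printed
mean/SD with the right support:

* **Head volumes: lognormal.** The reported distributions are strongly
  right-skewed with 11–204-fold max/min ranges; a lognormal reproduces
  both from the mean/SD alone. (µ, σ) are solved from the printed
  moments.
* **Neck length, neck diameter, per-dendrite density:
  moment-matched truncated Gaussians.** The underlying location/scale are
  solved numerically so the *truncated* distribution has exactly the
  configured mean and SD. Naive truncation of N(0.46, 0.246²) at zero
  would inflate the mean by ≈ 0.018 µm — larger than the Monte-Carlo
  error at the n = 10⁴ used by the recovery checks, i.e. the generator
  would fail to embody its own configuration.
* **PSD area = slope·(head volume)·f_d + N(0, σ_noise), floored at
  10⁻³ µm².** Only correlation coefficients are reported for the
  PSD–size relationship, so the functional form is a design choice; a
  linear coupling with additive noise is the simplest one that lets a
  single parameter (σ_noise) set the induced Spearman correlation. The
  per-region noise SDs were calibrated once so the induced correlations
  fall in the reported 0.42–0.89 range (CA1 PSR ≈ 0.77). The additive
  noise floor distorts the smallest spines, so slope recovery is
  estimated on the upper half of the head-volume distribution.
* **Diameter scaling.** f_d = 1 + s·(diameter − midrange)/(baseline PSD
  density) multiplies PSD areas, making the dendrite's PSD-area density
  increase with diameter at ≈ s µm²/µm per µm of diameter while leaving
  head volumes (and the overall PSD mean, since E[f_d] = 1) unchanged.
* **ER-positive spines** (Bernoulli at the region's ER fraction) have
  head volumes multiplied by the ER⁺/ER⁻ size contrast; all head volumes
  are then rescaled by 1/(1 − p + p·boost) so the configured overall
  mean is preserved exactly. Consequently the configured lognormal
  describes the overall marginal, and log-moment recovery is only exact
  with the boost disabled — the tests check it that way.
* **Axon-coupled spines** are realised by pairing randomly chosen
  same-dendrite spines under a shared axon ID (expected pair count
  rate·n/2, unbiased stochastic rounding). Pair members' PSD areas are
  redrawn around the pair mean with reduced intra-pair variance,
  reflecting the reported intra-pair similarity of synapse sizes.
  Multiplicities above 2 (observed in cerebellum, range 2–4) are not
  generated; the measurement side handles arbitrary multiplicity.
* Neck length and neck diameter are generated independently: the data
  show neck length is a poor predictor of neck diameter, and no
  within-region covariance is reported.

All draws flow from one `numpy` Generator seeded by the config, so a
(config, seed) pair is byte-reproducible. What passing recovery tests
show is that the *pipeline measures what the generator encodes* — they
say nothing about segmentation accuracy, annotator bias, or any feature
of real tissue beyond the encoded summary statistics.

## Two-layer model neuron

Parameters (all fixed by the study design): N_branch = 20, N_syn = 250,
V_rest = V_reset,dend = −75 mV, V_reset,soma = −80 mV, θ = −40 mV,
τ_dend = 10 ms, τ_soma = 20 ms, somatic weight per dendritic spike
W = 20 mV, refractory 20 ms in both layers, homogeneous Poisson inputs
at 0.5–10 Hz, weights lognormal with location μ_e = −6; case 2 draws
per-branch μ_e ~ N(−6, 0.4).

Numerical choices:

* **Event-driven exact integration.** Between events the membrane decays
  in closed form (V → V_rest + (V − V_rest)e^(−Δt/τ)); each Dirac input
  adds its weight instantaneously (the integral of the stated ODE across
  an event). The threshold test is strict (`V > θ`), checked at event
  times only — between events V decays toward V_rest < θ, so no crossing
  can occur there.
* **Simultaneous events** (identical timestamps) are summed in ascending
  synapse index before a single threshold check; two coincident 20-mV
  dendritic spikes therefore fire the soma.
* **Refractory semantics.** The stated "relative refractory period" is
  not defined further; it is implemented as an absolute 20-ms lockout:
  within 20 ms of a spike no new spike can be triggered, the membrane
  keeps integrating, and a suppressed crossing does not reset. Every
  emitted train has min ISI ≥ 20 ms.
* **σ_e = 4.5 (calibrated).** The weight-distribution shape is not
  printed. With μ_e = −6 the median weight is e⁻⁶ ≈ 0.0025 mV against a
  35-mV gap to threshold, so spiking lives entirely in the lognormal
  tail and σ_e sets where in the 0.5–10 Hz band the dendritic-spike
  regime begins. A coarse sweep (σ_e ∈ {3 … 5}, 20-s trials) shows the
  dendritic MI curve is still monotone in the band at σ_e ≤ 3.5, has an
  interior maximum at 3–6 Hz with the somatic curve peaking near 1 Hz at
  σ_e = 4.5, and pushes the somatic optimum to the band edge at
  σ_e = 5. σ_e = 4.5 is therefore the package default; only the
  *position* of the tuning curve, never its existence, depends on this
  choice within the workable range.
* The fixed-step reference integrator used by the equivalence tests
  steps at dt = 0.01 ms with the exact per-step decay factor e^(−dt/τ)
  and event times on the dt grid. This isolates the event-handling
  comparison: plain forward Euler carries an O(dt) systematic decay
  error (~0.02 mV across a decay span) that flips near-threshold events
  for reasons unrelated to the logic under test; a separate toy check
  compares against plain forward Euler with a one-step tolerance.

## Mutual information

Spike/input sequences are binned at 5 ms (bins anchored at t = 0,
trailing partial bin dropped) and binarized. MI is the plug-in estimator
over the empirical 2×2 joint with 0·log 0 ≡ 0, in bits (base 2 — the
base is a convention; every ordering and zero property is base-free).
No bias correction is applied: at the 2×10⁴ bins of a 100-s trial the
plug-in bias (~1/(2N ln 2) per degree of freedom) is far below the
trial-to-trial SD, and all conclusions rest on comparisons at equal N.
The analysis targets the strongest synapse (argmax weight) of each
branch; tuning curves report the branch-mean MI per trial and
mean ± SD across trials, for both the dendritic and the somatic
comparison. Per-branch values remain available from the lower-level
functions.

## Statistics layer

Shapiro–Wilk at α = 0.05 gates parametric vs non-parametric branches;
normality is assessed per group (the alternative — pooled assessment —
is not stated in the emulated workflow and per-group is the common SPSS
default). Two groups: Student's t vs Mann–Whitney U; ≥ 3 groups: one-way
ANOVA vs Kruskal–Wallis, followed by all pairwise two-group tests with
Bonferroni adjustment (p_adj = min(1, m·p), monotone and capped — some
comparisons legitimately report p = 1.00). Spearman uses midranks for
ties. Significance stars follow the p < 0.05/0.01/0.001 convention.

## Uncaging quantification

Per trial: baseline = mean of the 20 ms before the pulse; the extremum
is searched within 50 ms after the pulse; the amplitude is the mean of a
2-ms window centred on it; trial amplitudes are averaged (5–10 trials).
The 2-ms window and trial averaging are stated by the emulated protocol;
the 50-ms search and 20-ms baseline windows are not, and are exposed as
arguments. uEPSPs are positive deflections; uEPSCs (pA) are negative and
reported as magnitude via a polarity flag. No single-trial rejection is
applied. The neck grouping splits at the sample median of the
length/width ratio (threshold overridable); the minimum spine length of
0.2 µm is applied before the ratio.

## Problem sizes

Recovery checks use n ≈ 10⁴ spines with 4-SE bands computed from the
configured SDs. The MI tuning curve uses 20 frequencies × 10 trials ×
100-s trials for the acceptance checks (5 trials in the faster analysis
driver); the case-1/case-2 comparison uses 20 replicates per case at the
case-1 somatic optimum. The integrator equivalence check uses 100 random
1-s instances; the type-I-error calibration uses 1000 null simulations;
the uncaging separation check uses 200 cohort regenerations of 35 + 35
spines measured through the trace stage.

## Known limitations

* The generator reproduces summary distributions and the specific
  correlation structures listed above; it does not model segmentation
  error, spatial clustering of ER⁺ spines, within-pair head-volume
  similarity beyond PSD, or >2 spine multiplicity per axon.
* The two-layer model is deliberately abstract: no conductances, no
  dendritic morphology, no NMDA nonlinearity; dendro-somatic coupling is
  a fixed 20-mV kick per dendritic spike.
* Plug-in MI is biased upward at short durations; conclusions here use
  long trials and equal-N comparisons only.
* Head/neck segregation in real reconstructions is annotator-defined;
  the pipeline takes head and neck measurements as given.
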