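# pulsecap

Channel-capacity estimation of pulsatile signaling pathways from
single-cell reporter trajectories.

## What this is for

Cells relay extracellular events through signaling cascades such as
MAPK/ERK, and the temporal pattern of activity pulses can itself carry
information. Given an epithelial cell line with a light-activatable
receptor (optoFGFR) and an ERK kinase-translocation reporter (ERK KTR),
one can stimulate the pathway with a *random train of light pulses* S
and ask how many bits per hour survive the trip to the reporter readout
R. `pulsecap` implements that analysis end to end for users who design
pulsatile stimulation protocols and quantify information transmission in
live-cell imaging data:

* **Protocol design** — binary (clocked), interval (geometric) and
  interval-with-gap pulse trains on a 1-min grid, their exact input
  entropy rates, and the entropy-maximizing geometric parameter for a
  given refractory gap;
* **Synthetic data** — a ground-truth-annotated generator of raw KTR
  tracks reproducing the measured response phenomenology (6-min peak,
  refractory response probability, non-responders, noise), so the whole
  pipeline is testable without microscopy data;
* **Preprocessing** — two-step normalization to translocation x_t and
  rejection of the least-variable track fraction;
* **Reconstruction** — slice-based kNN decoding of the pulse train from
  single-cell trajectories (scikit-learn-style estimators), with a
  configurable time-to-decision window;
* **Bitrate estimation** — the reconstruction-based estimator
  i(S,R) = [H(S) − H(S|R)]/Δt with conditional entropy from
  confusion/contingency tables and a permutation-averaged decomposition
  of the loss into false, missed and inaccurate detections, plus a
  reconstruction-free kNN neighborhood-entropy estimator with
  Miller–Madow bias correction.

The core quantities, in standard notation: input entropy rate
h(S) = 1/τ_clock (binary) or
h(S) = [τ log₂τ − (τ−1) log₂(τ−1)]/(τ + τ_gap) with τ = τ_geom
(interval encodings); conditional entropy per digit
H(S_d|R_d) or H(S_d|(R_{d−1}, R_d, R_{d+1})); bitrate
i(S,R) = 60·[h(S) − h(S|R)] bit/h, a lower bound on the channel
capacity C. See `docs/methods.md` for the full model description.

## Worked example

Estimate the bitrate of the best-performing protocol family (geometric
intervals with mean τ_geom = 10 min plus a 20-min refractory gap) on a
simulated 16-h experiment with 200 cells:

```yaml
# example.yaml
protocol:
  kind: interval_gap
  tau_geom: 10
  tau_gap: 20
  duration_min: 960
simulation:
  n_cells: 200
estimation:
  method: both
  n_rep: 5
seed: 1
```

```bash
pulsecap estimate -c example.yaml -o out/
cat out/summary.txt
```

```
pulsecap run summary
========================================
protocol: interval_gap (tau_geom=10 min, tau_gap=20 min)
input entropy rate: 9.380 bit/h
simulated cells: 200; analyzed tracks: 160 (rejected fraction f=0.20)
bitrate: 4.479 bit/h
resamples: mean 4.497 +/- 0.388 bit/h (n=5)
loss decomposition (bit/h):
  false           0.085
  missed          1.073  ####
  inaccurate      3.742  ###############
  total           4.901
```

Reading this: the protocol injects 9.380 bit/h (the closed-form entropy
rate of the geometric-with-gap interval distribution). After training a
kNN decoder on half the analyzed tracks and reconstructing the pulse
train from the other half, 4.48 bit/h survive; the 4.90 bit/h loss is
dominated by detections landing one minute early or late (cells with
shifted response timing), with missed pulses second and false detections
nearly absent — the characteristic loss profile of this protocol family.
The `±0.388` is the dispersion over 5 random train/test splits. The same
library calls are available directly (`pulsecap.run`,
`pulsecap.resample_estimate`, `pulsecap.recfree_bitrate`, ...), and
`pulsecap sweep -p t_D --values 2,3,5,7 ...` reproduces
time-to-decision and rejection-fraction sweeps.

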