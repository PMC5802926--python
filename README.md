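# meaburst

Analysis of rhythmic superburst dynamics in multielectrode-array (MEA)
recordings of cultured neuronal networks — spike detection, network-burst
and superburst detection, activation-pattern extraction, propagation-motif
clustering, and superburst-type switching statistics — paired with a
ground-truthed synthetic MEA data generator so that every stage can be
validated by parameter recovery.

## The problem

Mature dissociated hippocampal cultures on a 59-electrode MEA (8×8 grid,
200 µm pitch) can spontaneously produce *long superbursts*: episodes of
tens of seconds containing hundreds of short (30–100 ms) network bursts
repeating at roughly theta frequency (~10 Hz). Within each small burst,
firing sweeps across the array as a wave; the per-electrode first-spike
latencies (the *activation pattern*) encode the wave's direction. Across a
recording the waves fall into a small number of direction *motifs*, and
each long superburst is dominated by one motif — so the superburst
sequence behaves like a binary process with random switching between two
"functional" states. This package quantifies that structure:

* **Spike detection.** Per channel, a threshold `T = N_S·σ` on the
  band-pass-filtered signal `x` (0.3–8 kHz), with the robust noise scale
  `σ = median(|x|)/0.6745` and `N_S = 8`; minimal inter-spike interval
  1 ms, amplitudes 20–200 µV.
* **Burst detection.** The total spiking rate `TSR(t)` (spikes from all
  electrodes per 5 ms bin) is thresholded at `T_burst = 0.2·σ_TSR`; burst
  start is adjusted to the first spike after the crossing. Interburst peak
  intervals (IBPI) between adjacent TSR peaks give instantaneous
  frequencies `IF = 1/IBPI`. Initiation bursts (1000–3000 spikes) are
  split from small bursts (10–500 spikes) by 1-D K-means on
  spikes-per-burst.
* **Superburst detection.** The TSR is correlated with a Gaussian kernel
  (effective width 50 s, 10 ms step) and thresholded at `0.4·std`;
  superbursts with ≥ 21 member small bursts are classified *long*.
* **Patterns and motifs.** Per burst, a local plane fit of first-spike
  latency over each electrode's lattice neighbourhood yields a gradient
  vector field (the *dynamic pattern*); the mean vector's angle is the
  burst's *major direction*. Bursts are clustered into motifs by K-means /
  Gaussian-mixture EM on principal components of the latency vectors or on
  the (cos, sin) embedding of major directions, with the cluster number
  chosen by the Davies-Bouldin index
  `DB = (1/k) Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ` over k = 2…30 (DB < 1 ⇒ robust
  clusters).
* **Sequence statistics.** Long superbursts are typed by EM on their
  motif-content fractions; the package reports motif fidelity (fraction of
  small bursts carrying their superburst type's dominant motif), the
  superburst type-switch probability, and the small-burst motif-switch
  probability.

## Worked example

```python
import tempfile
from pathlib import Path
from meaburst import GeneratorConfig, PipelineConfig, generate_dataset, run_pipeline
from meaburst.io import write_spike_table

cfg = GeneratorConfig(seed=7, n_superbursts=6)   # two motifs, fidelity 0.915
spikes, truth = generate_dataset(cfg)

with tempfile.TemporaryDirectory() as tmp:
    inp = Path(tmp) / "spikes.h5"
    write_spike_table(spikes, inp)
    report = run_pipeline(inp, PipelineConfig(seed=0), Path(tmp) / "out")
print(report["median_if_hz"], report["motif_db"],
      report["switch_stats"]["motif_fidelity"])
```

On this 1226 s recording (273 568 spikes, 787 planted bursts) the pipeline
detects 812 bursts and all 6 long superbursts and prints:

```
median_if_hz              = 11.11    # small-burst rhythm, theta range
mean_intra_burst_rate_hz  = 131.1    # per active electrode, inside bursts
motif_db                  = 0.121    # two robust direction motifs (DB < 1)
motif_angle_difference_deg= 87.7     # near-perpendicular propagation axes
motif_fidelity            = 0.922    # planted 0.915
superburst_switch_prob    = 0.60     # 3 of 5 consecutive type switches
burst_motif_switch_prob   = 0.145
```

i.e. the network cycles at ~11 Hz, its bursts propagate along two nearly
perpendicular directions, and each superburst keeps one direction with
~92% fidelity while consecutive superbursts switch type about half the
time.

The same stages are available as a CLI:

```bash
meaburst simulate --seed 7 --out spikes.h5
meaburst detect-bursts spikes.h5 --bin-ms 5 --coeff 0.2 --out bursts.csv
meaburst detect-superbursts spikes.h5 --width-s 50 --coeff 0.4 --out sb.csv
meaburst cluster-motifs spikes.h5 --space angle --kmax 30 --out motifs.csv
meaburst report spikes.h5 --out bundle/
```

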