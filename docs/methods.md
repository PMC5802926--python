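# Methods

## Analysis pipeline

### Spike detection

Each channel is band-pass filtered at 300–8000 Hz with a 4th-order
Butterworth applied forward-backward (zero phase, so first-spike latencies
downstream are not biased by filter delay). The noise scale is the
Gaussian-consistent median absolute deviation `σ = median(|x|)/0.6745`,
computed once per channel over the whole recording (a sliding-window
variant is not provided; extracellular noise in these preparations is
stationary on the recording timescale). Events are threshold crossings of
`|x|` at `T = N_S·σ` with `N_S = 8`; both polarities trigger, and the
reported spike time/amplitude is the signed absolute extremum within 1 ms
after the crossing, which stabilizes timing against noise. A 1 ms minimal
inter-spike interval is enforced per channel, and events with extremum
magnitude outside 20–200 µV are discarded (the gate is applied post hoc
and can be disabled, e.g. for sub-threshold test templates). A channel
with `σ = 0` has no defined threshold and is skipped with a warning.

### Burst detection

The total spiking rate `TSR(t)` counts spikes from all electrodes in
half-open 5 ms bins. With `σ_TSR` the standard deviation of the whole TSR
trace, maximal runs of bins with `TSR > 0.2·σ_TSR` become network bursts:
start = first spike at or after the run's first bin, end = start of the
first bin back below threshold, peak = start of the maximal bin in the
run (earliest bin on ties). Runs separated by fewer than `min_gap_bins`
sub-threshold bins are merged (default 1, i.e. no merging); no minimum
burst duration is imposed by default. Note that run-thresholding is *not*
monotone in the threshold in general — raising the coefficient can split
a burst whose empirical rate profile is multimodal into several runs —
so the burst count is only guaranteed non-increasing in the coefficient
for unimodal burst profiles.

IBPIs are differences of adjacent burst peak times; the pipeline computes
them within superbursts only, over small bursts (initiation bursts and
inter-superburst gaps excluded), and summarizes each recording by the
median instantaneous frequency because the IF distribution is heavily
skewed. Initiation vs small bursts are separated by 1-D K-means (k = 2,
10 restarts) on spikes-per-burst; the cluster with the larger mean is
"initiation" and the reported threshold is the midpoint between the two
clusters' facing extremes. Degenerate inputs (no count contrast) label
everything small with a warning. A caveat worth knowing: a 2-means split
cuts at the midpoint of the two cluster means, not at the gap in the
data's support, so when initiation counts are few and widely spread
(1000–3000) an unusually small initiation burst can end up in the small
cluster even under the exactly optimal partition. The per-electrode
intra-burst rate is (spikes inside small-burst windows) / (summed
small-burst durations); electrodes silent in every small burst are
reported at 0 Hz and excluded from the active-electrode mean.

### Superburst detection

The TSR is correlated with a Gaussian kernel whose *effective width* —
read as full width at half maximum — is 50 s; the kernel is truncated at
±2 FWHM and normalized to unit sum so correlation magnitudes are
comparable across widths. The correlation is evaluated every 10 ms and
thresholded at `0.4·std`; each supra-threshold run is one superburst, and
bursts whose peaks fall inside the run are its members. Because the
kernel is two orders of magnitude wider than a small burst, detected
boundaries overshoot the underlying bursting block by roughly one kernel
scale (measured ~34 s for a 20 s block amid 200 s of silence); superburst
*counts* are reliable when blocks are separated by more than twice the
kernel width. Superbursts with at least 21 member small bursts are
classified *long* — a declared, configurable boundary placed just above
the 3–20 small bursts typical of regular superbursts.

### Activation and dynamic patterns

A burst's activation pattern is its vector of per-electrode first-spike
latencies (NaN where an electrode stayed silent); patterns with
completeness below 0.5 are rejected. The dynamic pattern fits, per
electrode, a least-squares plane to the latencies of the electrode and
its lattice neighbours within one pitch (Chebyshev distance, up to 8
neighbours; at least 3 non-missing, non-collinear sites required, else
that electrode's vector is undefined). The fitted spatial gradient points
from early to late activation, i.e. along the propagation direction;
missing latencies are never imputed for gradient fitting. The burst's
major direction is the angle of the arithmetic mean of all defined
vectors — magnitude-weighted, so electrodes with a strong local gradient
count more; an unweighted unit-vector mean is easy to derive from the
returned field if wanted. Mean gradients below 1e-12 s/µm (≈1 ns of
latency spread across the whole array) are numerically zero and leave the
direction undefined. Because a plane fit is exact for a linear latency
field over any non-collinear site subset, direction recovery is exact at
zero jitter, equivariant under joint rotation of array and wave, and
insensitive to dropping single electrodes.

### Motif clustering

For latency-space clustering, missing entries are imputed with the
burst's own maximum observed latency (the electrode activated "last or
never" — this preserves activation order without inventing early
spikes); electrodes missing in more than half the bursts are dropped
globally; columns are centered and projected onto 2 or 3 principal
components. K-means uses 20 restarts keeping best inertia; EM is a
full-covariance Gaussian mixture (20 restarts, k-means initialization,
covariance regularization 1e-6), both deterministic under a fixed seed.
Major-direction angles are clustered on their (cos, sin) embedding, which
removes the 0°/360° seam; per-motif angles are resultant-vector circular
means. The Davies-Bouldin index uses Euclidean distances and the
mean-distance dispersion `S_i`; the cluster number is the argmin of DB
over k = 2…30 (smallest k on ties, failed fits recorded as missing).
DB below 1 is taken as robust clustering. The reported angle difference
between two motifs is the circular difference in [0°, 180°]; a linear
difference of circular means is not meaningful and no significance test
on angles is provided.

### Superburst typing and switching statistics

Long superbursts are typed by a 2-component Gaussian mixture on their
motif-content fraction vectors (the last fraction column is dropped —
fractions live on a simplex and would otherwise make the covariance
structurally singular). Each type's dominant motif is the modal motif
across its superbursts' small bursts, earliest-occurring on ties. Motif
fidelity is the fraction of small bursts (within typed long superbursts)
carrying their type's dominant motif; the superburst switch probability
is the fraction of consecutive long-superburst pairs with different
types (regular superbursts are not included by default); the burst motif
switch probability is computed over the whole recording's small-burst
sequence, deliberately including pairs spanning superburst boundaries.
All three are invariant to relabeling motifs or types.

## Synthetic data generator

The generator is the package's ground truth and defines its study
conditions. A recording is a sequence of superbursts separated by long
gaps; each superburst opens with a motif-neutral initiation burst
(spatially unstructured spikes, count uniform in 1000–3000, duration
75 ms) followed by a train of small bursts whose onsets are spaced by
Gaussian draws (mean 90 ms, sd 12 ms — a ~11 Hz rhythm), with durations
uniform in 30–50 ms. Each small burst is a planar wave: electrode first
spikes lag the front by (position · û)/v with wave speed v = 100 µm/ms,
plus Gaussian jitter (sd 2 ms) truncated to the burst window; afterwards
each electrode fires as a homogeneous Poisson process calibrated so its
expected in-burst spike count is exactly `intra_burst_rate × duration`
(default 139 Hz), making the rate-recovery check exact in expectation.
Superburst types (1 or 2) are drawn independently and equiprobably by
default, or as a two-state Markov chain with an explicit switch
probability; a small burst carries its superburst's own motif direction
with probability `motif_fidelity` (default 0.915) and the other motif's
otherwise. Default motif directions are 29° and 302° (87° apart
circularly). `motif_directions=None` produces the structureless null:
latency fields are pure jitter and recovered directions are isotropic,
emulating regular superbursts. Background activity is a 0.05 Hz/electrode
Poisson process kept out of burst windows so every spike is attributably
planted or background. Inter-superburst gaps default to 120–300 s,
consistent with several long superbursts per tens of minutes and with
the separation the 50 s detection kernel needs to resolve neighbouring
superbursts. Randomness uses one root seed with four spawned child
streams (schedule, burst realizations, background, amplitudes), so equal
configs give byte-identical outputs.

What the generator does *not* emulate: electrode-specific firing-rate
heterogeneity, refractoriness and spike-sorting artefacts, serial
correlation of motifs beyond the superburst level, wave-front curvature
or spiral dynamics, non-stationary noise, and slow drifts in rhythm.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every property of
real recordings. One consequence of the within-type independence of
motif draws: at fidelity 0.915 the expected small-burst motif switch
rate is ≈2f(1−f) ≈ 15.6%, noticeably higher than rates reported for real
cultures at the same fidelity, where motif sequences are serially
correlated (runs of the same motif). The closed-form expectations used by
the recovery tests are derived from exactly this two-level process.

An optional renderer turns any spike table into raw voltage traces:
white Gaussian noise plus a fixed ~1 ms biphasic template (negative main
phase) at each spike time, skipping spikes closer than 1 ms to the
previous one on the same channel so templates never overlap.

## Numerical and interface choices

* Times are seconds from recording start, 0-based; all intervals are
  half-open `[start, end)`. Electrode ids are integers keyed to the
  59-site layout (8×8 grid, 200 µm pitch, four corner sites and one
  reference site absent).
* Spike tables round-trip losslessly between CSV (`%.17g`) and HDF5;
  every pipeline bundle records the package version and a SHA-256 hash of
  the canonical config JSON, so any parameter change changes the hash and
  two runs with equal input and config produce hash-identical bundles.
* Degenerate inputs fail loudly and specifically: empty spike tables,
  constant TSR (undefined burst threshold), flat correlation (undefined
  superburst threshold), coincident centroids (undefined DB), identical
  motif fractions (undegenerate typing impossible).

## Problem sizes

The test suite validates stages on recordings of 2–6 superbursts with
25–150 small bursts each (tens of thousands to ~10⁵ spikes), 10⁶-sample
noise draws for the estimator checks, 100 random tables for the
burst-detector oracle equivalence, 100 paired simulations for the
motif-vs-null Davies-Bouldin contrast, and 40 × 100 burst schedules for
the sequence-statistic recovery. The reproduction script analyses a
20-superburst recording (~10⁶ spikes, ~70 min equivalent) plus an
8-superburst structureless null; both complete in seconds on one CPU.
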