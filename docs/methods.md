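# Methods

## Pipeline

For a recording r_i(t), i = 1…19 (10–20 montage, default fs = 1000 Hz):

1. baseline (mean) removal per channel;
2. zero-phase 50 Hz notch (2nd-order IIR, Q = 30, forward–backward);
3. zero-phase 1–50 Hz FIR band-pass;
4. zero-phase 30–50 Hz FIR gamma extraction;
5. segmentation into non-overlapping 0.2 s windows (trailing remainder
   discarded, start-sample provenance kept);
6. screening: per-window PLV of the core pairs Fz–Cz and Fz–Pz, combined
   by arithmetic mean (min/max available); windows with score ≥ the
   (1−q)-quantile are kept (default q = 0.3; an absolute threshold τ is
   available). Ties at the threshold are all kept; if an absolute threshold
   excludes everything, the single best window is kept;
7. per-window wPLI over all 171 channel pairs, elementwise average across
   selected windows;
8. binarization by proportional density d = 0.33 (top round(d·171) = 56
   weights; ties broken by fixed lexicographic channel-pair order), chosen
   so a 19-node graph has mean degree ≈ 6, the magnitude reported for such
   balance networks; an absolute-τ rule is available. Node degree is
   computed on the binary graph; weighted strength is retained alongside;
9. per-region degree mean ± sample SD (frontal 7, central 5, occipital 7
   channels) and two-sided paired t-tests between conditions (uncorrected,
   mirroring common reporting; apply Bonferroni externally if desired);
10. Welch PSD per channel (Hamming taper, 1 s segments, 50% overlap,
    one-sided density scaling) and per-region band-integrated power.

### Numerical choices

* **Zero-phase filtering.** Phase metrics are bias-sensitive to group
  delay, so all filters are zero-phase. The FIR stages use a symmetric
  (linear-phase) kernel applied by centered FFT convolution, which is
  exactly zero-phase in a single pass and keeps the designed magnitude
  response; kernel length follows the Hamming transition-width heuristic
  (3.3·fs/Δf, default transition Δf = 2 Hz → 1651 taps at 1 kHz).
* **Hilbert transform on the continuous record.** Instantaneous phases are
  extracted once from the continuous filtered record and then sliced at the
  window boundaries, avoiding Hilbert edge artifacts in 200-sample windows;
  a per-window transform is available (`per_window_hilbert=True`).
* **PLV/PLI sums.** All metrics average over all N samples of a window.
* **PLI sign convention.** PLI is computed as mean sign(sin θ) with
  sign(0) = 0; the absolute value is reported (range [0, 1]) and the signed
  mean is retained on the result object.
* **wPLI cross-spectrum.** X(t) is estimated per time sample from the
  analytic signals and averaged within the window. The 0/0 case (purely
  zero-lag relation, Im X ≡ 0) is defined as 0; in floating point the
  denominator is compared against 1e-12 of the mean cross-spectrum
  magnitude so rounding residue of exactly zero-lag pairs does not produce
  spurious values.
* **Degenerate channels.** Constant (e.g. all-zero) channels have no
  defined phase: scalar metrics raise `DegenerateChannelError`; pairwise
  matrices flag the channel (NaN row/column plus a `flagged` list) rather
  than silently zeroing it, and binarization refuses flagged matrices.

## Synthetic generator

The generator emulates the statistical structure the pipeline needs, not
the biophysics of the head:

* **Baseline.** Each channel is an independent phase-diffusion (Wiener
  phase) oscillator at a 40 Hz carrier: φ(t) = 2π·40·t + W(t), with
  diffusion D = 2π·linewidth (default linewidth 8 Hz, i.e. a Lorentzian
  line that fits inside the 30–50 Hz band). Under it, pairwise PLV decays
  predictably to zero with record length. Carriers are unit RMS with a slow
  (τ = 1 s) ±10% amplitude modulation.
* **Events.** Balance adjustments are transient coupling episodes: during
  an event all listed channels lock to a shared diffusing driver with fixed
  per-channel offsets (so each listed pair holds its prescribed mean lag)
  plus slow Ornstein–Uhlenbeck phase jitter (τ = 50 ms, slow enough to
  survive the gamma band-pass). Jitter variance per channel is
  1/(2κ(c)) with κ(c) = min(2c/(1−c²), 50), a monotone map from coupling
  strength c to von-Mises-like concentration of the pair phase difference;
  the pair resultant length is ≈ c over the useful range and ≥ 0.95 at
  c = 1. Event waveforms are crossfaded in and out over 20 ms to avoid
  spectral splatter at the boundaries. Locked oscillations are scaled by
  (1 + c) (activation gain), so coupling gradients also appear as band-power
  gradients, as task EEG shows.
* **Noise.** 1/f^α background (default α = 1) at 5 dB carrier-to-noise.
* **Volume conduction.** A zero-lag linear mixing stage blends every
  channel with one common source: y_i = (1−m)·x_i + m·s. This is the
  minimal model of the "homologous signal" problem: it inflates PLV without
  creating any true lag, and the wPLI should ignore it. The mixing matrix
  is part of the ground truth.
* **Presets.** P1–P4 plant region-graded coupling at Poisson-timed events
  (default 12/min × 1 s ≈ 20% coverage, 180 s records): every channel locks
  to its region core (Fz/Cz/Pz) at the region's strength, the core pairs
  Fz–Cz and Fz–Pz lock at 0.9 in all paradigms (they are the screening
  index), and per-channel offsets are redrawn each event so pairwise lags
  vary. Region strengths: P1 = (0.8, 0.8, 0.8) (frontal, central,
  occipital); P2 = (0.9, 0.8, 0.35) — blocked vision depresses occipital;
  P3 = (0.9, 0.35, 0.8) — blocked proprioception depresses central;
  P4 = (0.9, 0.4, 0.35) — both blocked, frontal dominant.

### What the generator does not emulate

Realistic lead fields (mixing is one global common source, not a
distance-dependent field), ocular/muscle artifacts, non-stationary
background rhythms (alpha blocking etc.), inter-subject variability, and
any true biophysics of balance control. Passing tests therefore show that
the *pipeline* recovers what was planted under a fair model of the
measurement problems (random event timing, volume conduction, 1/f noise) —
they are not evidence about human cortex.

## Validation experiments (tests/test_acceptance.py)

Problem sizes are the package's own choices: the structural and oracle
checks run on seconds of data; the volume-conduction check uses 60 s
records at mixing 0.5; screening recovery uses 60 s records with twelve
1 s events (20% coverage, coupling 0.9, lag π/2) over 20 seeds; the
regional-ordering check runs the full pipeline on 60 s preset records over
20 seeds per paradigm.

The wPLI-vs-PLI sensitivity experiment (dynamic range across a coupling
sweep at lag π/4) is defined at study scale — 180 s records with zero-lag
mixing 0.5 — because that is the regime where the PLI's weakness is
visible: zero-lag contamination erodes its sign counts near the real-axis
discontinuity, while the wPLI downweights those samples. On short,
unmixed records both metrics simply saturate between a sampling floor and
1 and their ranges tie.

## Limitations

* The screening threshold (q = 0.3), the core-pair combination rule (mean)
  and the edge density (0.33) are protocol defaults, not estimated
  quantities; published degree values depend on the analogous unstated
  choices of each study and are data-dependent.
* PLI/wPLI estimators are positively biased at small effective sample
  sizes; 0.2 s gamma windows carry roughly a handful of independent phase
  samples, so per-window values should be compared, not interpreted
  absolutely.
* EDF files are read (via MNE); recordings are written as delimited text
  or `.npy` + JSON sidecar.
* ICA artifact removal is out of scope; input recordings are assumed
  artifact-handled upstream.
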