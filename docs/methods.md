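# Methods

This note documents the models, parameter choices and numerical
conventions behind `erpspell`, and what the synthetic study can and
cannot show about real EEG.

## Stimulus scheduling

One sequence = 12 flashes; each of the 36 symbols appears in exactly
two flash sets per sequence in every condition. For RC these sets are
the 6 physical rows and 6 physical columns in uniformly random order.
For RASP and RASP-F a fresh uniformly random virtual 6×6 arrangement is
drawn **once per sequence**; its 6 virtual rows and 6 virtual columns
flash in random interleaved order (rows = self face, columns = non-self
face in RASP-F). Re-randomizing per sequence rather than per flash is
the only scheme that simultaneously guarantees "every symbol twice per
sequence" and a clean 6:6 row/column face split; it is the package's
chosen reading of "shuffled" and is deliberate.

Timing: flash 135 ms + gap 50 ms (SOA 185 ms), 2 s countdown per trial,
10 sequences per trial by default; no enforced minimum target-to-target
interval (TTI) — double flashes occur by chance, which is what makes
the TTI analysis possible. Onsets are bookkept in integer microseconds
so event logs round-trip exactly through 6-decimal TSV.

## The forward model

The generator produces what the analysis pipeline assumes: 29-channel
EEG at 500 Hz = 1/f^α background noise + stimulus-locked components.

**Components.** Each component is a half-sine kernel supported exactly
on its latency window, scaled by a per-(stimulus class, target)
amplitude and a Gaussian spatial profile exp(−d²/2s²) over the
projected 2-D electrode positions:

| component | window (ms) | polarity | peak | amplitudes (µV) |
|---|---|---|---|---|
| P300 | 280–370 | + | Cz | target 5 (any class) |
| N170 | 130–200 | − | PO7 | face flashes 3, +1 if target |
| N400f | 400–550 | − | Cz | self-face target 4, non-self target 2 |

Amplitudes are free parameters, not estimates of any recording; they
were chosen so the three conditions order qualitatively as
RASP-F > RASP ≥ RC in decodability. The P300 of a target flash is
further scaled by a TTI-dependent factor {0: 0.4, 1: 0.6, 2: 0.8,
≥3: 1.0}, emulating the refractory rise-and-plateau of target responses
after recent targets.

**Noise.** Per channel, spectrally shaped Gaussian noise with power
∝ 1/f^α (α = 1), plus a common-mode term (30 % of σ) shared across
channels for spatial correlation; the two parts are scaled so the total
per-channel standard deviation is σ = 6 µV. The default σ was fixed
once, during generator design, so that the pipeline operates in the
regime typical of able-bodied P300 spelling (per-flash classification
~0.87–0.92, single-sequence letter accuracy ~0.6–0.8); all acceptance
checks were written after this default was frozen.

**Study layout.** One simulated subject = 3 conditions × (training run:
`BRAIN_COMPUTER_INTERFACE`, 24 trials; test run: `KOREAUNIVERSITY`,
15 trials). Test-run amplitudes are scaled by 0.95 to emulate
session-to-session transfer loss (the two phases are "recorded on
different days"). Cohorts add a per-subject ERP gain drawn uniformly
from [0.8, 1.2] as a crude model of inter-subject SNR spread; subjects
are otherwise exchangeable.

**What the generator does not model:** eye/muscle artifacts, volume
conduction from a head model (the Gaussian topography is schematic),
latency jitter, non-stationarity, habituation, or attention lapses.
Passing tests therefore show the *pipeline* is correct and that the
paradigm effects follow from the assumed ERP structure — not that real
subjects would produce these exact numbers.

## Preprocessing

Zero-phase (forward–backward) filtering throughout, so component
latencies are not shifted. Band-pass 0.1–30 Hz as a cascade of
order-5 Butterworth high- and low-pass sections (a joint band-pass
design with edges 300× apart is numerically ill-conditioned; the
cascade is equivalent and stable). Decimation 500 → 100 Hz via an
order-8 Chebyshev type-I anti-alias filter (0.05 dB ripple, cutoff
0.8× the new Nyquist) — conventional EEG-toolbox defaults; the filter
orders are configurable. Epochs cover the half-open window
[−200, 800) ms (100 samples at 100 Hz; t = 0 belongs to the
post-stimulus side); baselines are per-epoch, per-channel means over
[−200, 0) ms.

## Feature selection

The signed-r² map uses the population (divide-by-N) pooled standard
deviation, which makes it exactly the signed squared Pearson
correlation between amplitude and the 0/1 label — an unambiguous
oracle. Interval selection maximizes the channel-summed r² score s(t)
inside 100–600 ms: repeatedly take the best unmasked sample, grow a
contiguous interval while s(t) ≥ half the peak, mask it; if scores run
out before 8 intervals, unoccupied stretches fill in left-to-right
(an all-zero map yields 8 equal tiles). Interval bounds sit halfway
between samples, clipped to the window, with (start, end] membership.
Selection runs on training data only; the intervals are stored in the
model and reused unchanged on test data, preventing leakage.

## Classifier

LDA on the 232-dimensional features with pooled within-class
covariance (each class centered by its own mean), shrunk toward the
trace-preserving target νI with the analytic (Schäfer–Strimmer)
intensity γ* = Σ Var̂(s_ij) / Σ (s_ij − t_ij)², clamped to [0, 1];
γ = 1 when S already equals νI, and identical class means yield w = 0
by convention. The numerator is computed via
Σ_k‖x_k‖⁴ − n‖W̄‖_F², keeping memory at O(np + p²). The bias is the
class-mean midpoint (no priors): decoding uses score ranks only, so
priors cannot change the argmax, and 0 is the natural per-flash
decision threshold.

## Evaluation

Letter evidence for symbol ℓ is the sum of flash scores over all sets
containing ℓ within the first n sequences; ties break to the smallest
row-major matrix position. On RC schedules this reduces exactly to
best-row + best-column intersection. ITR uses the symmetric-channel
bits-per-selection formula with 0·log 0 ≡ 0, clamped to 0 below chance,
and an explicit selection duration = countdown + n·12·SOA; every ITR
output states the duration used, since the timing accounting is a
reporting convention, not a property of the classifier.

Chronological cross-validation splits epochs in recording order into
k = 8 contiguous folds (earlier folds absorb remainders); strata
(self-face / non-self-face) are selected before splitting. Statistics:
exact two-sided binomial sign test with ties dropped; pooled-variance
two-sample t-tests on subject-level means (15 observations per group,
not pooled epochs); Bonferroni as p·m capped at 1; two-way
fully-within-subject ANOVA with effect×subject error terms, no
sphericity correction, and F ≡ 0 when both effect and error sums of
squares vanish. TTI bins are 0–4 plus ≥5; empty bins are reported as
undefined, never as 0. The error topography centers targets in an
11×11 offset grid whose total equals the trial count.

## Problem sizes and determinism

Default runs are full-scale (24/15 trials × 10 sequences × 12 flashes
at 500 Hz); the acceptance script and acceptance tests use a 15-subject
cohort, examples use 1–5 subjects. All randomness flows from a single
seed through `numpy.random.SeedSequence` spawning (schedules, noise,
subject gains), so identical seeds reproduce schedules byte-for-byte
and signals bit-for-bit.

## Known limitations

- The interval-growing heuristic is one concrete reading of r²-based
  interval selection; other variants (per-channel sign consistency,
  weighted channels) would select slightly different intervals.
- EDF storage is 16-bit; round-trips quantize at (physical span)/2¹⁵,
  well below the noise floor but not bit-exact.
- The adjacency advantage of RASP over RC is only partially emulated:
  the generator has no attention/crowding model, so RASP's benefit in
  simulation comes from error geometry, not from cleaner target ERPs.
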