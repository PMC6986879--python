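# Methods

`prpdecode` analyzes olfactory-bulb local field potentials (LFP) recorded
while a mouse performs go/no-go odor discrimination: on each trial an
odorant — rewarded (S+) or unrewarded (S−) — is delivered for 2.5 s, and
the animal reports its decision by licking (or withholding licks at) a
waterspout. The package quantifies how the coupling between the slow
theta rhythm and fast oscillations encodes the *contextual* identity of
the odorant (is it rewarded?) and how that code changes with learning.

## Phase-amplitude coupling and the modulation index

The raw trace is band-filtered with an order-20 Butterworth applied
forward and backward (zero phase). The filter is realized as cascaded
second-order sections: a direct polynomial realization at this order is
numerically unstable, while the SOS cascade is exact in design and
stable in evaluation. Default bands: theta 6–14 Hz (an alternative
2–14 Hz respiratory-theta definition is provided), beta 15–30 Hz, high
gamma 65–95 Hz.

The analytic signal (Hilbert transform) of the theta-band trace gives
the instantaneous phase; the analytic amplitude of the fast band gives
its envelope. Phase convention: 0° at the theta waveform maximum
(cosine convention), increasing through the cycle, reported in
[0°, 360°). The convention is configurable
(`AnalysisConfig.phase_origin_deg`) because peak-phase values are only
interpretable relative to a stated origin.

The mean envelope is tallied in N = 51 phase bins and normalized to a
distribution p. Coupling strength is the modulation index

    MI = (ln N − H) / ln N,   H = −Σ p_j ln p_j,

the Kullback–Leibler distance of p from uniform scaled to [0, 1]: 0 for
no coupling, 1 for an envelope concentrated in a single bin. Per-trial
PAC uses the odor-aligned [0, 2.5] s window. The across-trial
variability of the preferred phase is summarized by the circular
variance 1 − R of the per-trial peak angles (R = mean resultant
length); the ordinary variance of the centered angles in deg² is
available behind a flag since either convention appears in practice.

## Phase-referenced power (PRP)

Band power is estimated with a continuous complex Morlet transform
(7 cycles by default). The squared wavelet magnitude at each
1 Hz-spaced center frequency estimates the PSD smoothed by the
wavelet's spectral window (power-response sd s = f/cycles); summing
over the grid with the resolution correction step/(√π·s) integrates
power over the band, so a mid-band sinusoid of amplitude a reads its
true mean power a²/2. Power is reported as 10·log10(P / 1 µV²); an
optional per-trial baseline-subtracted mode uses the [−1, 0) s window.

Reference phases — the peak and trough of the amplitude-by-phase
distribution — are determined per electrode from the pooled S+ trials
only, and held fixed for both odorants and all stages within a session:
the question is what a downstream reader locked to the *learned*
reference would see. Power is sampled instantaneously once per theta
cycle at the upward crossing of the reference phase, averaged within
0.1 s bins on the trial-aligned grid ([−1.5, 4] s by default; t = 0 is
the odor-valve diversion, not odor arrival at the nose, which lags by
roughly 0.07–0.13 s — a configurable offset exists and defaults to 0).
Bins without a crossing are filled by linear interpolation (edge bins
by nearest value); a debounce of 0.3 theta periods suppresses duplicate
crossings from phase jitter.

## Decoding

For every 0.1 s bin, a two-class linear discriminant with pooled
within-class covariance is trained on all trials but one and tested on
the held-out trial, cycled over trials (leave-one-out). The covariance
gets a small ridge (ε = 1e-6·trace/M) so the solve stays well-posed
when trials barely outnumber the M electrodes; exact discriminant ties
are broken by a seeded coin flip.

The chance band is a permutation null: the identical leave-one-out
estimator run on label-permuted data, scored against the permuted
labels (20 permutations by default). Scoring the permuted-training
decoder against the *true* labels would center the control exactly at
50% while the true-label estimate carries the usual leave-one-out
hold-out bias (the held-out trial's class is underrepresented in
training), so only the permutation form is a valid reference for "no
class information". The reported band is the normal-approximation 95%
interval (mean ± 1.96 sd) of the permutation accuracies.

Decoding over the odor window is summarized as a normalized area under
the accuracy curve: mean of max(accuracy − 50, 0)/50 over [0.5, 2.5] s,
anchored at 0 for chance and 1 for perfect decoding; below-chance
accuracy is clipped rather than rewarded. Per-outcome accuracy (Hit,
Miss, CR, FA) groups the held-out predictions by outcome; the decoder
itself is always trained on all trials. PC1 time courses use a per-bin
principal axis over the pooled trials-by-electrodes matrix, with the
per-bin sign ambiguity resolved so the S+ mean score is non-negative.

## Decision times

Licks are scored 0/1 per 0.1 s bin (presence, never counts). Per bin,
a two-sided Wilcoxon rank-sum test compares S+ against S− trials — for
licks, the binary lick score; for the decoder, the predicted identity
(1 = predicted S+), which equals correctness on S+ trials and
1 − correctness on S− trials. Raw correctness cannot work here: a good
decoder is correct on *both* classes, so correctness never separates
them. The rank-sum p-value uses exhaustive enumeration over all
C(n1+n2, n1) assignments (midranks under ties) when the smaller sample
has ≤ 9 observations, and the tie-corrected normal approximation with
continuity correction otherwise; the two agree within 0.01 well below
that switch point. The decision time is the earliest bin at or after
odor onset whose p-value, and those of all later bins through the end
of the odor epoch (2.5 s), stay below α = 0.05 — a sustained crossing,
so transient pre-odor dips are ignored. If no sustained crossing
exists the decision time is undefined, not 2.5 s.

## Dimensionality

For M channels with covariance eigenvalues λ_i, the participation
ratio dim = (Σλ)²/Σλ² is M when all eigenvalues are equal and m when
exactly m equal eigenvalues are nonzero. It is computed per 0.1 s bin
from the covariance across trials of the M-dimensional PRP vector,
within each (odorant × stage) group by default (a combined mode
exists), and normalized to the mean over the [−1, 0) s baseline
window. Negative numerical eigenvalues are floored at zero. Pooling
across sessions concatenates electrodes (channels = 16·N) and
truncates, per odorant, to the smallest trial count across sessions
(first n trials in session order).

## Inference utilities

Confidence intervals are percentile bootstrap of the mean, 1000
resamples, seeded; the input is sorted before resampling so the
interval is invariant to input order. Multiple comparisons use
Benjamini–Hochberg step-up FDR, reporting the largest rejected p-value
as the threshold. Pairwise post-hoc comparisons apply an
Anderson–Darling normality check to each sample at 5%: both consistent
with normality → two-sample t-test, otherwise rank-sum. Omnibus
multi-factor testing is out of scope here; standard GLM machinery
(e.g. statsmodels) applies directly to the exported tables.

## Synthetic data

Two generators define the test bed.

**Two-oscillation validation signal** (20 s at 20 kHz): an 8 Hz cosine
plus a 40 Hz cosine. Uncoupled: constant 40 Hz amplitude; the measured
MI is then limited only by filter/Hilbert edge transients, ~3×10⁻⁴ at
these defaults (it scales down with duration — the figure to check
against is the order of magnitude). Coupled: the 40 Hz cosine is
multiplied by a gaussian train, FWHM (1/8 Hz)/2 = 62.5 ms, centered at
180° of each slow cycle, on top of a small residual tonic 40 Hz
component (5% of burst amplitude by default — pure bursts give
MI ≈ 0.011, and the tonic floor lowers it toward 0.009).

**Go/no-go session generator.** Trials repeat every 7 s; the odor
valve opens 2 s into the trial for 2.5 s. Each electrode carries a
shared theta carrier (8 ± 0.3 Hz per trial, 100 µV), plus beta and
high-gamma burst trains whose envelope is a wrapped gaussian in theta
phase (FWHM 180°) around a per-trial burst phase drawn von Mises
around the configured peak phase (κ sets across-trial phase jitter).
Burst amplitude (30 µV, 15% tonic floor) is modulated three ways:

* a rank-m latent structure — m = 3 unit-power sources mixed through
  an orthonormal 16×m matrix — sets the baseline participation ratio
  to m. Latents are redrawn every 0.1 s (`latent_tau_s`): real
  oscillatory power fluctuates cycle to cycle, and a per-trial-constant
  latent would make every time bin re-measure the same trial vector,
  rendering per-bin decoding accuracies perfectly correlated across
  bins and per-bin null calibration meaningless;
* an odor-epoch gain per odorant × stage (proficient default: S+
  +6 dB, S− −6 dB; naive: 0 dB both), applied as an amplitude factor;
* a trial-common gain fluctuation during the odor epoch
  (`shared_gain_sd`, proficient default 0.35) — the shared component
  that collapses dimensionality toward 1 when the odorant is on.

Sensor noise is 1 µV white. Sessions are synthesized at 1 kHz: every
analyzed band lies below 100 Hz, and this keeps a 100-trial,
16-electrode session (~45 MB) analyzable end-to-end in a couple of
minutes on one core; the two-oscillation validation signal keeps its
20 kHz rate.

Licking is a ~7 Hz quasi-regular train starting 1 s before odor onset.
On "go" trials (probability `p_go`: proficient 0.95 for S+, 0.10 for
S−; naive 0.95/0.85) it continues past the response window; on "no-go"
trials it stops 0.25 ± 0.05 s after odor onset — the configurable
S+/S− divergence latency. Outcomes are *not* assigned: they emerge by
scoring the generated lick trains with the same four-block rule used
for real data, so configured go probabilities reappear as Hit/FA rates.
The generator returns a ground-truth record (analytic MI implied by the
envelope shape, burst phase, gains, latent count, lick divergence) for
parameter-recovery tests.

What the generator does not emulate: respiration-locked theta
(sniffing), 1/f background spectra, electrode drift and artifacts,
inter-trial engagement dynamics, and any biophysical network structure.
Passing recovery tests therefore demonstrates that the estimators
recover the statistical structure they assume, not that real recordings
satisfy those assumptions.

## Numerical and scale choices

* Windows are cut from the continuously filtered recording (with 0.5 s
  pad where per-window filtering is unavoidable), avoiding per-window
  filter transients.
* Phase bins are half-open [j·360/N, (j+1)·360/N); an unpopulated bin
  is an error instructing longer input rather than a silent NaN.
* Test sessions run at 500 Hz with 8 electrodes and 40–100 trials; the
  parameter-recovery suite uses the full 16-electrode, 100-trial
  configuration. The recovery tolerances (peak phase ±15°, odor-gain
  contrast ±2 dB, latent dimensionality ±0.5, lick decision time
  ±0.1 s, MI within 30%) reflect finite-sample noise at those sizes.
* All randomness flows from explicit seeds; sessions, pipeline runs and
  the manifest checksums are bit-reproducible for a fixed seed.

## Known limitations

* The LDA assumes shared within-class covariance; strongly
  class-dependent covariance would favor its quadratic counterpart,
  which is not provided.
* Decision times are quantized to the 0.1 s bin grid and bounded by the
  odor epoch; latencies beyond 2.5 s are reported as undefined.
* The participation ratio is a linear, second-moment notion of
  dimensionality; nonlinear manifold structure is invisible to it.
* Per-bin PRP rests on ~1 theta crossing per 0.1 s bin, so single-bin
  values are noisy by construction; conclusions should rest on window
  averages or time-course statistics, as the pipeline's summaries do.
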