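# Methods

## Decoding model

The decoder assumes a *time-synchronous* stimulation protocol: every
selection starts with a stimulation onset to which both the EEG window and
the class templates are locked, so a window of `n_y` samples is comparable
to the first `n_y` columns of a template.  Targets are separated either by
the circular lag of a shared binary code (c-VEP) or by flicker
frequency/phase (SSVEP); in both cases classification reduces to
correlating a spatially filtered window against per-class templates.

**Spatial filters.** Per class, the `n_b` training trials are averaged into
a template `X` and a filter `w` is obtained as the template-side first
canonical weight of CCA(`[T_1 … T_nb]`, `[X … X]`).  CCA is solved by
whitening both auto-covariances (symmetric eigendecomposition) and taking
the SVD of the whitened cross-covariance.  A ridge of `1e-8 · tr(C)/p` is
always added to the auto-covariances; genuine rank deficiency (judged on the
unregularized spectrum) additionally raises a warning.  CCA weights are
sign-ambiguous; we anchor the sign deterministically by making the
largest-magnitude coefficient of `w` positive (the convention sklearn uses
for SVD factors), then normalize to unit Euclidean norm.  Correlations are
scale-invariant, so both choices are conventions for reproducibility and
logging, not tuning knobs.

**Ensemble correlation.** All `K` filters are applied to both the window
and the reference and the `K` projections are stacked into one long vector
before taking a single Pearson correlation.  Stacking uses the similarity
of the class filters: each projection contributes evidence, and the joint
correlation discriminates better than any single projection at short
windows.

**Filter bank.** Sub-band `m` spans `m·8`–60 Hz (8th-order Butterworth,
forward–reverse filtered so the phase response cancels).  Per-band
correlations combine with weights `a_m ∝ m^(−1.25) + 0.25`, normalized to
sum to one — a fixed, decreasing profile mirroring the amplitude decay of
VEP harmonics.  Defaults: `M = 1` for c-VEP, `M = 5` for SSVEP; both
configurable.

**Reference filtering (design choice).** Online windows are short, and an
8th-order zero-phase band-pass on a 30–300-sample window is dominated by
edge transients.  Two reference constructions are provided via
`template_filtering`:

* `"window"` (default): the *raw* class template is truncated to `n_y`
  samples and passed through exactly the same in-window filter as the data,
  so both sides carry identical transients (matched linear treatment).
* `"full"`: the reference is a plain slice of the full-length band-filtered
  template.

The two agree as `n_y` grows (transients become negligible); at 50–100 ms
windows the matched variant is decisively more informative, which is why it
is the default.  For windows shorter than the filter's standard reflection
pad (3·(2·sections+1) = 51 samples) the pad shrinks to `n_y − 1` on both
sides of the correlation identically.

**Dynamic window.** Amplifier blocks of `n_a = 30` samples (50 ms at
600 Hz) accumulate in a buffer.  Below `n_y_min` no classification is
attempted; between the bounds the full buffer is classified; above
`n_y_max` whole cycles (`n_c` samples) are discarded from the front — since
`n_a | n_c` and `n_y_max` is a multiple of `n_c`, the trimmed window starts
at a cycle boundary and stays phase-locked to the stimulus.  If the trimmed
remainder is shorter than `n_y_min` (possible whenever
`n_y_min > n_y_max − n_c + n_a`), no classification is attempted and the
window regrows from the last cycle boundary.  A decision is emitted iff
`n_y ≥ n_y_min` and `Δ_C ≥ β` (boundary inclusive); argmax ties break to
the lowest class index.  After an accepted decision the buffer clears and a
1 s gaze-shift pause follows during which amplifier blocks are ignored.
An optional `max_wait_s` horizon aborts a selection that never reaches the
threshold (disabled by default; the synthetic stream additionally enforces
`max_s_per_target` so unattended runs terminate).

## Calibration

`n_y_min` and `β` come from the training data alone.  Leave-one-block-out
cross-validation classifies every held-out trial truncated to each window
of the grid `30, 60, …, 3·n_c` samples, ungated (β is an *output* of
calibration, not an input).  Accuracy per window converts to bits/min via
the Wolpaw ITR with `t = n_y/f_s + 1 s` gaze shift — including the gaze
shift is what makes a perfect-accuracy 0.45 s window worth
180/1.45 = 124.14 bits/min.  The ITR argmax (ties → smallest window)
becomes `n_y_min`; `β` is the smallest per-class mean margin
(target λ̃ minus best non-target λ̃) at that window, floored at zero with a
warning when classes overlap.  Leave-one-trial-out is available as a config
switch; block-wise is the default because training blocks are the natural
exchangeable unit.  A manual β override supports deliberately more
responsive settings.

Note the bits term of the ITR is the KL divergence between the induced
symbol distribution and uniform chance: it is non-negative for every
`p ∈ [0, 1]` and zero exactly at `p = 1/K`, so the defensive clamp at zero
never actually fires.

## Synthetic EEG

The generator emulates the statistics of 16-channel, 600 Hz occipital
recordings; it is a benchmark harness, not a head model.

* **SSVEP response:** `Σ_{h=1..3} 0.5^(h−1) · sin(2π·h·f·t + h·φ)` —
  fundamental plus two decaying harmonics, phase-locked from onset.
* **c-VEP response:** the bipolar (±1) code drive convolved with a
  gamma-shaped single-flash kernel (mode 80 ms, FWHM 60 ms, unit peak).
* **Channel mixing:** a fixed linear gain gradient (0.2 → 1.0 across
  channels), mimicking the posterior dominance of visual responses.
* **Noise:** 30 % white + 70 % 1/f power, band-limited 2–60 Hz like the
  amplifier's analog band-pass; no 50 Hz mains component is generated, so
  the notch filter is not modelled.
* **SNR:** the evoked part is rescaled per trial so total evoked power over
  total noise power (across channels) equals `snr_db` exactly.
* **Randomness:** one root seed; trial `i` draws from substream
  `(seed, i)`, so any trial regenerates in isolation and whole pipelines
  are byte-reproducible.

Consequences worth knowing: the c-VEP kernel's 80 ms latency means windows
shorter than ~0.1 s contain almost no evoked energy — small-window accuracy
saturates for SSVEP first; trial-onset latency jitter defaults to 0 ms
(cue-locked recording) and can be enabled; and none of alpha-band
interference, artifacts, electrode drift or per-target monitor latency is
modelled.  Passing tests therefore demonstrate the correctness and internal
consistency of the decoding/calibration machinery under a controlled signal
model, not performance on human EEG.

## Speller

Layer I shows four character groups ([A–G], [H–N], [O–U],
[V W X Y Z _ .] — sizes fixed by the 2×4 layout, membership contiguous by
convention), three word suggestions and UNDO; Layer II shows the seven
characters of the chosen group and BACK.  Suggestions rank bi-gram
continuations of the previous word (text between the last two separators)
matching the current prefix by co-occurrence count, backed off to unigram
frequency, ties lexicographic.  Accepting a suggestion replaces the current
partial word and appends the separator `_`; that convention is what makes
`JUST_DO_IT` writable in seven selections, and a copy-spelling session
therefore terminates when the typed text equals the target sentence with or
without a trailing separator.  UNDO reverts the last text-modifying command
(navigation has no text effect, so BACK, group entries and empty suggestion
slots are not pushed onto the history).  The packaged lexicon is a
synthetic ~200-word stand-in for a corpus-derived frequency table with
Zipf-like counts.

The copy-spelling simulator uses a greedy user model (take a displayed
correct suggestion, else type the next character; repair divergent text
with UNDO, wrong-group detours with BACK).  Command errors are injected
uniformly over the seven wrong targets with a configurable rate, or every
selection can be driven end-to-end through the decoder on a fresh synthetic
stream.  OCM = 60 · output characters / elapsed seconds; corrections cost
commands, so errors lower OCM without entering the formula explicitly.

## Problem sizes in tests

The default training design (6 blocks × 8 targets × 3 cycles) is used
wherever the study conditions matter.  Heavier sweeps scale down: the
SNR-recovery ladder uses a 90-sample window grid (window choice trends are
grid-invariant) and the end-to-end pipeline checks use 3 blocks × 1 cycle
with a 210-sample grid.  The pooled monotonicity check is a Mann–Kendall
style sign test: over 10 seeds × 4 SNRs, all within-seed SNR pairs are
counted as concordant (window shrinks or ties) vs discordant, and the
binomial one-sided p-value must fall below 0.05.

## Known limitations

* The generator's gamma kernel and harmonic model are stylized; real VEP
  latencies, amplitudes and topographies vary per subject.
* Only the first canonical correlation pair is used; multi-pair extensions
  are out of scope.
* Zero-phase filtering is acausal: the online loop refilters the whole
  buffered window each block rather than streaming, which is fine at desk
  scale but not an embedded real-time design.
* The speller models words over A–Z only; `.` and `_` are ordinary
  characters with no sentence-level semantics.
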