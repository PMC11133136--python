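# Methods

This note documents the models, conventions and numerical choices behind
rhythmkit, in enough detail to reproduce or audit any number the package
computes.

## The timing model

The universal container is the `EventSequence`: an ordered list of
inter-onset intervals (IOIs), the times from one event's onset to the next
event's onset. IOIs, rather than onsets or event durations, are the primary
representation because they are onset-to-onset (so they apply equally to
musical rhythms and click trains), they carry the rhythm percept, and they
are unchanged when event durations change. Onsets are recovered as the
cumulative sum of IOIs shifted by `first_onset`, which is preserved from
input data rather than forced to zero, because empirical recordings start at
arbitrary times (`shifted_to_zero()` discards it explicitly).

A sequence either *ends with an event* (n events, n−1 IOIs; the default) or
*ends with an interval* (n events, n IOIs). Only the latter can be
concatenated or repeated: without a trailing interval the last event of one
sequence and the first event of the next would coincide. This is enforced as
an error, not a warning, as is the rejection of zero or negative IOIs —
simultaneous onsets would silently break every downstream computation that
assumes strictly increasing onsets.

Sequences are unit-agnostic. A `unit` annotation ("ms", "s") travels with
the data for bookkeeping but is never converted implicitly; only the sound
module assumes milliseconds, because audio rendering needs a physical time
scale.

The truncated-normal IOI generator resamples out-of-range draws rather than
clipping them, so the IOI distribution has no point mass at the boundary.

## Rhythms and melodies

A `RhythmSpec` quantizes note durations onto a grid whose step is a fraction
of a whole note (the smallest note value in use). The duration of one beat,
`beat_ms`, is the duration of one *denominator* note of the time signature:
in 5/8 the beat is an eighth note, in 5/4 a quarter note. Conversion to
milliseconds is `grid_step_ms = beat_ms × denominator × grid_step`. Total
duration must fill whole bars exactly — checked with exact rational
arithmetic (`fractions.Fraction`), so no floating-point tolerance is
involved. Only power-of-two note values are supported; dotted and triplet
values are out of scope.

Rests do not create events. A rest's duration is absorbed into the IOI of
the preceding played note; rests before the first played note extend the
converted sequence's `first_onset`. This preserves onset-to-onset semantics
and the conservation law the tests pin: leading offset + sum of IOIs =
n_bars × numerator × beat_ms, exactly.

### Uniform random rhythms

"A random rhythm given constraints" is defined as a draw from the *uniform*
distribution over all ordered compositions of one bar's grid length into the
allowed note durations. Sampling is exact, not approximate: with `f(L)` the
number of compositions of grid length `L` (computed by dynamic programming,
e.g. `f(L) = f(L−1) + f(L−2) + f(L−4)` on an eighth-note grid allowing
eighths, quarters and halves), the next note duration `p` is chosen with
probability `f(L−p)/f(L)`. Every complete composition then has probability
`1/f(bar)` by telescoping, with no rejection loop. Multi-bar rhythms sample
bars independently and concatenate; constraints do not span barlines. The
test suite verifies the composition counts against brute-force enumeration
(the canonical 4/4 bar of halves/quarters/eighths has 55 compositions) and
the uniformity of 10⁴ draws by chi-square at α = 0.01 for two constraint
sets.

### Pitch

Pitch names (letter, optional ASCII `#`/`b`, optional octave digit,
defaulting to octave 4) map to 12-tone equal temperament anchored at
A4 = 440 Hz: `f = 440 · 2^((midi−69)/12)`. Diatonic scales are spelled with
one letter per degree; keys that would need double accidentals are rejected.
Minor keys use the natural minor. Random melodies draw each pitch
independently and uniformly from the key's scale in the requested octave —
deliberately, no harmonic rules (tonic anchoring, leading-tone resolution)
are imposed.

## Sound synthesis

Tones are sine waves starting at phase 0, sampled at 48 kHz by default, with
optional linear or raised-cosine on/off ramps applied multiplicatively (the
ramp shape default is linear; the literature the ramps come from does not
fix a shape). Merging clips takes the samplewise *mean*, not the sum, which
guarantees the [−1, 1] amplitude invariant without a normalization pass —
the intended use is building complex tones from a fundamental plus
harmonics, where relative (not absolute) component amplitudes matter.

Trial assembly places each event's clip at `round(onset × fs / 1000)`
samples into a silent buffer. A clip longer than the IOI that follows its
event is an error (trials in timing research are non-overlapping; an
accidental overlap usually means a unit mistake), and a non-integer-sample
onset triggers a warning before rounding. The rendered length is the last
onset plus the last clip's duration, or the full span when the sequence ends
with an interval — which makes rendered end-with-interval trials exactly
concatenable.

WAV output is 32-bit float by default (bit-exact round trip) with a 16-bit
PCM option; PCM encoding scales by 32768 with the single out-of-range code
clipped, keeping round-trip error within 2⁻¹⁵. Stereo files are downmixed
to mono (channel mean) on read, with a warning.

## Statistics

* **nPVI** = `100/(m−1) · Σ |I_k − I_{k+1}| / ((I_k + I_{k+1})/2)`.
* **CV** = population standard deviation of the IOIs over their mean. The
  population convention (divisor m) is stated here because the sample
  convention differs materially at the short sequence lengths typical of
  animal vocalizations.
* **Shannon entropy** (bits) of the histogrammed IOIs. Binning is the open
  design choice here: the default is equal-width bins by the
  Freedman–Diaconis rule, clamped to between 2 and 20 bins, with identical
  IOIs collapsing to one bin (0 bits). Explicit edges always override the
  rule, and entropy comparisons across datasets should fix edges explicitly.
* **ugof**: for each onset, the distance to the nearest integer multiple of
  a reference interval, normalized by the maximal possible deviation (half
  the reference), averaged (mean by default; median offered, as both appear
  in the source literature). The grid is anchored at the sequence's first
  onset, so ugof measures internal fit, not absolute alignment.
* **Edit distance**: unit-cost Levenshtein distance between binary onset
  grids (1 = onset at a grid point). Rhythms are first requantized to the
  finest common grid (the gcd of their grid steps as exact fractions).
  Levenshtein rather than Hamming so rhythms of unequal grid length remain
  comparable. The implementation is a single-row DP; tests check it against
  a separately written full-matrix oracle and against the edlib library.
* **Phase differences**: a test onset `t` between reference onsets
  `t_i ≤ t < t_{i+1}` gets phase `360·(t − t_i)/(t_{i+1} − t_i)` degrees.
  This interval-proportional convention generalizes to non-isochronous
  references. An onset exactly on the final reference onset gets phase 0
  (completing the cycle); onsets outside the reference span are dropped with
  a warning.

## Beat extraction

Sequences are converted to binary impulse trains at a fixed resolution
(default 1 ms); two onsets rounding to the same sample is an error advising
a finer resolution.

**Autocorrelation**: the correlogram of the (optionally Gaussian-smoothed)
train, normalized to 1 at lag 0; the estimate is the lag of the global
maximum in a search window (default [2 × resolution, span/2]), ties broken
toward the smallest lag. Smoothing matters under timing jitter: the
recommended bandwidth is a kernel sd matched to the expected jitter sd.
Under-smoothing leaves the correlogram a field of narrow spikes whose
maximum is noisy, and the estimate then jumps to harmonics of the true
interval; in our recovery simulations (20 events, 4 % jitter) a matched
20 ms bandwidth recovers the interval within 5 % in 99 % of runs, versus
93 % at half that bandwidth.

**Fourier**: the magnitude spectrum of the zero-mean train, zero-padded to
10 × the train's span in samples, argmax within a frequency band (default
[0.1 Hz, Nyquist/2]), no peak interpolation. The padding length is chosen
deliberately: an isochronous train's span is a whole number of periods, so
with 10 × span padding every harmonic of the event rate falls on an exact
DFT bin and all harmonics tie in magnitude exactly. Candidates within a
1e-9 relative tolerance of the maximum are treated as tied and the lowest
frequency wins, which makes the estimator return exactly `1000/T` Hz for
exact isochrony at period T ms — the tolerance only breaks exact arithmetic
ties and does not affect jittered input, where the spectral peak is unique.

**Cross-correlation** respects absolute onsets (both trains share the
earlier first onset as origin), is normalized by the geometric mean of the
trains' energies, and breaks ties toward the smallest absolute lag, negative
first. All tie-breaking rules are deterministic so repeated analyses are
bit-reproducible.

## Plot computations

Every figure is split into a pure data computation and a thin renderer that
draws onto a caller-supplied matplotlib `Axes` (so plots compose into
grids). Tests pin the data layer only; no pixel snapshots.

* Recurrence matrices are `|I_i − I_j|` by default; a relative mode divides
  by the pair mean, making the matrix tempo-invariant. Thresholding at ε is
  optional — continuous distances are the default display. Axes are 1-based
  interval indices.
* Event-plot segments are (onset, width) pairs per sequence, order
  preserving and lossless; when data carry no duration information a
  constant nominal width (one tenth of the smallest IOI) is used.
* Phase-space points are the successive-interval pairs `(I_k, I_{k+1})`.
* Rose histograms use equal-width bins on [0, 360) starting at 0.

## Synthetic coda data

The fixture generator emulates click-train IOI data of the kind recorded
from sperm whale codas: per-coda identifier, ordered IOIs in seconds, and a
ground-truth pattern label. Three patterns, mixed 1/3 : 1/3 : 1/3 by
default:

* **regular** — 3–12 clicks, base IOI uniform in [0.1, 0.4] s, 5 %
  multiplicative jitter (positive-truncated Normal(1, 0.05) factors);
* **decelerating** — first IOI uniform in [0.1, 0.25] s, successive IOIs
  growing geometrically with ratio uniform in [1.1, 1.4];
* **grouped** — a short–short–long [1, 1, 2] template tiled to the coda
  length and scaled so the short IOI lies in [0.1, 0.4] s.

These ranges are stylized: the generator reproduces the *rhythmic classes*
(near-isochrony, deceleration, grouping) and the variable coda lengths that
the analysis pipeline must handle, not the click-rate distributions, ocean
noise, missed-click dropouts or clan-specific repertoires of real
recordings. Passing tests on this data therefore demonstrate that the
statistics and plots respond correctly to known rhythmic structure — they
say nothing about detection or preprocessing of real acoustic data, which
the package deliberately does not do (input is pre-processed onsets or
IOIs, single stream only). Pattern labels are generator ground truth and
are never read by any analysis code; a test asserts the statistics are
unchanged under relabeling.

## Problem sizes and defaults used in checks

The bundled verification runs use desk-scale inputs chosen to make the
statistical assertions sharp: 10⁴ draws for uniformity chi-squares
(expected cell counts ≥ 180), 200 replicates for the jittered tempo
recovery, 200 random pairs for the edit-distance oracle comparison, and
10⁴-IOI sequences for generator moment checks.

## Known limitations

* No onset detection from audio; no polyphonic/multi-stream sequences.
* Only power-of-two note values; no dotted notes, triplets, or ties.
* Melody generation has no harmonic constraints by design.
* The FFT tempo estimator reports a grid argmax; for short jittered
  sequences its resolution is limited by the padded bin width, and the ACF
  estimator with matched smoothing is the better default.
* Entropy values depend on the binning rule; cross-study comparisons must
  fix bin edges.
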