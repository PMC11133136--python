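"""Stimulus synthesis and trial assembly.

A :class:`SoundClip` is a mono sampled waveform; a :class:`TrialAudio`
couples an :class:`~rhythmkit.sequences.EventSequence` (whose IOIs are in
milliseconds) with one clip per event and renders the whole trial into a
single waveform.  One trial object corresponds to one experimental trial.

WAV I/O is 32-bit float by default, with a 16-bit PCM option; stereo files
are downmixed to mono on read with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .rhythm import MelodySpec, rhythm_to_sequence
from .sequences import EventSequence

__all__ = [
    "SoundClip",
    "TrialAudio",
    "synthesize_tone",
    "merge_clips",
    "assemble_trial",
    "synthesize_melody",
    "write_wav",
    "read_wav",
    "play",
]

DEFAULT_FS = 48_000


@dataclass(frozen=True)
class SoundClip:
    """Mono waveform with sample rate; amplitudes stay within [-1, 1]."""

    samples: np.ndarray
    fs: int = DEFAULT_FS
    name: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("SoundClip is mono: samples must be 1-D")
        if self.fs <= 0:
            raise ValueError(f"sample rate must be positive, got {self.fs}")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("amplitudes must lie within [-1, 1]")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs


@dataclass(frozen=True)
class TrialAudio:
    """Timing plus audio: one clip per event, rendered to one waveform."""

    sequence: EventSequence
    clips: tuple[SoundClip, ...]
    rendered: SoundClip


def _rising_ramp(n: int, shape: str) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    if shape == "linear":
        return x
    if shape in ("cosine", "raised-cosine"):
        return (1.0 - np.cos(np.pi * x)) / 2.0
    raise ValueError(f"unknown ramp shape {shape!r}; use 'linear' or 'cosine'")


def synthesize_tone(
    freq: float = 440.0,
    duration_ms: float = 50.0,
    fs: int = DEFAULT_FS,
    amplitude: float = 1.0,
    onramp_ms: float = 0.0,
    offramp_ms: float = 0.0,
    ramp_shape: str = "linear",
    name: str | None = None,
) -> SoundClip:
    """Pure tone starting at phase zero, with optional attack/decay ramps.

    Ramps are amplitude envelopes applied multiplicatively; their combined
    length may not exceed the tone's duration.  ``freq`` must respect the
    Nyquist limit ``fs/2``.
    """
    if freq >= fs / 2:
        raise ValueError(f"freq {freq} Hz violates the Nyquist limit fs/2 = {fs / 2} Hz")
    if freq <= 0 or duration_ms <= 0:
        raise ValueError("freq and duration_ms must be positive")
    if not 0 < amplitude <= 1:
        raise ValueError(f"amplitude must be in (0, 1], got {amplitude}")
    if onramp_ms < 0 or offramp_ms < 0 or onramp_ms + offramp_ms > duration_ms:
        raise ValueError(
            f"ramps ({onramp_ms} + {offramp_ms} ms) exceed tone duration {duration_ms} ms"
        )
    n = round(duration_ms * fs / 1000)
    t = np.arange(n) / fs
    samples = amplitude * np.sin(2 * np.pi * freq * t)
    n_on = round(onramp_ms * fs / 1000)
    n_off = round(offramp_ms * fs / 1000)
    if n_on:
        samples[:n_on] *= _rising_ramp(n_on, ramp_shape)
    if n_off:
        samples[-n_off:] *= _rising_ramp(n_off, ramp_shape)[::-1]
    return SoundClip(samples, fs=fs, name=name)


def merge_clips(clips) -> SoundClip:
    """Samplewise mean of several clips (e.g. a fundamental plus harmonics).

    Averaging rather than summing keeps the result within [-1, 1] without a
    separate normalization pass.  Shorter clips are zero-padded at the end.
    """
    clips = list(clips)
    if not clips:
        raise ValueError("need at least one clip to merge")
    fs = clips[0].fs
    for c in clips:
        if c.fs != fs:
            raise ValueError(f"sample rates differ: {c.fs} vs {fs}")
    n = max(c.n_samples for c in clips)
    acc = np.zeros(n)
    for c in clips:
        acc[: c.n_samples] += c.samples
    names = [c.name for c in clips if c.name]
    return SoundClip(acc / len(clips), fs=fs, name="+".join(names) or None)


def assemble_trial(seq: EventSequence, clips, fs: int | None = None) -> TrialAudio:
    """Place one clip at each event onset of a millisecond sequence.

    ``clips`` is either a single clip (reused for every event) or one clip
    per event.  A clip may not outlast the IOI that follows its event (the
    last event is exempt unless the sequence ends with an interval).  Onsets
    that do not fall on an integer sample raise a warning and are rounded.
    """
    if isinstance(clips, SoundClip):
        clips = [clips] * seq.n_events
    else:
        clips = list(clips)
    if len(clips) != seq.n_events:
        raise ValueError(
            f"need 1 or {seq.n_events} clips for {seq.n_events} events, got {len(clips)}"
        )
    fs = fs or clips[0].fs
    for c in clips:
        if c.fs != fs:
            raise ValueError(f"all clips must share one sample rate; {c.fs} != {fs}")

    onsets = seq.onsets()
    iois = seq.iois
    for i, c in enumerate(clips):
        has_following_ioi = i < len(iois)
        if has_following_ioi and c.duration_ms > iois[i] + 1e-9:
            raise ValueError(
                f"clip at event {i} lasts {c.duration_ms:.1f} ms but the "
                f"following IOI is only {iois[i]:.1f} ms; events would overlap"
            )

    if seq.end_with_interval:
        total_ms = seq.first_onset + seq.span
    else:
        total_ms = onsets[-1] + clips[-1].duration_ms
    buf = np.zeros(round(total_ms * fs / 1000))
    for i, (t, c) in enumerate(zip(onsets, clips)):
        exact = t * fs / 1000
        idx = round(exact)
        if abs(exact - idx) > 1e-9:
            warnings.warn(
                f"onset {t} ms of event {i} is not an integer number of samples "
                f"at {fs} Hz; rounding to sample {idx}",
                stacklevel=2,
            )
        buf[idx : idx + c.n_samples] = np.clip(
            buf[idx : idx + c.n_samples] + c.samples, -1.0, 1.0
        )
    rendered = SoundClip(buf, fs=fs, name=seq.name)
    return TrialAudio(sequence=seq, clips=tuple(clips), rendered=rendered)


def synthesize_melody(
    melody: MelodySpec,
    fs: int = DEFAULT_FS,
    amplitude: float = 1.0,
    event_duration_ms: float | None = None,
    onramp_ms: float = 0.0,
    offramp_ms: float = 0.0,
    ramp_shape: str = "linear",
) -> TrialAudio:
    """Render a melody: one tone per played note at that note's pitch.

    By default each tone lasts its full note value; passing
    ``event_duration_ms`` (e.g. 50) gives every tone a fixed duration while
    preserving the rhythm's timing.
    """
    seq = rhythm_to_sequence(melody.rhythm)
    freqs = melody.frequencies()
    clips = []
    for f, ioi in zip(freqs, seq.iois):
        dur = ioi if event_duration_ms is None else event_duration_ms
        clips.append(
            synthesize_tone(
                f, dur, fs=fs, amplitude=amplitude,
                onramp_ms=onramp_ms, offramp_ms=offramp_ms, ramp_shape=ramp_shape,
            )
        )
    return assemble_trial(seq, clips, fs=fs)


def write_wav(obj, path, *, encoding: str = "float32") -> None:
    """Write a clip or a rendered trial to a WAV file.

    ``encoding`` is ``"float32"`` (lossless for our samples) or ``"pcm16"``.
    """
    clip = obj.rendered if isinstance(obj, TrialAudio) else obj
    if encoding == "float32":
        wavfile.write(path, clip.fs, clip.samples.astype(np.float32))
    elif encoding == "pcm16":
        scaled = np.round(np.clip(clip.samples, -1.0, 1.0) * 32768.0)
        wavfile.write(path, clip.fs, np.clip(scaled, -32768, 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}; use 'float32' or 'pcm16'")


def read_wav(path, name: str | None = None) -> SoundClip:
    """Read a WAV file; integer PCM is rescaled to [-1, 1], stereo is
    downmixed to mono (channel mean) with a warning."""
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        warnings.warn(
            f"{path} has {samples.shape[1]} channels; downmixing to mono",
            stacklevel=2,
        )
        samples = samples.mean(axis=1)
    return SoundClip(np.clip(samples, -1.0, 1.0), fs=int(fs), name=name)


def play(obj) -> None:  # pragma: no cover - requires an audio device
    """Optional playback through the system audio device, if available."""
    clip = obj.rendered if isinstance(obj, TrialAudio) else obj
    try:
        import sounddevice as sd
    except ImportError as exc:
        raise RuntimeError(
            "playback requires the optional 'sounddevice' package"
        ) from exc
    sd.play(clip.samples, clip.fs)
    sd.wait()
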