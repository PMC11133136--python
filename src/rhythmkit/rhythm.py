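"""Musical rhythms and melodies on a quantized note-value grid.

A rhythm is a sequence of note durations expressed in units of a grid step
(a fraction of a whole note), together with a time signature, the duration
in milliseconds of one beat (one denominator note), and a played/rest flag
per note.  Total duration must fill whole bars exactly.  Converted to an
:class:`~rhythmkit.sequences.EventSequence`, a rhythm always ends with an
interval, which is what makes rhythms concatenable.

Pitch names follow scientific pitch notation in 12-tone equal temperament
anchored at A4 = 440 Hz; accidentals are ASCII ``#`` and ``b``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np

from .sequences import EventSequence

__all__ = [
    "RhythmSpec",
    "MelodySpec",
    "rhythm_from_integer_ratios",
    "rhythm_from_note_values",
    "generate_random_rhythm",
    "count_rhythms",
    "rhythm_to_sequence",
    "pitch_to_frequency",
    "parse_pitch",
    "diatonic_scale",
    "generate_random_melody",
    "render_rhythm_text",
]

_NATURAL_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_LETTERS = "CDEFGAB"


@dataclass(frozen=True)
class RhythmSpec:
    """Grid-quantized rhythm.

    ``durations_grid[k]`` is the length of note ``k`` in grid steps;
    ``grid_step`` is the step as a fraction of a whole note (e.g. 1/8);
    ``beat_ms`` is the duration of one denominator note of the time
    signature; ``is_played[k]`` is False for rests.
    """

    durations_grid: tuple[int, ...]
    grid_step: Fraction
    time_signature: tuple[int, int]
    beat_ms: float
    is_played: tuple[bool, ...]
    name: str | None = None

    def __post_init__(self) -> None:
        num, den = self.time_signature
        if num < 1 or den < 1:
            raise ValueError(f"invalid time signature {num}/{den}")
        if self.beat_ms <= 0:
            raise ValueError(f"beat_ms must be positive, got {self.beat_ms}")
        if not self.durations_grid:
            raise ValueError("rhythm needs at least one note")
        if any(d < 1 for d in self.durations_grid):
            raise ValueError("every note must span at least one grid step")
        if len(self.is_played) != len(self.durations_grid):
            raise ValueError("is_played must have one flag per note")
        bar = Fraction(num, den)
        total = sum(self.durations_grid) * self.grid_step
        if total % bar != 0:
            raise ValueError(
                f"rhythm spans {total} whole notes, which does not fill whole "
                f"{num}/{den} bars (bar = {bar}); off by {total % bar}"
            )

    @property
    def n_bars(self) -> int:
        num, den = self.time_signature
        return int(sum(self.durations_grid) * self.grid_step / Fraction(num, den))

    @property
    def grid_step_ms(self) -> float:
        """Duration of one grid step: one denominator note lasts beat_ms."""
        _, den = self.time_signature
        return self.beat_ms * den * float(self.grid_step)

    @property
    def n_played(self) -> int:
        return sum(self.is_played)

    def to_json(self) -> str:
        return json.dumps(
            {
                "durations_grid": list(self.durations_grid),
                "grid_step": [self.grid_step.numerator, self.grid_step.denominator],
                "time_signature": list(self.time_signature),
                "beat_ms": self.beat_ms,
                "is_played": list(self.is_played),
                "name": self.name,
            }
        )

    @staticmethod
    def from_json(text: str) -> "RhythmSpec":
        d = json.loads(text)
        return RhythmSpec(
            tuple(d["durations_grid"]),
            Fraction(*d["grid_step"]),
            tuple(d["time_signature"]),
            d["beat_ms"],
            tuple(d["is_played"]),
            d.get("name"),
        )


@dataclass(frozen=True)
class MelodySpec:
    """A rhythm plus one pitch name per played note."""

    rhythm: RhythmSpec
    pitches: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.pitches) != self.rhythm.n_played:
            raise ValueError(
                f"need one pitch per played note: {self.rhythm.n_played} notes "
                f"but {len(self.pitches)} pitches"
            )
        for p in self.pitches:
            parse_pitch(p)  # raises on bad names

    def frequencies(self) -> np.ndarray:
        return np.array([pitch_to_frequency(p) for p in self.pitches])

    def to_json(self) -> str:
        return json.dumps(
            {"rhythm": json.loads(self.rhythm.to_json()), "pitches": list(self.pitches)}
        )

    @staticmethod
    def from_json(text: str) -> "MelodySpec":
        d = json.loads(text)
        return MelodySpec(RhythmSpec.from_json(json.dumps(d["rhythm"])), tuple(d["pitches"]))


# -- construction -----------------------------------------------------------


def rhythm_from_integer_ratios(
    ratios, time_signature: tuple[int, int] = (4, 4), beat_ms: float = 500.0
) -> RhythmSpec:
    """Rhythm from relative durations, one beat per unit ratio.

    ``[1, 1, 2]`` in 4/4 at 500 ms/beat gives IOIs 500, 500, 1000 ms: the
    last note is twice as long as the first two.
    """
    ratios = [int(r) for r in ratios]
    if not ratios or any(r < 1 for r in ratios):
        raise ValueError("ratios must be positive integers")
    _, den = time_signature
    return RhythmSpec(
        tuple(ratios),
        Fraction(1, den),
        time_signature,
        beat_ms,
        tuple(True for _ in ratios),
    )


def rhythm_from_note_values(
    values,
    time_signature: tuple[int, int] = (4, 4),
    beat_ms: float = 500.0,
    *,
    is_played=None,
) -> RhythmSpec:
    """Rhythm from note values given as whole-note denominators (4 = quarter).

    Only power-of-two values are supported; the grid step is the smallest
    note value used.
    """
    values = [int(v) for v in values]
    if not values:
        raise ValueError("need at least one note value")
    for v in values:
        if v < 1 or (v & (v - 1)) != 0:
            raise ValueError(f"note value must be a power-of-two denominator, got {v}")
    grid_den = max(values)
    durations = tuple(grid_den // v for v in values)
    played = tuple(True for _ in values) if is_played is None else tuple(is_played)
    return RhythmSpec(durations, Fraction(1, grid_den), time_signature, beat_ms, played)


def _bar_grid_length(allowed_note_values, time_signature) -> tuple[int, list[int]]:
    """Grid length of one bar and allowed part lengths, in grid steps."""
    values = sorted({int(v) for v in allowed_note_values})
    if not values:
        raise ValueError("allowed_note_values must be non-empty")
    for v in values:
        if v < 1 or (v & (v - 1)) != 0:
            raise ValueError(f"note value must be a power-of-two denominator, got {v}")
    grid_den = max(values)
    num, den = time_signature
    bar = Fraction(num, den) / Fraction(1, grid_den)
    if bar.denominator != 1:
        raise ValueError(
            f"note values {values} cannot exactly fill a {num}/{den} bar: "
            f"the bar is not a whole number of 1/{grid_den} steps"
        )
    parts = [grid_den // v for v in values]
    return int(bar), parts


def _composition_counts(length: int, parts) -> np.ndarray:
    """f[L] = number of ordered compositions of L into the given parts."""
    f = np.zeros(length + 1, dtype=object)
    f[0] = 1
    for L in range(1, length + 1):
        f[L] = sum(f[L - p] for p in parts if p <= L)
    return f


def count_rhythms(allowed_note_values, time_signature=(4, 4), n_bars: int = 1) -> int:
    """Number of distinct rhythms: compositions of each bar, bars independent."""
    length, parts = _bar_grid_length(allowed_note_values, time_signature)
    per_bar = int(_composition_counts(length, parts)[length])
    return per_bar**n_bars


def _sample_composition(length: int, parts, f: np.ndarray, rng: np.random.Generator):
    """Draw one composition of ``length`` exactly uniformly.

    At each position the next part ``p`` is chosen with probability
    f[rest - p] / f[rest], which makes every full composition equally
    likely; no rejection, terminates in at most ``length`` steps.
    """
    out = []
    rest = length
    while rest > 0:
        feasible = [p for p in parts if p <= rest and f[rest - p] > 0]
        weights = np.array([float(f[rest - p]) for p in feasible])
        p = feasible[rng.choice(len(feasible), p=weights / weights.sum())]
        out.append(p)
        rest -= p
    return out


def generate_random_rhythm(
    n_bars: int,
    allowed_note_values,
    time_signature: tuple[int, int],
    beat_ms: float,
    rng: np.random.Generator,
) -> RhythmSpec:
    """Draw a rhythm uniformly from all rhythms satisfying the constraints.

    Each bar is an ordered composition of the bar's grid length into the
    allowed note durations; every such composition has equal probability
    (dynamic-programming counts with weighted sequential choice).  Bars are
    sampled independently and concatenated.  All notes are played.
    """
    if n_bars < 1:
        raise ValueError(f"n_bars must be >= 1, got {n_bars}")
    length, parts = _bar_grid_length(allowed_note_values, time_signature)
    f = _composition_counts(length, parts)
    if f[length] == 0:
        raise ValueError(
            f"no combination of note values {sorted(set(allowed_note_values))} "
            f"fills a {time_signature[0]}/{time_signature[1]} bar"
        )
    grid_den = max(int(v) for v in allowed_note_values)
    durations: list[int] = []
    for _ in range(n_bars):
        durations.extend(_sample_composition(length, parts, f, rng))
    return RhythmSpec(
        tuple(durations),
        Fraction(1, grid_den),
        time_signature,
        beat_ms,
        tuple(True for _ in durations),
    )


# -- conversion -------------------------------------------------------------


def rhythm_to_sequence(r: RhythmSpec) -> EventSequence:
    """Convert played notes to events; the result ends with an interval.

    A rest does not create an event: its duration is absorbed into the IOI
    of the preceding played note (onset-to-onset semantics).  Rests before
    the first played note delay the first onset instead.
    """
    if not any(r.is_played):
        raise ValueError("an all-rest rhythm has no events to convert")
    step_ms = r.grid_step_ms
    first_onset = 0.0
    iois: list[float] = []
    for dur, played in zip(r.durations_grid, r.is_played):
        ms = dur * step_ms
        if played:
            iois.append(ms)
        elif iois:
            iois[-1] += ms
        else:
            first_onset += ms
    return EventSequence(
        np.array(iois),
        end_with_interval=True,
        first_onset=first_onset,
        name=r.name,
        unit="ms",
    )


# -- pitch ------------------------------------------------------------------

_PITCH_RE = re.compile(r"^([A-Ga-g])([#b]?)(\d)?$")


def parse_pitch(name: str) -> int:
    """Parse a pitch name like ``'G'``, ``'F#3'`` or ``'Bb'`` to a MIDI number.

    The octave defaults to 4 (the octave of middle C and A440).
    """
    m = _PITCH_RE.match(name.strip()) if isinstance(name, str) else None
    if m is None:
        raise ValueError(f"cannot parse pitch name {name!r}")
    letter, accidental, octave = m.groups()
    semitone = _NATURAL_SEMITONE[letter.upper()]
    semitone += {"#": 1, "b": -1, "": 0}[accidental]
    octave = 4 if octave is None else int(octave)
    return 12 * (octave + 1) + semitone


def pitch_to_frequency(name: str) -> float:
    """Frequency in Hz of a named pitch in 12-TET, A4 = 440 Hz."""
    midi = parse_pitch(name)
    return 440.0 * 2.0 ** ((midi - 69) / 12)


_MODE_STEPS = {
    "major": (2, 2, 1, 2, 2, 2, 1),
    "minor": (2, 1, 2, 2, 1, 2, 2),  # natural minor
}


def diatonic_scale(tonic: str, mode: str = "major", octave: int = 4) -> list[str]:
    """The seven pitch names of a diatonic scale, spelled with one letter each.

    Keys whose spelling would require a double accidental are rejected.
    """
    if mode not in _MODE_STEPS:
        raise ValueError(f"mode must be one of {sorted(_MODE_STEPS)}, got {mode!r}")
    m = _PITCH_RE.match(tonic.strip())
    if m is None or m.group(3) is not None:
        raise ValueError(f"tonic must be a pitch letter with optional accidental, got {tonic!r}")
    letter, accidental = m.group(1).upper(), m.group(2)
    tonic_semi = _NATURAL_SEMITONE[letter] + {"#": 1, "b": -1, "": 0}[accidental]
    li = _LETTERS.index(letter)
    names = []
    oct_offset = 0
    semi = tonic_semi
    for k in range(7):
        lett = _LETTERS[(li + k) % 7]
        if k > 0 and (li + k) % 7 == 0:
            oct_offset += 1
        natural = _NATURAL_SEMITONE[lett] + 12 * oct_offset
        acc = semi - natural
        if acc not in (-1, 0, 1):
            raise ValueError(
                f"key {tonic} {mode} needs a double accidental on {lett}; unsupported"
            )
        names.append(lett + {1: "#", -1: "b", 0: ""}[acc] + str(octave + oct_offset))
        semi += _MODE_STEPS[mode][k]
    return names


def generate_random_melody(
    key: str,
    octave: int,
    n_bars: int,
    allowed_note_values,
    time_signature: tuple[int, int],
    beat_ms: float,
    rng: np.random.Generator,
    *,
    mode: str = "major",
) -> MelodySpec:
    """Random rhythm plus pitches drawn uniformly from the key's diatonic scale.

    No harmonic rules are imposed (the melody need not start or end on the
    tonic).
    """
    scale = diatonic_scale(key, mode=mode, octave=octave)
    rhythm = generate_random_rhythm(n_bars, allowed_note_values, time_signature, beat_ms, rng)
    picks = rng.integers(0, len(scale), size=rhythm.n_played)
    return MelodySpec(rhythm, tuple(scale[i] for i in picks))


# -- plain-text rendering ---------------------------------------------------


def render_rhythm_text(r: RhythmSpec) -> str:
    """Render the rhythm as a grid line: ``|`` onset, ``.`` continuation,
    ``-`` rest, with bar separators.  Deterministic and snapshot-testable."""
    num, den = r.time_signature
    bar_len = int(Fraction(num, den) / r.grid_step)
    cells: list[str] = []
    for dur, played in zip(r.durations_grid, r.is_played):
        if played:
            cells.append("|")
            cells.extend("." * (dur - 1))
        else:
            cells.extend("-" * dur)
    bars = [
        "".join(cells[i : i + bar_len]) for i in range(0, len(cells), bar_len)
    ]
    return f"{num}/{den} " + " / ".join(bars)
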