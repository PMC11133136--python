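"""The core timing data model: event sequences described by inter-onset intervals.

An event sequence is an ordered set of point events on a time axis.  The
informative quantity is the inter-onset interval (IOI): the time from one
event's onset to the next event's onset, independent of how long each event
lasts.  Sequences come in two flavours:

* *end with an event* (the default): ``n`` events but ``n - 1`` IOIs;
* *end with an interval*: equally many events and IOIs, with a trailing
  silent interval after the last event.

Only sequences that end with an interval can be concatenated or repeated --
otherwise the last event of one sequence and the first event of the next
would coincide.

Sequences are agnostic about the time unit; milliseconds are assumed only
when audio is rendered (see :mod:`rhythmkit.sound`).  An optional ``unit``
annotation travels with the sequence but is never converted implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EventSequence",
    "generate_isochronous",
    "generate_random_uniform",
    "generate_random_normal",
    "from_onsets",
    "concat",
    "append_interval",
    "repeat",
    "scale_tempo",
    "interval_ratios",
]


@dataclass(frozen=True)
class EventSequence:
    """Ordered IOIs plus bookkeeping flags.

    Parameters
    ----------
    iois
        Strictly positive durations, in an arbitrary (but consistent) unit.
    end_with_interval
        If True the sequence has as many events as IOIs and ends with a
        silent interval; if False (default) it ends with an event and has
        one more event than IOIs.
    first_onset
        Absolute time of the first event; empirical recordings rarely start
        at zero, so the offset is preserved rather than discarded.
    name
        Optional label (e.g. a trial or coda identifier).
    unit
        Optional annotation such as ``"ms"`` or ``"s"``; informational only.
    """

    iois: np.ndarray
    end_with_interval: bool = False
    first_onset: float = 0.0
    name: str | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        iois = np.asarray(self.iois, dtype=float)
        if iois.ndim != 1 or iois.size == 0:
            raise ValueError("a sequence needs at least one IOI")
        if np.any(iois <= 0):
            bad = int(np.argmax(iois <= 0))
            raise ValueError(
                f"IOIs must be strictly positive; ioi[{bad}] = {iois[bad]} "
                "(zero-duration IOIs would make two onsets coincide)"
            )
        if self.first_onset < 0:
            raise ValueError(f"first_onset must be >= 0, got {self.first_onset}")
        iois.setflags(write=False)
        object.__setattr__(self, "iois", iois)

    # -- derived quantities -------------------------------------------------

    @property
    def n_iois(self) -> int:
        return int(self.iois.size)

    @property
    def n_events(self) -> int:
        return self.n_iois if self.end_with_interval else self.n_iois + 1

    @property
    def span(self) -> float:
        """Total duration from the first onset to the end of the sequence."""
        return float(np.sum(self.iois))

    def onsets(self) -> np.ndarray:
        """Absolute event onsets; strictly increasing, length ``n_events``."""
        cum = np.concatenate(([0.0], np.cumsum(self.iois)))
        if self.end_with_interval:
            cum = cum[:-1]
        return self.first_onset + cum

    def shifted_to_zero(self) -> "EventSequence":
        """Copy with ``first_onset`` reset to 0."""
        return replace(self, first_onset=0.0)

    def with_name(self, name: str | None) -> "EventSequence":
        return replace(self, name=name)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, EventSequence):
            return concat(self, other)
        if isinstance(other, (int, float)):
            return append_interval(self, float(other))
        return NotImplemented

    def __mul__(self, k):
        if isinstance(k, int):
            return repeat(self, k)
        return NotImplemented

    __rmul__ = __mul__

    def __len__(self) -> int:
        return self.n_events

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventSequence):
            return NotImplemented
        return (
            np.array_equal(self.iois, other.iois)
            and self.end_with_interval == other.end_with_interval
            and self.first_onset == other.first_onset
            and self.name == other.name
            and self.unit == other.unit
        )

    def __repr__(self) -> str:  # compact, list-like, for interactive use
        kind = "interval" if self.end_with_interval else "event"
        label = f" {self.name!r}" if self.name else ""
        return (
            f"EventSequence({np.array2string(self.iois, precision=4, threshold=8)},"
            f" ends with {kind}{label})"
        )


# -- constructors -----------------------------------------------------------


def generate_isochronous(
    n_events: int, ioi: float, *, end_with_interval: bool = False, name: str | None = None
) -> EventSequence:
    """Perfectly regular sequence: ``n_events`` events separated by ``ioi``."""
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    if ioi <= 0:
        raise ValueError(f"ioi must be positive, got {ioi}")
    n_iois = n_events if end_with_interval else n_events - 1
    return EventSequence(
        np.full(n_iois, float(ioi)), end_with_interval=end_with_interval, name=name
    )


def generate_random_uniform(
    n_events: int,
    low: float,
    high: float,
    rng: np.random.Generator,
    *,
    end_with_interval: bool = False,
    name: str | None = None,
) -> EventSequence:
    """IOIs drawn i.i.d. from Uniform(low, high)."""
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    if low <= 0:
        raise ValueError(f"low must be positive, got {low}")
    if high < low:
        raise ValueError(f"need low <= high, got [{low}, {high}]")
    n_iois = n_events if end_with_interval else n_events - 1
    iois = rng.uniform(low, high, size=n_iois)
    return EventSequence(iois, end_with_interval=end_with_interval, name=name)


def generate_random_normal(
    n_events: int,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
    *,
    end_with_interval: bool = False,
    name: str | None = None,
) -> EventSequence:
    """IOIs drawn from Normal(mu, sigma) truncated to positive values.

    Truncation is by resampling, not clipping, so there is no point mass at
    zero and all IOIs remain strictly positive.
    """
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    n_iois = n_events if end_with_interval else n_events - 1
    iois = rng.normal(mu, sigma, size=n_iois)
    while np.any(iois <= 0):
        bad = iois <= 0
        iois[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
    return EventSequence(iois, end_with_interval=end_with_interval, name=name)


def from_onsets(onsets, *, name: str | None = None, unit: str | None = None) -> EventSequence:
    """Build a sequence from absolute event onsets.

    The first onset is preserved (not forced to zero); use
    :meth:`EventSequence.shifted_to_zero` to discard it.  The result ends
    with an event.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.ndim != 1 or onsets.size < 2:
        raise ValueError("need at least two onsets")
    if onsets[0] < 0:
        raise ValueError(f"first onset must be >= 0, got {onsets[0]}")
    diffs = np.diff(onsets)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise ValueError(
            f"onsets must be strictly increasing; onset[{bad + 1}] = {onsets[bad + 1]} "
            f"does not follow onset[{bad}] = {onsets[bad]}"
        )
    return EventSequence(diffs, first_onset=float(onsets[0]), name=name, unit=unit)


# -- combinators ------------------------------------------------------------


def concat(a: EventSequence, b: EventSequence) -> EventSequence:
    """Join two sequences in time; ``a`` must end with an interval.

    If ``a`` ended with an event, its last event and the first event of
    ``b`` would land on the same onset.  The result is unnamed.
    """
    if not a.end_with_interval:
        raise ValueError(
            "the left sequence ends with an event; its last event and the "
            "first event of the right sequence would coincide. Append a "
            "trailing interval first (seq + interval)."
        )
    return EventSequence(
        np.concatenate([a.iois, b.iois]),
        end_with_interval=b.end_with_interval,
        first_onset=a.first_onset,
        unit=a.unit or b.unit,
    )


def append_interval(seq: EventSequence, interval: float) -> EventSequence:
    """Append a trailing silent interval, turning an end-with-event sequence
    into one that ends with an interval (and can thus be concatenated)."""
    if seq.end_with_interval:
        raise ValueError("sequence already ends with an interval")
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    return replace(
        seq, iois=np.append(seq.iois, float(interval)), end_with_interval=True
    )


def repeat(seq: EventSequence, k: int) -> EventSequence:
    """Repeat an end-with-interval sequence ``k`` times back to back."""
    if not seq.end_with_interval:
        raise ValueError(
            "only sequences ending with an interval can be repeated "
            "(otherwise adjacent repetitions would share an onset)"
        )
    if k < 1:
        raise ValueError(f"repeat count must be >= 1, got {k}")
    return replace(seq, iois=np.tile(seq.iois, k))


def scale_tempo(seq: EventSequence, factor: float) -> EventSequence:
    """Multiply every IOI by ``factor`` (> 1 slows down, < 1 speeds up)."""
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return replace(seq, iois=seq.iois * float(factor))


def interval_ratios(seq: EventSequence) -> np.ndarray:
    """Ratios of successive IOIs: ``r_k = I_k / (I_k + I_{k+1})``.

    Each ratio lies strictly in (0, 1); 0.5 means two equal neighbouring
    intervals.  The statistic is invariant under tempo scaling.
    """
    if seq.n_iois < 2:
        raise ValueError("need at least 2 IOIs to form interval ratios")
    a = seq.iois[:-1]
    b = seq.iois[1:]
    return a / (a + b)
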