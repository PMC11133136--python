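"""Plot-data computations and thin matplotlib renderers.

Every figure in the package is split into a pure computation returning
plain data (segments, matrices, points, bin counts) and a small renderer
that draws those data onto a matplotlib ``Axes``.  Renderers accept an
existing ``ax`` so figures compose into larger grids; the computations are
what the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import EventSequence
from .stats import PhaseSet

__all__ = [
    "RecurrenceMatrix",
    "recurrence_matrix",
    "event_plot_segments",
    "phase_space_points",
    "rose_histogram",
    "plot_event_sequences",
    "plot_recurrence",
    "plot_phase_space",
    "plot_rose",
    "plot_waveform",
]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Pairwise IOI dissimilarities of one sequence.

    ``values[i, j] = |I_i - I_j|`` (or the normalized variant); symmetric
    with a zero diagonal.  If an ``epsilon`` threshold was requested,
    ``thresholded[i, j] = 1`` where the dissimilarity is at most epsilon.
    """

    values: np.ndarray
    thresholded: np.ndarray | None = None
    epsilon: float | None = None


def recurrence_matrix(
    seq: EventSequence, epsilon: float | None = None, relative: bool = False
) -> RecurrenceMatrix:
    """Recurrence structure of the IOIs.

    ``relative=True`` divides each difference by the pair mean
    ``(I_i + I_j)/2``, making the matrix tempo-invariant.
    """
    if seq.n_iois < 2:
        raise ValueError("a recurrence matrix needs at least 2 IOIs")
    iois = seq.iois
    diff = np.abs(iois[:, None] - iois[None, :])
    if relative:
        diff = diff / ((iois[:, None] + iois[None, :]) / 2.0)
    thr = None
    if epsilon is not None:
        thr = (diff <= epsilon).astype(int)
    return RecurrenceMatrix(diff, thresholded=thr, epsilon=epsilon)


def event_plot_segments(seqs, linewidths=None):
    """Onset/width segments for a raster-style event plot.

    ``linewidths`` may be a scalar (one width for every event — used when
    the data carry no duration information), a per-sequence collection, or
    None for a default width of 1/10 of the smallest IOI across sequences.
    Returns ``(segments, (t_min, t_max))`` where ``segments[i]`` is a list
    of ``(onset, width)`` pairs for sequence ``i`` in input order.
    """
    seqs = [seqs] if isinstance(seqs, EventSequence) else list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    if linewidths is None:
        linewidths = min(float(np.min(s.iois)) for s in seqs) / 10.0
    if np.isscalar(linewidths):
        widths = [np.full(s.n_events, float(linewidths)) for s in seqs]
    else:
        widths = [np.broadcast_to(np.asarray(w, dtype=float), (s.n_events,))
                  for w, s in zip(linewidths, seqs)]
    segments = []
    for s, w in zip(seqs, widths):
        segments.append([(float(t), float(wk)) for t, wk in zip(s.onsets(), w)])
    t_min = min(seg[0][0] for seg in segments)
    t_max = max(seg[-1][0] + seg[-1][1] for seg in segments)
    return segments, (t_min, t_max)


def phase_space_points(seq: EventSequence) -> np.ndarray:
    """Successive-interval pairs ``(I_k, I_{k+1})`` in traversal order.

    Isochrony collapses onto the diagonal; alternating long-short rhythms
    trace two off-diagonal clusters.
    """
    if seq.n_iois < 2:
        raise ValueError("a phase space plot needs at least 2 IOIs")
    return np.column_stack([seq.iois[:-1], seq.iois[1:]])


def rose_histogram(phases: PhaseSet, n_bins: int = 12):
    """Equal-width circular histogram over [0, 360) degrees.

    Returns ``(counts, edges)``; counts sum to the number of phases and the
    first edge sits at 0.
    """
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(phases.phases, bins=edges)
    return counts, edges


# -- renderers --------------------------------------------------------------


def _require_ax(ax, polar=False):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(subplot_kw={"projection": "polar"} if polar else None)
    return ax


def plot_event_sequences(seqs, linewidths=None, ax=None, labels=None):
    """Raster plot: one row per sequence, a bar per event onset."""
    segments, (t_min, t_max) = event_plot_segments(seqs, linewidths)
    ax = _require_ax(ax)
    for row, segs in enumerate(segments):
        y = len(segments) - 1 - row  # first sequence on top
        for onset, width in segs:
            ax.barh(y, width, left=onset, height=0.6, color="tab:blue")
    ax.set_xlim(t_min, t_max)
    ax.set_yticks(range(len(segments)))
    if labels is not None:
        ax.set_yticklabels(list(labels)[::-1])
    ax.set_xlabel("time")
    return ax


def plot_recurrence(seq: EventSequence, epsilon=None, relative=False, ax=None):
    """Recurrence plot; axes are 1-based interval indices."""
    rm = recurrence_matrix(seq, epsilon=epsilon, relative=relative)
    mat = rm.thresholded if rm.thresholded is not None else rm.values
    ax = _require_ax(ax)
    m = mat.shape[0]
    ax.imshow(mat, origin="lower", cmap="Greys",
              extent=(0.5, m + 0.5, 0.5, m + 0.5))
    ax.set_xlabel("interval index")
    ax.set_ylabel("interval index")
    if seq.name:
        ax.set_title(seq.name)
    return ax


def plot_phase_space(seq: EventSequence, ax=None):
    pts = phase_space_points(seq)
    ax = _require_ax(ax)
    ax.plot(pts[:, 0], pts[:, 1], "o-", alpha=0.7)
    ax.set_xlabel("$I_k$")
    ax.set_ylabel("$I_{k+1}$")
    return ax


def plot_rose(phases: PhaseSet, n_bins: int = 12, ax=None):
    counts, edges = rose_histogram(phases, n_bins)
    ax = _require_ax(ax, polar=True)
    centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
    ax.bar(centers, counts, width=np.deg2rad(np.diff(edges)), alpha=0.7)
    return ax


def plot_waveform(clip, ax=None):
    """Amplitude-versus-time rendering of a clip or rendered trial."""
    from .sound import SoundClip, TrialAudio

    if isinstance(clip, TrialAudio):
        clip = clip.rendered
    ax = _require_ax(ax)
    t = np.arange(clip.n_samples) / clip.fs * 1000.0
    ax.plot(t, clip.samples, linewidth=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude")
    ax.set_ylim(-1.05, 1.05)
    return ax
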