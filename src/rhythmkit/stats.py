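"""Descriptive statistics for rhythmic sequences.

Implemented measures: the normalized pairwise variability index (nPVI), the
coefficient of variation of the IOIs, Shannon entropy of the IOI
distribution, the universal goodness-of-fit against an isochronous
reference grid (ugof), Levenshtein edit distance between grid-quantized
rhythms, and phase differences of one sequence's events relative to
another sequence's intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .rhythm import RhythmSpec
from .sequences import EventSequence

__all__ = [
    "PhaseSet",
    "npvi",
    "coefficient_of_variation",
    "shannon_entropy",
    "ugof",
    "edit_distance",
    "phase_differences",
    "summary",
]


@dataclass(frozen=True)
class PhaseSet:
    """Phase angles in degrees, each in [0, 360)."""

    phases: np.ndarray
    reference_label: str = ""

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        if phases.size and (np.any(phases < 0) or np.any(phases >= 360)):
            raise ValueError("phases must lie in [0, 360) degrees")
        phases.setflags(write=False)
        object.__setattr__(self, "phases", phases)

    def resultant_vector_length(self) -> float:
        """Length of the mean resultant vector; 1 means perfect alignment."""
        rad = np.deg2rad(self.phases)
        return float(np.abs(np.mean(np.exp(1j * rad))))


def npvi(seq: EventSequence) -> float:
    """Normalized pairwise variability index of the IOIs.

    nPVI = 100/(m-1) * sum_k |(I_k - I_{k+1}) / ((I_k + I_{k+1})/2)|

    Zero for an isochronous sequence; larger values mean more contrast
    between neighbouring intervals.  Invariant under tempo scaling.
    """
    if seq.n_iois < 2:
        raise ValueError("nPVI needs at least 2 IOIs")
    a, b = seq.iois[:-1], seq.iois[1:]
    return float(100.0 * np.mean(np.abs((a - b) / ((a + b) / 2.0))))


def coefficient_of_variation(seq: EventSequence) -> float:
    """Population standard deviation of the IOIs divided by their mean.

    The population convention (divisor m, not m-1) is used; the two
    conventions differ noticeably for short sequences.
    """
    if seq.n_iois < 2:
        raise ValueError("CV needs at least 2 IOIs")
    mean = float(np.mean(seq.iois))
    return float(np.std(seq.iois) / mean)


def _default_edges(iois: np.ndarray) -> np.ndarray:
    # Freedman-Diaconis width, bin count clamped to [2, 20]
    lo, hi = float(np.min(iois)), float(np.max(iois))
    if hi == lo:
        return np.array([lo - 0.5, hi + 0.5])
    q75, q25 = np.percentile(iois, [75, 25])
    iqr = q75 - q25
    h = 2.0 * iqr / iois.size ** (1 / 3)
    n_bins = int(np.ceil((hi - lo) / h)) if h > 0 else 20
    n_bins = min(max(n_bins, 2), 20)
    return np.linspace(lo, hi, n_bins + 1)


def shannon_entropy(seq: EventSequence, bin_edges=None) -> float:
    """Shannon entropy (bits) of the histogrammed IOI distribution.

    With no explicit ``bin_edges``, equal-width bins are chosen by the
    Freedman-Diaconis rule clamped to between 2 and 20 bins; identical IOIs
    collapse to a single bin and yield 0 bits.
    """
    iois = seq.iois
    if bin_edges is None:
        edges = _default_edges(iois)
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be a strictly increasing 1-D array")
    counts, _ = np.histogram(iois, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def ugof(seq: EventSequence, reference_ioi: float, aggregate: str = "mean") -> float:
    """Universal goodness of fit against an isochronous grid, in [0, 1].

    For each onset (measured relative to the sequence's first onset) the
    deviation from the nearest multiple of ``reference_ioi`` is normalized
    by the largest possible deviation, half the reference interval.  0 means
    every onset sits exactly on the grid; 1 means maximal misfit.
    """
    if reference_ioi <= 0:
        raise ValueError(f"reference_ioi must be positive, got {reference_ioi}")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    t = seq.onsets() - seq.first_onset
    d = np.abs(t - np.round(t / reference_ioi) * reference_ioi)
    u = d / (reference_ioi / 2.0)
    return float(np.mean(u) if aggregate == "mean" else np.median(u))


def _onset_grid(x) -> str:
    """Coerce a rhythm or binary grid to a 0/1 onset string."""
    if isinstance(x, RhythmSpec):
        cells = []
        for dur, played in zip(x.durations_grid, x.is_played):
            cells.append("1" if played else "0")
            cells.extend("0" * (dur - 1))
        return "".join(cells)
    if isinstance(x, str):
        if not x or set(x) - {"0", "1"}:
            raise ValueError(f"binary grid string may contain only 0/1, got {x!r}")
        return x
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0 or not np.isin(arr, (0, 1)).all():
        raise ValueError("binary grid must be a non-empty 1-D 0/1 collection")
    return "".join("1" if v else "0" for v in arr)


def edit_distance(a, b) -> int:
    """Levenshtein distance between two rhythms' binary onset grids.

    Rhythms are quantized onto a common grid (the finer of the two grid
    steps; the steps must be commensurable).  Unit insertion, deletion and
    substitution costs, so grids of unequal length remain comparable.
    """
    if isinstance(a, RhythmSpec) and isinstance(b, RhythmSpec):
        # finest common grid: gcd of the two steps as fractions
        step = Fraction(
            int(np.gcd(a.grid_step.numerator, b.grid_step.numerator)),
            int(np.lcm(a.grid_step.denominator, b.grid_step.denominator)),
        )
        a = _refine(a, step)
        b = _refine(b, step)
    sa, sb = _onset_grid(a), _onset_grid(b)
    # single-row Levenshtein DP
    prev = list(range(len(sb) + 1))
    for i, ca in enumerate(sa, 1):
        cur = [i]
        for j, cb in enumerate(sb, 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def _refine(r: RhythmSpec, step: Fraction) -> str:
    factor = int(r.grid_step / step)
    cells = []
    for dur, played in zip(r.durations_grid, r.is_played):
        cells.append("1" if played else "0")
        cells.extend("0" * (dur * factor - 1))
    return "".join(cells)


def phase_differences(
    test: EventSequence, reference: EventSequence, reference_label: str | None = None
) -> PhaseSet:
    """Phase of each test onset within its surrounding reference interval.

    A test onset ``t`` with reference onsets ``t_i <= t < t_{i+1}`` maps to
    ``360 * (t - t_i) / (t_{i+1} - t_i)`` degrees; an onset coinciding with
    the final reference onset gets phase 0.  Test onsets outside the
    reference span are dropped with a warning.  This interval-proportional
    convention generalizes to non-isochronous references.
    """
    ref = reference.onsets()
    if ref.size < 2:
        raise ValueError("reference needs at least 2 onsets")
    t = test.onsets()
    inside = (t >= ref[0]) & (t <= ref[-1])
    if not np.all(inside):
        warnings.warn(
            f"{int(np.sum(~inside))} test onset(s) fall outside the reference "
            "span and are dropped",
            stacklevel=2,
        )
    t = t[inside]
    idx = np.searchsorted(ref, t, side="right") - 1
    at_end = idx == ref.size - 1
    idx = np.minimum(idx, ref.size - 2)
    phi = 360.0 * (t - ref[idx]) / (ref[idx + 1] - ref[idx])
    phi[at_end] = 0.0  # landing exactly on the last reference onset
    phi = np.mod(phi, 360.0)
    label = reference_label or reference.name or ""
    return PhaseSet(phi, reference_label=label)


def summary(seq: EventSequence, reference_ioi: float | None = None) -> dict:
    """Per-sequence record of the standard measures, JSON-ready."""
    rec = {
        "id": seq.name,
        "n_events": seq.n_events,
        "n_iois": seq.n_iois,
        "npvi": npvi(seq) if seq.n_iois >= 2 else None,
        "cv": coefficient_of_variation(seq) if seq.n_iois >= 2 else None,
        "entropy_bits": shannon_entropy(seq),
    }
    if reference_ioi is not None:
        rec["ugof"] = ugof(seq, reference_ioi)
    return rec
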