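"""Synthetic sperm-whale coda fixtures.

Sperm whales produce stereotyped click patterns ("codas") whose inter-click
intervals identify clan membership.  This module generates synthetic coda
IOI data (in seconds) with three ground-truth rhythmic patterns —
regular (near-isochronous), decelerating (geometrically lengthening IOIs)
and grouped (short-short-long templates) — so the analysis pipeline can be
exercised end to end without any recorded data.  The ``pattern_label``
carried by each record is generator ground truth only; no analysis code
reads it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import EventSequence

__all__ = ["CodaRecord", "generate_synthetic_codas", "codas_to_csv", "codas_from_csv"]

PATTERNS = ("regular", "decelerating", "grouped")


@dataclass(frozen=True)
class CodaRecord:
    """One synthetic coda: identifier, click IOIs in seconds, true pattern."""

    coda_id: str
    iois: np.ndarray
    pattern_label: str

    def __post_init__(self) -> None:
        iois = np.asarray(self.iois, dtype=float)
        if iois.size < 1 or np.any(iois <= 0):
            raise ValueError("a coda needs at least 2 clicks with positive IOIs")
        iois.setflags(write=False)
        object.__setattr__(self, "iois", iois)

    def to_sequence(self) -> EventSequence:
        return EventSequence(self.iois, name=self.coda_id, unit="s")


def _jitter(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative jitter: positive-truncated Normal(1, sd) factors."""
    if sd == 0:
        return values
    factors = rng.normal(1.0, sd, size=values.size)
    while np.any(factors <= 0):
        bad = factors <= 0
        factors[bad] = rng.normal(1.0, sd, size=int(bad.sum()))
    return values * factors


def generate_synthetic_codas(
    n_codas: int,
    rng: np.random.Generator,
    pattern_mix: dict[str, float] | None = None,
    jitter_sd: float = 0.05,
) -> list[CodaRecord]:
    """Draw synthetic codas with known rhythmic structure.

    Per pattern:

    * ``regular`` — 3-12 clicks, base IOI drawn from [0.1, 0.4] s, 5 %
      multiplicative jitter by default;
    * ``decelerating`` — IOIs grow geometrically with a ratio in [1.1, 1.4],
      first IOI in [0.1, 0.25] s;
    * ``grouped`` — a short-short-long [1, 1, 2] template tiled to the coda
      length, scaled so the short IOI lies in [0.1, 0.4] s.

    ``pattern_mix`` maps pattern name to proportion (must sum to 1);
    default is an even three-way split.  Reproducible under a seeded rng.
    """
    if n_codas < 1:
        raise ValueError(f"n_codas must be >= 1, got {n_codas}")
    if pattern_mix is None:
        pattern_mix = {p: 1.0 / 3.0 for p in PATTERNS}
    unknown = set(pattern_mix) - set(PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern(s) {sorted(unknown)}; valid: {PATTERNS}")
    props = np.array([pattern_mix.get(p, 0.0) for p in PATTERNS])
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"pattern proportions must be >= 0 and sum to 1, got {pattern_mix}")

    labels = [PATTERNS[i] for i in rng.choice(len(PATTERNS), size=n_codas, p=props)]
    records = []
    for i, label in enumerate(labels):
        k = int(rng.integers(3, 13))  # number of clicks
        if label == "regular":
            base = rng.uniform(0.1, 0.4)
            iois = _jitter(np.full(k - 1, base), jitter_sd, rng)
        elif label == "decelerating":
            first = rng.uniform(0.1, 0.25)
            ratio = rng.uniform(1.1, 1.4)
            iois = _jitter(first * ratio ** np.arange(k - 1), jitter_sd, rng)
        else:  # grouped
            short = rng.uniform(0.1, 0.4)
            template = np.array([1.0, 1.0, 2.0]) * short
            iois = _jitter(np.tile(template, (k + 2) // 3)[: k - 1], jitter_sd, rng)
        records.append(CodaRecord(f"coda{i + 1:03d}", iois, label))
    return records


def codas_to_csv(records, path) -> None:
    """Long-format CSV: coda_id, ioi_index, ioi_s (plus the ground-truth label)."""
    rows = [
        {"coda_id": r.coda_id, "ioi_index": k, "ioi_s": ioi, "pattern_label": r.pattern_label}
        for r in records
        for k, ioi in enumerate(r.iois)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def codas_from_csv(path) -> list[CodaRecord]:
    df = pd.read_csv(path)
    for col in ("coda_id", "ioi_index", "ioi_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = []
    for cid, grp in df.groupby("coda_id", sort=False):
        grp = grp.sort_values("ioi_index")
        label = str(grp["pattern_label"].iloc[0]) if "pattern_label" in grp else ""
        out.append(CodaRecord(str(cid), grp["ioi_s"].to_numpy(), label))
    return out
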