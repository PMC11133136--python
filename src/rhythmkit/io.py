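"""CSV and JSON round-tripping for event sequences.

The CSV layout is long format: one row per event (``onset`` column) or per
interval (``ioi`` column), grouped by ``sequence_id``.  Exactly one of the
two value columns must be present.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .sequences import EventSequence, from_onsets

__all__ = [
    "sequences_to_csv",
    "sequences_from_csv",
    "sequence_to_json",
    "sequence_from_json",
]


def sequences_to_csv(seqs, path, *, column: str = "onset") -> None:
    """Write sequences to a long-format CSV.

    ``column`` selects the representation: ``"onset"`` writes one row per
    event, ``"ioi"`` one row per interval.  The end-with-interval flag is
    not representable in onset form; such sequences must be written as IOIs.
    """
    if column not in ("onset", "ioi"):
        raise ValueError(f"column must be 'onset' or 'ioi', got {column!r}")
    rows = []
    for i, seq in enumerate(seqs):
        sid = seq.name if seq.name is not None else f"seq{i}"
        if column == "onset":
            if seq.end_with_interval:
                raise ValueError(
                    f"sequence {sid!r} ends with an interval; onsets cannot "
                    "represent the trailing interval -- write IOIs instead"
                )
            for k, t in enumerate(seq.onsets()):
                rows.append({"sequence_id": sid, "index": k, "onset": t})
        else:
            for k, ioi in enumerate(seq.iois):
                rows.append({"sequence_id": sid, "index": k, "ioi": ioi})
    pd.DataFrame(rows).to_csv(path, index=False)


def sequences_from_csv(path, *, unit: str | None = None) -> list[EventSequence]:
    """Read sequences from a long-format CSV with an ``onset`` or ``ioi`` column."""
    df = pd.read_csv(path)
    if "sequence_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sequence_id'")
    has_onset = "onset" in df.columns
    has_ioi = "ioi" in df.columns
    if has_onset == has_ioi:
        raise ValueError(
            f"{path}: need exactly one of an 'onset' or an 'ioi' column"
        )
    out: list[EventSequence] = []
    for sid, grp in df.groupby("sequence_id", sort=False):
        if "index" in grp.columns:
            grp = grp.sort_values("index")
        if has_onset:
            seq = from_onsets(grp["onset"].to_numpy(), name=str(sid), unit=unit)
        else:
            seq = EventSequence(grp["ioi"].to_numpy(), name=str(sid), unit=unit)
        out.append(seq)
    return out


def sequence_to_json(seq: EventSequence) -> str:
    return json.dumps(
        {
            "iois": [float(x) for x in seq.iois],
            "end_with_interval": seq.end_with_interval,
            "first_onset": seq.first_onset,
            "name": seq.name,
            "unit": seq.unit,
        }
    )


def sequence_from_json(text: str) -> EventSequence:
    d = json.loads(text)
    return EventSequence(
        d["iois"],
        end_with_interval=d.get("end_with_interval", False),
        first_onset=d.get("first_onset", 0.0),
        name=d.get("name"),
        unit=d.get("unit"),
    )


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
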