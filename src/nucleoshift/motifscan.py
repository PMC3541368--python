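"""Short-linear-motif scanning for the LLTPPG docking sequence.

Several proteins dock at the central canal of WD40 beta-propellers through a
phosphopeptide motif whose sequence context is LLTPPG (the threonine carries
the phospho-mark).  Scanning a transcription-factor panel for this motif
classifies each factor as a candidate propeller binder.

Matching is exact by default; an opt-in Hamming distance (substitutions
only, no indels) covers near-matches.  Coordinates are 0-based and
half-open; overlapping hits are all reported, left to right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msquant import AMINO_ACIDS

__all__ = ["DEFAULT_PATTERN", "ProteinRecord", "MotifHit", "find_motif", "classify_panel"]

#: The beta-propeller central-canal docking motif.
DEFAULT_PATTERN = "LLTPPG"


def _check_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"{what} contains non-amino-acid symbol(s): {', '.join(sorted(bad))}"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence (uppercase, 20-letter alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, f"sequence of {self.id!r}"))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based start, the matched window and its
    Hamming distance to the pattern."""

    protein_id: str
    start: int
    end: int  # half-open
    matched: str
    mismatches: int


def find_motif(
    record: ProteinRecord,
    pattern: str = DEFAULT_PATTERN,
    max_mismatch: int = 0,
) -> list[MotifHit]:
    """All windows of ``record.sequence`` within Hamming distance
    ``max_mismatch`` of ``pattern``, left to right, overlaps allowed.

    A pattern longer than the sequence yields an empty result (not an
    error); illegal symbols in either input are rejected.
    """
    pattern = _check_sequence(pattern, "pattern")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = record.sequence
    m = len(pattern)
    if m > len(seq):
        return []
    # vectorized Hamming distance over all windows
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    dists = (windows != pat).sum(axis=1)
    hits = [
        MotifHit(
            protein_id=record.id,
            start=int(s),
            end=int(s) + m,
            matched=seq[s : s + m],
            mismatches=int(dists[s]),
        )
        for s in np.nonzero(dists <= max_mismatch)[0]
    ]
    return hits


def classify_panel(
    records: list[ProteinRecord],
    pattern: str = DEFAULT_PATTERN,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Classify a protein panel as motif-positive or -negative.

    Returns one row per input protein, in input order, with columns
    ``protein_id``, ``positive`` (>=1 hit), ``n_hits`` and ``positions``
    (semicolon-joined 0-based starts).
    """
    rows = []
    for rec in records:
        hits = find_motif(rec, pattern=pattern, max_mismatch=max_mismatch)
        rows.append(
            {
                "protein_id": rec.id,
                "positive": len(hits) > 0,
                "n_hits": len(hits),
                "positions": ";".join(str(h.start) for h in hits),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "positive", "n_hits", "positions"])
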