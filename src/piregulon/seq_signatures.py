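"""Positional nucleotide composition and length spectra of piRNA pools.

The two diagnostic signatures: a uridine bias at position 1 (1U) marks
primary piRNA biogenesis, and adenosine enrichment at position 10 (10A)
marks ping-pong amplification; their combination distinguishes the two
biogenesis routes. Frequencies are read-weighted by default so they
reflect the molecular pool rather than the species catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sequence_io import SmallRNALibrary

BASES = "ACGT"


@dataclass
class PositionalFrequencyMatrix:
    """Per-position base frequencies (rows: 1-based positions)."""

    matrix: pd.DataFrame  # index: position 1..L; columns: A C G T
    weighting: str
    one_u: float
    ten_a: float


def _as_records(library: SmallRNALibrary | Mapping[str, int]) -> dict[str, int]:
    if isinstance(library, SmallRNALibrary):
        return library.records
    return dict(library)


def positional_base_frequency(
    library: SmallRNALibrary | Mapping[str, int],
    max_pos: int = 32,
    weighting: str = "reads",
) -> PositionalFrequencyMatrix:
    """Base frequency at each position among sequences long enough to
    cover it, plus the scalar 1U (T at position 1) and 10A fractions."""
    if weighting not in ("reads", "species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    records = _as_records(library)
    if not records:
        raise ValueError("empty library")
    counts = np.zeros((max_pos, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq in sorted(records):
        w = records[seq] if weighting == "reads" else 1
        for pos, base in enumerate(seq[:max_pos]):
            counts[pos, base_idx[base]] += w
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals[:, None] > 0, counts / np.where(totals == 0, 1, totals)[:, None], np.nan)
    matrix = pd.DataFrame(freqs, index=np.arange(1, max_pos + 1), columns=list(BASES))
    one_u = float(matrix.loc[1, "T"]) if totals[0] > 0 else float("nan")
    ten_a = float(matrix.loc[10, "A"]) if max_pos >= 10 and totals[9] > 0 else float("nan")
    return PositionalFrequencyMatrix(
        matrix=matrix, weighting=weighting, one_u=one_u, ten_a=ten_a
    )


def length_distribution(
    library: SmallRNALibrary | Mapping[str, int], weighting: str = "reads"
) -> pd.Series:
    """Normalized length histogram of the library."""
    if weighting not in ("reads", "species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    records = _as_records(library)
    if not records:
        raise ValueError("empty library")
    acc: dict[int, float] = {}
    for seq in sorted(records):
        w = records[seq] if weighting == "reads" else 1
        acc[len(seq)] = acc.get(len(seq), 0.0) + w
    total = sum(acc.values())
    return pd.Series(
        {length: acc[length] / total for length in sorted(acc)}, name="fraction"
    )
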