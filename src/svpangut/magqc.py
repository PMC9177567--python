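"""MAG quality statistics and representative-MAG selection.

A metagenome-assembled genome (MAG) enters the SV comparison only after
quality control (completeness > 70%, contamination < 10%), and each species'
representative MAG — the reference for all same-species comparisons — is the
one maximising

    score = 1 * completeness - 5 * contamination + 0.5 * log10(N50)

with completeness/contamination on the 0-100 scale and N50 in bp.  The log
base is log10 (the dRep scoring convention); it only rescales the N50 term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def contig_n50(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("contig_n50 needs a non-empty list of lengths")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def mag_score(completeness: float, contamination: float, n50: int) -> float:
    """Representative-selection score: completeness - 5*contamination + 0.5*log10(N50)."""
    if n50 < 1:
        raise ValueError("n50 must be >= 1")
    return 1.0 * completeness - 5.0 * contamination + 0.5 * math.log10(n50)


@dataclass
class MagRecord:
    """Per-MAG quality record; n50 and score are derived on construction."""

    mag_id: str
    completeness: float
    contamination: float
    contig_lengths: list[int] = field(default_factory=list)
    n50: int = 0
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError("completeness must be in [0,100]")
        if not 0.0 <= self.contamination <= 100.0:
            raise ValueError("contamination must be in [0,100]")
        if self.contig_lengths:
            self.n50 = contig_n50(self.contig_lengths)
        if self.n50 >= 1:
            self.score = mag_score(self.completeness, self.contamination, self.n50)


def qc_filter(mags: list[MagRecord]) -> list[MagRecord]:
    """Keep MAGs with completeness strictly > 70 and contamination strictly < 10."""
    return [m for m in mags if m.completeness > 70.0 and m.contamination < 10.0]


def select_representative(mags: list[MagRecord]) -> str:
    """Highest-scoring MAG id; ties broken by higher completeness, then lower
    contamination, then lexicographic id."""
    if not mags:
        raise ValueError("select_representative needs a non-empty list")
    best = min(
        mags,
        key=lambda m: (-m.score, -m.completeness, m.contamination, m.mag_id),
    )
    return best.mag_id


def coding_density(
    orf_intervals: list[tuple[int, int]] | dict[str, list[tuple[int, int]]],
    genome_length: int,
    merge_overlaps: bool = False,
) -> float:
    """Sum of ORF interval lengths divided by the genome length.

    Intervals are 0-based half-open, optionally grouped per contig.  By
    default overlapping ORFs are counted as summed lengths (a literal sum of
    ORF lengths); ``merge_overlaps`` unions them first.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if isinstance(orf_intervals, dict):
        groups = list(orf_intervals.values())
    else:
        groups = [orf_intervals]
    total = 0
    for ivs in groups:
        for s, e in ivs:
            if e < s:
                raise ValueError(f"interval end before start: ({s},{e})")
        if merge_overlaps:
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            total += sum(e - s for s, e in merged)
        else:
            total += sum(e - s for s, e in ivs)
    return total / genome_length
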