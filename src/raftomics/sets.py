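"""Set-commonality (proportional Venn) statistics between protein sets.

Commonality between two protein sets is the Jaccard index expressed as a
percentage: ``100 * |A ∩ B| / |A ∪ B|``.  This is the denominator that
reproduces the receptor-subset commonality printed for the bundled
two-condition receptor fixture (8 shared of a 69-symbol union -> 11.6%).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OverlapStats:
    size_a: int
    size_b: int
    common: int
    union_size: int
    commonality_percent: float
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]
    shared: tuple[str, ...]

    def rounded_percent(self, ndigits: int = 1) -> float:
        """Presentation rounding; the stored percentage is exact."""
        return round(self.commonality_percent, ndigits)


def overlap_stats(a: set[str], b: set[str]) -> OverlapStats:
    """Exact overlap statistics between two (normalized) symbol sets.

    Raises
    ------
    ValueError
        If both sets are empty (the percentage is then undefined).
    """
    if not a and not b:
        raise ValueError("both sets empty: commonality undefined")
    shared = a & b
    union = a | b
    return OverlapStats(
        size_a=len(a),
        size_b=len(b),
        common=len(shared),
        union_size=len(union),
        commonality_percent=100.0 * len(shared) / len(union),
        unique_a=tuple(sorted(a - b)),
        unique_b=tuple(sorted(b - a)),
        shared=tuple(sorted(shared)),
    )
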