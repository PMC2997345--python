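"""Identification filtering, replicate consensus, and spectral-count ratios.

The filtering policy mirrors a conservative label-free shotgun-proteomics
validity rule: a protein is accepted in a replicate only with at least two
validated peptides, a minimum search-engine total score, and a minimum
identification confidence; it enters a condition's consensus set only when
detected in at least two of three animals.  Relative quantitation is the
deliberately simple spectral-count ratio (case:control) over the proteins
identified in both conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .core import ConditionDataset, ProteinIdentification

logger = logging.getLogger("raftomics")


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for accepting a protein identification.

    All thresholds are inclusive (``>=``).  ``min_replicates`` out of
    ``replicate_total`` animals must contain an accepted identification for
    the protein to enter the condition consensus.
    """

    min_peptides: int = 2
    min_score: float = 25.0
    min_confidence: float = 0.95
    min_replicates: int = 2
    replicate_total: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_replicates <= self.replicate_total:
            raise ValueError(
                f"need 0 < min_replicates <= replicate_total, got "
                f"{self.min_replicates}/{self.replicate_total}"
            )
        if not 0 < self.min_confidence <= 1:
            raise ValueError(f"min_confidence must be in (0, 1], got {self.min_confidence}")


@dataclass(frozen=True)
class SpectralRatioResult:
    """Case:control spectral-count ratio for one commonly identified protein."""

    symbol: str
    case_count: int
    control_count: int
    ratio: float
    rank: int = 0
    direction: str = "unchanged"


def filter_identifications(
    records: Sequence[ProteinIdentification], policy: FilterPolicy = FilterPolicy()
) -> list[ProteinIdentification]:
    """Keep records meeting every acceptance threshold (all inclusive).

    Input order is preserved; per-criterion rejection counts are logged.
    """
    kept: list[ProteinIdentification] = []
    rejected = {"peptides": 0, "score": 0, "confidence": 0}
    for rec in records:
        ok = True
        if rec.peptide_count < policy.min_peptides:
            rejected["peptides"] += 1
            ok = False
        if rec.id_score < policy.min_score:
            rejected["score"] += 1
            ok = False
        if rec.confidence < policy.min_confidence:
            rejected["confidence"] += 1
            ok = False
        if ok:
            kept.append(rec)
    logger.info(
        "filter_identifications: kept %d/%d (rejected: %d peptides, %d score, %d confidence)",
        len(kept), len(records), rejected["peptides"], rejected["score"], rejected["confidence"],
    )
    return kept


def consensus_set(
    filtered: Sequence[ProteinIdentification],
    condition: str,
    policy: FilterPolicy = FilterPolicy(),
    replicates: Sequence[str] | None = None,
) -> ConditionDataset:
    """Build the per-condition consensus: symbols seen in >= min_replicates animals.

    ``replicates`` may enumerate the expected replicate ids; by default they
    are taken from the records themselves.  Spectral counts are summed
    across replicates for every consensus symbol.
    """
    records = [r for r in filtered if r.condition == condition]
    rep_ids = sorted(replicates) if replicates is not None else sorted({r.replicate_id for r in records})
    if not rep_ids:
        raise ValueError(f"condition {condition!r} has no replicates")

    seen_in: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for rec in records:
        seen_in.setdefault(rec.symbol, set()).add(rec.replicate_id)
        counts[rec.symbol] = counts.get(rec.symbol, 0) + rec.spectral_count
    consensus = {s for s, reps in seen_in.items() if len(reps) >= policy.min_replicates}
    logger.info(
        "consensus_set[%s]: %d/%d symbols in >=%d of %d replicates",
        condition, len(consensus), len(seen_in), policy.min_replicates, len(rep_ids),
    )
    return ConditionDataset(
        condition=condition,
        replicates=list(rep_ids),
        consensus_symbols=consensus,
        spectral_counts={s: counts.get(s, 0) for s in consensus},
    )


def spectral_ratio(
    case: ConditionDataset,
    control: ConditionDataset,
    pseudocount: float = 0.5,
    pseudocount_mode: Literal["zero-only", "always", "off"] = "zero-only",
) -> list[SpectralRatioResult]:
    """Case:control count ratios for proteins present in both consensus sets.

    Counts are replicate-summed.  The continuity pseudocount is applied to
    both sums when either is zero (``zero-only``, default), always, or never
    (``off`` raises on a zero denominator / a 0:0 pair).
    """
    common = sorted(case.consensus_symbols & control.consensus_symbols)
    out: list[SpectralRatioResult] = []
    for sym in common:
        a = case.spectral_counts.get(sym, 0)
        b = control.spectral_counts.get(sym, 0)
        if pseudocount_mode == "always":
            ratio = (a + pseudocount) / (b + pseudocount)
        elif pseudocount_mode == "zero-only" and (a == 0 or b == 0):
            if a == 0 and b == 0 and pseudocount == 0:
                raise ValueError(f"{sym}: ratio 0:0 undefined with zero pseudocount")
            ratio = (a + pseudocount) / (b + pseudocount)
        else:
            if b == 0 or (a == 0 and b == 0):
                raise ValueError(
                    f"{sym}: counts {a}:{b} give an undefined ratio with pseudocounts disabled"
                )
            ratio = a / b
        out.append(SpectralRatioResult(symbol=sym, case_count=a, control_count=b, ratio=ratio))
    return out


def rank_differential(
    ratios: Sequence[SpectralRatioResult], top_n: int = 50
) -> tuple[list[SpectralRatioResult], list[SpectralRatioResult]]:
    """Split ratios into ranked up- (>1) and down- (<1) regulated lists.

    Rank 1 is the most extreme ratio on each side; proteins at exactly 1.0
    are reported in neither list.  Ties break by symbol so output is
    deterministic.
    """
    up = sorted((r for r in ratios if r.ratio > 1), key=lambda r: (-r.ratio, r.symbol))[:top_n]
    down = sorted((r for r in ratios if r.ratio < 1), key=lambda r: (r.ratio, r.symbol))[:top_n]
    up = [
        SpectralRatioResult(r.symbol, r.case_count, r.control_count, r.ratio, i + 1, "up")
        for i, r in enumerate(up)
    ]
    down = [
        SpectralRatioResult(r.symbol, r.case_count, r.control_count, r.ratio, i + 1, "down")
        for i, r in enumerate(down)
    ]
    return up, down


def ratios_to_frame(up: Sequence[SpectralRatioResult], down: Sequence[SpectralRatioResult]) -> pd.DataFrame:
    rows = [
        (r.symbol, r.case_count, r.control_count, r.ratio, r.rank, r.direction)
        for r in [*up, *down]
    ]
    return pd.DataFrame(
        rows, columns=["symbol", "case_count", "control_count", "ratio", "rank", "direction"]
    )
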