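"""Hypergeometric pathway enrichment, hybrid scores, and subtractive profiles.

For a dataset of ``n`` proteins drawn from a background universe of ``N``
symbols, a pathway with ``K`` members and ``k`` of them in the dataset is
scored by the right-tailed Fisher exact (hypergeometric) test

    P = P(X >= k),  X ~ Hypergeometric(N, K, n)

and summarized by the *hybrid score*

    hybrid = (k / K) * (-log10 P)

which combines how much of the pathway the dataset covers with how unlikely
the overlap is by chance.  A pathway is reported only when it holds at
least two dataset proteins and P <= .05.  The two-condition comparison
subtracts the control hybrid score from the case hybrid score: a positive
delta marks a pathway more active in the case condition, a negative delta
one more active in the control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .core import ConditionDataset, GeneSetCollection

logger = logging.getLogger("raftomics")

P_FLOOR = 1e-300  # keeps -log10 finite
MIN_OVERLAP = 2
ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one gene set in one dataset."""

    set_name: str
    category: str
    k: int  # overlap: dataset ∩ pathway
    K: int  # pathway size
    n: int  # dataset size
    N: int  # universe size
    ratio: float  # k / K (or percent, per ratio_scale)
    p_value: float
    hybrid_score: float
    passes: bool


@dataclass(frozen=True)
class DifferentialResult:
    """Case-minus-control hybrid-score delta for one gene set."""

    set_name: str
    category: str
    hs_control: float
    hs_case: float
    delta: float
    dominant: str  # "case" | "control" | "tied"


def hypergeometric_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact right-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters follow the sampling-without-replacement convention: ``N``
    population size, ``K`` marked items, ``n`` draws, ``k`` observed marks.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy's hypergeom is exact for these sizes
    return float(hypergeom.sf(k - 1, N, K, n))


def hybrid_score(ratio: float, p_value: float) -> float:
    """ratio x (-log10 P), with P floored to keep the product finite."""
    return ratio * (-math.log10(max(p_value, P_FLOOR)))


def enrich(
    dataset: ConditionDataset,
    sets: GeneSetCollection,
    ratio_scale: Literal["fraction", "percent"] = "fraction",
) -> list[EnrichmentResult]:
    """Score every gene set against one condition dataset.

    Dataset symbols outside the universe are dropped with a warning (they
    cannot participate in a test defined on the universe).  Results are
    sorted by hybrid score descending, ties by set name.
    """
    if not dataset.consensus_symbols:
        raise ValueError("empty dataset")
    if not sets.sets:
        raise ValueError("empty gene-set collection")
    symbols = dataset.consensus_symbols & sets.universe
    dropped = len(dataset.consensus_symbols) - len(symbols)
    if dropped:
        logger.warning("enrich[%s]: dropped %d symbols outside universe", dataset.condition, dropped)
    n, N = len(symbols), len(sets.universe)
    scale = 100.0 if ratio_scale == "percent" else 1.0
    results = []
    for gs in sets.sets:
        k = len(symbols & gs.members)
        K = len(gs.members)
        p = hypergeometric_right_tail(k, K, n, N)
        ratio = scale * k / K
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                category=gs.category,
                k=k, K=K, n=n, N=N,
                ratio=ratio,
                p_value=p,
                hybrid_score=hybrid_score(ratio, p),
                passes=(k >= MIN_OVERLAP and p <= ALPHA),
            )
        )
    results.sort(key=lambda r: (-r.hybrid_score, r.set_name))
    return results


def differential_profile(
    case_results: Sequence[EnrichmentResult],
    control_results: Sequence[EnrichmentResult],
) -> list[DifferentialResult]:
    """Subtractive profile over sets passing the inclusion rule in >= 1 dataset.

    A dataset in which a set fails the (k >= 2, P <= .05) rule contributes a
    hybrid score of zero to the subtraction; sets failing in both datasets
    are excluded.  The profile is antisymmetric under swapping the inputs.
    """
    case_by = {r.set_name: r for r in case_results}
    ctrl_by = {r.set_name: r for r in control_results}
    if set(case_by) != set(ctrl_by):
        raise ValueError("case and control results computed on different gene-set collections")
    out = []
    for name in case_by:
        rc, rk = ctrl_by[name], case_by[name]
        if not (rc.passes or rk.passes):
            continue
        hs_case = rk.hybrid_score if rk.passes else 0.0
        hs_ctrl = rc.hybrid_score if rc.passes else 0.0
        delta = hs_case - hs_ctrl
        dominant = "case" if delta > 0 else ("control" if delta < 0 else "tied")
        out.append(
            DifferentialResult(
                set_name=name, category=rk.category,
                hs_control=hs_ctrl, hs_case=hs_case, delta=delta, dominant=dominant,
            )
        )
    out.sort(key=lambda r: (-r.delta, r.set_name))
    return out


def category_report(
    differentials: Sequence[DifferentialResult], category: str
) -> pd.DataFrame:
    """Differential table restricted to one functional category, sorted by delta.

    ``dominant`` encodes the plotting convention (case-dominant vs
    control-dominant bars, red vs blue).
    """
    known = sorted({d.category for d in differentials})
    if category not in known:
        raise ValueError(f"unknown category {category!r}; known: {', '.join(known) or '(none)'}")
    rows = [d for d in differentials if d.category == category]
    if not rows:
        logger.warning("category %s: no passing sets", category)
    rows.sort(key=lambda d: (-d.delta, d.set_name))
    return pd.DataFrame(
        [(d.set_name, d.category, d.hs_case, d.hs_control, d.delta, d.dominant) for d in rows],
        columns=["set_name", "category", "hs_case", "hs_control", "delta", "dominant"],
    )


def results_to_frame(
    case_results: Sequence[EnrichmentResult],
    control_results: Sequence[EnrichmentResult],
    differentials: Sequence[DifferentialResult],
) -> pd.DataFrame:
    """Joined per-set table: enrichment in each dataset plus the delta."""
    diff_by = {d.set_name: d for d in differentials}
    ctrl_by = {r.set_name: r for r in control_results}
    rows = []
    for rk in case_results:
        rc = ctrl_by[rk.set_name]
        d = diff_by.get(rk.set_name)
        rows.append(
            (
                rk.set_name, rk.category, rk.k, rk.K, rk.n, rk.N, rk.ratio, rk.p_value,
                rk.hybrid_score, rk.passes, rc.k, rc.ratio, rc.p_value, rc.hybrid_score,
                rc.passes, d.delta if d else float("nan"), d.dominant if d else "excluded",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set_name", "category", "k_case", "K", "n_case", "N", "ratio_case", "p_case",
            "hybrid_case", "passes_case", "k_control", "ratio_control", "p_control",
            "hybrid_control", "passes_control", "delta", "dominant",
        ],
    )
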