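"""Synthetic two-condition study generator with machine-readable ground truth.

Every pipeline input can be generated here with known truth so each stage
is testable without external downloads: two condition protein sets with an
exact target commonality, identification tables whose filter/consensus
outcome is known, Poisson spectral counts with planted fold changes, gene
sets with planted condition-specific enrichment, a literature corpus with
planted gene-term co-occurrence, and grayscale images with a planted
Gaussian band.  One global seed fans out to independent per-generator
streams through stable labels, so regenerating any one input never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConditionDataset, GeneSet, GeneSetCollection, ProteinIdentification
from .lsi import DEFAULT_INTERROGATION_TERMS, Corpus, tokenize

_STREAMS = {
    "condition_sets": 1,
    "gene_sets": 2,
    "corpus": 3,
    "spectral_counts": 4,
    "band_image": 5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate the shape of a two-condition membrane-proteome study:
    a few hundred consensus proteins per condition with minority overlap,
    three animals per condition with a 2-of-3 consensus rule, modest
    Poisson spectral counts, and a small planted-association literature
    corpus.
    """

    seed: int = 0
    universe_size: int = 600
    control_size: int = 300
    case_size: int = 285
    target_commonality: float = 0.17
    replicate_count: int = 3
    min_replicates: int = 2
    n_gene_sets: int = 30
    n_planted_sets: int = 6
    gene_set_size: int = 10
    planted_strength: float = 0.8
    poisson_lambda: float = 20.0
    planted_fold_change: float = 2.0
    n_planted_folds: int = 10
    corpus_docs: int = 200
    corpus_genes: int = 50
    n_planted_pairs: int = 20
    cooccur_docs: int = 5
    background_vocab: int = 300
    interrogation_terms: tuple[str, ...] = DEFAULT_INTERROGATION_TERMS
    image_shape: tuple[int, int] = (60, 80)
    band_amplitude: float = 0.5
    band_sigma: float = 6.0
    band_background: float = 0.2
    image_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_commonality <= 1.0:
            raise ValueError(f"target_commonality must be in [0,1], got {self.target_commonality}")
        for name in ("universe_size", "control_size", "case_size", "replicate_count",
                     "corpus_genes", "background_vocab"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, label: str) -> np.random.Generator:
        """Per-generator stream derived from the global seed by stable label."""
        return np.random.default_rng([self.seed, _STREAMS[label]])


def _symbols(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# condition protein sets


@dataclass
class ConditionSetsTruth:
    control_symbols: set[str]
    case_symbols: set[str]
    shared: set[str]
    commonality_percent: float


@dataclass
class SyntheticConditionSets:
    control: ConditionDataset
    case: ConditionDataset
    records: list[ProteinIdentification]
    truth: ConditionSetsTruth


def shared_core_size(size_a: int, size_b: int, target: float) -> int:
    """Exact shared-core size giving commonality |A∩B|/|A∪B| = target.

    Solves s/(a + b - s) = c for s and rounds to the nearest feasible
    integer; raises with the feasible commonality range when the target
    cannot be realized for the given sizes.
    """
    a, b = size_a, size_b
    s = round(target * (a + b) / (1.0 + target))
    lo, hi = 0, min(a, b)
    if not lo <= s <= hi:
        c_max = hi / (a + b - hi)
        raise ValueError(
            f"target commonality {target} infeasible for sizes ({a}, {b}); "
            f"feasible range is [0.0, {c_max:.3f}]"
        )
    return s


def make_condition_sets(cfg: SyntheticConfig) -> SyntheticConditionSets:
    """Two condition consensus sets with an exactly constructed commonality.

    The shared core is sized deterministically from the target; the
    remaining unique members are sampled from the universe.  Per-replicate
    identification records are emitted such that running the default
    filter + 2-of-3 consensus reproduces the intended sets exactly: every
    intended symbol passes all thresholds in >= min_replicates animals,
    and decoy records (below-threshold evidence and single-replicate
    detections) are planted to exercise the filters.
    """
    rng = cfg.rng("condition_sets")
    a, b = cfg.control_size, cfg.case_size
    s = shared_core_size(a, b, cfg.target_commonality)
    union = a + b - s
    if union > cfg.universe_size:
        raise ValueError(
            f"union {union} exceeds universe {cfg.universe_size}; "
            f"increase universe_size or target_commonality"
        )
    universe = _symbols(cfg.universe_size)
    picked = rng.choice(cfg.universe_size, size=union, replace=False)
    shared = {universe[i] for i in picked[:s]}
    control = shared | {universe[i] for i in picked[s : s + (a - s)]}
    case = shared | {universe[i] for i in picked[s + (a - s) :]}

    records: list[ProteinIdentification] = []
    reps = {cond: [f"{cond}-{i+1}" for i in range(cfg.replicate_count)]
            for cond in ("control", "case")}

    def emit(symbol: str, condition: str, replicate: str, passing: bool) -> None:
        if passing:
            peptides = 2 + int(rng.poisson(2))
            score = 25.0 + float(rng.exponential(20.0))
            conf = float(0.95 + 0.05 * rng.random())
        else:
            mode = rng.integers(3)
            peptides = 1 if mode == 0 else 2 + int(rng.poisson(2))
            score = float(rng.uniform(5, 24.9)) if mode == 1 else 25.0 + float(rng.exponential(20.0))
            conf = float(rng.uniform(0.5, 0.949)) if mode == 2 else float(0.95 + 0.05 * rng.random())
            if mode != 0 and peptides < 2:
                peptides = 2
        records.append(
            ProteinIdentification(
                symbol=symbol, accession=f"ACC_{symbol}",
                peptide_count=peptides, id_score=round(score, 1),
                confidence=round(conf, 3), spectral_count=int(rng.poisson(cfg.poisson_lambda)),
                replicate_id=replicate, condition=condition,
            )
        )

    picked_set = set(int(i) for i in picked)
    leftovers = [universe[i] for i in range(cfg.universe_size) if i not in picked_set]
    rng.shuffle(leftovers)
    decoy_iter = iter(leftovers)
    for condition, members in (("control", control), ("case", case)):
        for sym in sorted(members):
            n_present = int(rng.integers(cfg.min_replicates, cfg.replicate_count + 1))
            present = rng.choice(cfg.replicate_count, size=n_present, replace=False)
            for j in present:
                emit(sym, condition, reps[condition][j], passing=True)
        # decoys: single-replicate detections and failed identifications
        for _ in range(max(3, len(members) // 20)):
            try:
                sym = next(decoy_iter)
            except StopIteration:
                break
            # a passing decoy in a single replicate still fails the consensus rule
            j = int(rng.integers(cfg.replicate_count))
            emit(sym, condition, reps[condition][j], passing=bool(rng.integers(2)))

    truth = ConditionSetsTruth(
        control_symbols=control, case_symbols=case, shared=shared,
        commonality_percent=100.0 * s / union,
    )
    control_ds = ConditionDataset(
        condition="control", replicates=reps["control"], consensus_symbols=set(control),
        spectral_counts={s_: 0 for s_ in control},
    )
    case_ds = ConditionDataset(
        condition="case", replicates=reps["case"], consensus_symbols=set(case),
        spectral_counts={s_: 0 for s_ in case},
    )
    return SyntheticConditionSets(control=control_ds, case=case_ds, records=records, truth=truth)


# ---------------------------------------------------------------------------
# gene sets with planted enrichment


@dataclass
class GeneSetsTruth:
    planted_signs: dict[str, int]  # set name -> expected delta sign (+1 case, -1 control)


def make_gene_sets(
    cfg: SyntheticConfig, condition_sets: SyntheticConditionSets
) -> tuple[GeneSetCollection, GeneSetsTruth]:
    """Background gene sets plus planted condition-enriched sets.

    A planted set draws each member from the designated condition's unique
    symbols with probability ``planted_strength`` (from the whole universe
    otherwise), so its enrichment delta has a known expected sign.
    """
    if not 0.0 < cfg.planted_strength <= 1.0:
        raise ValueError(f"planted_strength must be in (0,1], got {cfg.planted_strength}")
    rng = cfg.rng("gene_sets")
    universe = _symbols(cfg.universe_size)
    uniques = {
        "case": sorted(condition_sets.truth.case_symbols - condition_sets.truth.control_symbols),
        "control": sorted(condition_sets.truth.control_symbols - condition_sets.truth.case_symbols),
    }
    categories = ("cellular-signaling", "neuronal-function", "energy-metabolism",
                  "stress-response", "receptor-signaling")
    sets: list[GeneSet] = []
    signs: dict[str, int] = {}
    for i in range(cfg.n_planted_sets):
        target = "case" if i % 2 == 0 else "control"
        members: set[str] = set()
        while len(members) < cfg.gene_set_size:
            pool = uniques[target] if rng.random() < cfg.planted_strength else universe
            members.add(pool[int(rng.integers(len(pool)))])
        name = f"PLANTED_{target.upper()}_{i:02d}"
        sets.append(GeneSet(name=name, description=f"planted {target}-enriched",
                            members=frozenset(members),
                            category=categories[i % len(categories)]))
        signs[name] = +1 if target == "case" else -1
    for i in range(cfg.n_gene_sets - cfg.n_planted_sets):
        idx = rng.choice(cfg.universe_size, size=cfg.gene_set_size, replace=False)
        sets.append(GeneSet(name=f"BACKGROUND_{i:02d}", description="background set",
                            members=frozenset(universe[j] for j in idx),
                            category=categories[i % len(categories)]))
    collection = GeneSetCollection(sets=sets, universe=set(universe))
    return collection, GeneSetsTruth(planted_signs=signs)


# ---------------------------------------------------------------------------
# literature corpus with planted gene-term associations


@dataclass
class CorpusTruth:
    genes: list[str]
    planted_pairs: set[tuple[str, str]]  # (gene symbol, interrogation term)


def make_corpus(
    cfg: SyntheticConfig, genes: Sequence[str] | None = None
) -> tuple[Corpus, CorpusTruth]:
    """Background abstracts plus planted gene-term co-occurrence documents.

    Background documents draw ~40 tokens from a Zipf-weighted nuisance
    vocabulary.  Every gene receives a few grounding documents mentioning
    it against background noise; each planted (gene, term) pair
    additionally co-occurs, prominently, in ``cooccur_docs`` dedicated
    documents.  Genes and term tokens are kept disjoint from the nuisance
    vocabulary and the stopword list.
    """
    if cfg.corpus_docs <= 0:
        raise ValueError("corpus_docs must be positive")
    rng = cfg.rng("corpus")
    gene_list = list(genes) if genes is not None else [f"GEN{i:03d}" for i in range(cfg.corpus_genes)]
    terms = list(cfg.interrogation_terms)
    vocab = [f"w{i:03d}" for i in range(cfg.background_vocab)]
    zipf_p = 1.0 / np.arange(1, cfg.background_vocab + 1)
    zipf_p /= zipf_p.sum()

    def background(n_tokens: int) -> list[str]:
        idx = rng.choice(cfg.background_vocab, size=n_tokens, p=zipf_p)
        return [vocab[i] for i in idx]

    # choose planted pairs over the gene x term grid
    n_pairs = cfg.n_planted_pairs
    grid = [(g, t) for g in gene_list for t in terms]
    if n_pairs > len(grid):
        raise ValueError("more planted pairs than gene-term combinations")
    pair_idx = rng.choice(len(grid), size=n_pairs, replace=False)
    planted = [grid[i] for i in sorted(pair_idx)]
    n_planted_docs = n_pairs * cfg.cooccur_docs
    grounding_per_gene = 2
    n_ground = len(gene_list) * grounding_per_gene
    if n_planted_docs + n_ground > cfg.corpus_docs:
        raise ValueError(
            f"corpus_docs={cfg.corpus_docs} too small for {n_planted_docs} planted "
            f"+ {n_ground} grounding documents"
        )

    docs: list[tuple[str, str]] = []
    counter = 0

    def add(text_tokens: list[str]) -> None:
        nonlocal counter
        docs.append((f"doc{counter:04d}", " ".join(text_tokens)))
        counter += 1

    for gene in gene_list:  # grounding documents: gene + noise
        for _ in range(grounding_per_gene):
            toks = background(30) + [gene.lower()] * 2
            rng.shuffle(toks)
            add(toks)
    for gene, term in planted:  # planted co-occurrence documents
        term_toks = tokenize(term)
        for _ in range(cfg.cooccur_docs):
            toks = [gene.lower()] * 3 + term_toks * 3 + background(10)
            rng.shuffle(toks)
            add(toks)
    while counter < cfg.corpus_docs:  # pure background
        add(background(40))

    corpus = Corpus(documents=docs)
    return corpus, CorpusTruth(genes=gene_list, planted_pairs=set(planted))


# ---------------------------------------------------------------------------
# spectral counts with planted fold changes


@dataclass
class SpectralTruth:
    fold_changes: dict[str, float]  # symbol -> planted case:control fold


def make_spectral_counts(
    cfg: SyntheticConfig, condition_sets: SyntheticConditionSets
) -> tuple[pd.DataFrame, SpectralTruth]:
    """Per-replicate Poisson spectral counts over the shared consensus symbols.

    Control replicates draw counts ~ Poisson(lambda); case replicates draw
    ~ Poisson(f * lambda) where f is the planted fold change (1 for
    unplanted symbols).  The replicate-summed counts are written back into
    the condition datasets so ratio estimation runs on this table.
    """
    if cfg.poisson_lambda <= 0:
        raise ValueError(f"poisson_lambda must be > 0, got {cfg.poisson_lambda}")
    rng = cfg.rng("spectral_counts")
    shared = sorted(condition_sets.truth.shared)
    n_fold = min(cfg.n_planted_folds, len(shared))
    fold_idx = rng.choice(len(shared), size=n_fold, replace=False)
    folds = {shared[i]: cfg.planted_fold_change for i in fold_idx}
    rows = []
    for sym in shared:
        f = folds.get(sym, 1.0)
        ctrl = rng.poisson(cfg.poisson_lambda, size=cfg.replicate_count)
        case = rng.poisson(f * cfg.poisson_lambda, size=cfg.replicate_count)
        for j in range(cfg.replicate_count):
            rows.append((sym, "control", f"control-{j+1}", int(ctrl[j])))
            rows.append((sym, "case", f"case-{j+1}", int(case[j])))
        condition_sets.control.spectral_counts[sym] = int(ctrl.sum())
        condition_sets.case.spectral_counts[sym] = int(case.sum())
    table = pd.DataFrame(rows, columns=["symbol", "condition", "replicate", "spectral_count"])
    return table, SpectralTruth(fold_changes=folds)


# ---------------------------------------------------------------------------
# band images


@dataclass
class BandTruth:
    amplitude: float
    sigma: float
    background: float
    center: tuple[float, float]  # (x, y)


def make_band_image(
    cfg: SyntheticConfig, amplitude: float | None = None
) -> tuple[np.ndarray, BandTruth]:
    """Flat background + additive Gaussian band + Gaussian pixel noise."""
    if cfg.band_sigma <= 0:
        raise ValueError(f"band_sigma must be > 0, got {cfg.band_sigma}")
    h, w = cfg.image_shape
    if min(h, w) < 6 * cfg.band_sigma / 2:
        raise ValueError(f"image {cfg.image_shape} too small for band sigma {cfg.band_sigma}")
    rng = cfg.rng("band_image")
    amp = cfg.band_amplitude if amplitude is None else amplitude
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    band = amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * cfg.band_sigma**2))
    noise = rng.normal(0.0, cfg.image_noise_sd, size=(h, w)) if cfg.image_noise_sd > 0 else 0.0
    img = cfg.band_background + band + noise
    return img, BandTruth(amplitude=amp, sigma=cfg.band_sigma,
                          background=cfg.band_background, center=(cx, cy))


def gaussian_band_roi_mean(amplitude: float, sigma: float, roi_halfwidth: float) -> float:
    """Closed-form mean of a centered 2-D Gaussian over a square ROI.

    For a square ROI of side ``2m`` centered on the band, the mean of
    A*exp(-(x^2+y^2)/(2 sigma^2)) over the continuous square is
    A * (sigma sqrt(pi/2) * erf(m / (sigma sqrt 2)) / m)^2 — the analytic
    oracle for band recovery tests.  A ROI of ``2p+1`` pixels centered on a
    pixel covers the continuous square of half-width ``p + 0.5`` (each
    pixel is a unit cell), so pass ``roi_halfwidth=p + 0.5`` when
    comparing against a discrete pixel mean.
    """
    from math import erf, pi, sqrt

    m = float(roi_halfwidth)
    one_d = sigma * sqrt(pi / 2.0) * erf(m / (sigma * sqrt(2.0))) / m
    return amplitude * one_d * one_d
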