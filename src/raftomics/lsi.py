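"""Latent semantic indexing of a literature corpus and gene-term scoring.

A weighted term-document matrix A (terms x documents, log-entropy or
tf-idf weighting) is factorized by truncated singular value decomposition,
A ~ U_k S_k V_k'.  Each document is smoothed onto the rank-k subspace; a
gene is represented by the centroid of its linked documents' smoothed
columns, and an interrogation term by the weighted centroid of its token
axes in term space.  The association score is the cosine of the two
vectors, so it lies in [-1, 1]; at full rank it coincides exactly with the
cosine computed on the unfactorized weighted matrix, while truncation lets
genes score against terms they never co-occur with (implicit association)
through shared latent structure.

An *explicit* association is a score at or above the reporting threshold
(default 0.1).  The multidimensional filter keeps only genes explicitly
associated with at least two interrogation terms, mirroring a
keystone-protein selection across several disease-relevant concepts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import AliasMap

logger = logging.getLogger("raftomics")

_TOKEN_RE = re.compile(r"[a-z0-9]+")

#: queries return this sentinel for genes with no linked literature
NO_SCORE = float("nan")

DEFAULT_INTERROGATION_TERMS = (
    "Alzheimer's",
    "oxidation",
    "neurodegeneration",
    "synaptic transmission",
    "neurogenesis",
    "scaffolding",
    "GPCR",
)


def default_stopwords() -> frozenset[str]:
    path = Path(__file__).parent / "data" / "stopwords.txt"
    return frozenset(w.strip() for w in path.read_text().split() if w.strip())


def tokenize(text: str, stopwords: frozenset[str] = frozenset()) -> list[str]:
    """Lower-case alphanumeric tokens of length >= 2, stopwords removed."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2 and t not in stopwords]


@dataclass
class Corpus:
    """A literature corpus: one (doc_id, text) record per abstract."""

    documents: list[tuple[str, str]]
    stopwords: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [d for d, _ in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.documents]

    def vocabulary(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, text in self.documents:
            for tok in tokenize(text, self.stopwords):
                seen.setdefault(tok)
        return sorted(seen)

    @classmethod
    def from_jsonl(cls, path: str | Path, stopwords: frozenset[str] = frozenset()) -> "Corpus":
        import json

        docs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            docs.append((str(rec["doc_id"]), str(rec["text"])))
        if not docs:
            raise ValueError(f"{path}: empty corpus")
        return cls(documents=docs, stopwords=stopwords)

    def to_jsonl(self, path: str | Path) -> None:
        import json

        with open(path, "w") as fh:
            for doc_id, text in self.documents:
                fh.write(json.dumps({"doc_id": doc_id, "text": text}) + "\n")


@dataclass
class LsiModel:
    """Truncated-SVD factorization of a weighted term-document matrix.

    ``term_factors`` is U_k (terms x k, orthonormal columns),
    ``doc_coords`` is S_k V_k' (k x docs), so column j of
    ``term_factors @ doc_coords`` is document j smoothed to rank k.
    ``global_weights`` carries the per-term global weight used to fold
    queries in; ``presence`` is the binary term-in-document matrix used for
    explicit/implicit bookkeeping.
    """

    vocabulary: list[str]
    doc_ids: list[str]
    weighting: str
    k: int
    term_factors: np.ndarray
    singular_values: np.ndarray
    doc_coords: np.ndarray
    global_weights: np.ndarray
    presence: np.ndarray
    stopwords: frozenset[str] = frozenset()
    gene_doc_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._vocab_index = {t: i for i, t in enumerate(self.vocabulary)}
        self._doc_index = {d: j for j, d in enumerate(self.doc_ids)}
        sv = self.singular_values
        if np.any(np.diff(sv) > 1e-9) or np.any(sv <= 0):
            raise ValueError("singular values must be positive and non-increasing")

    def query_vector(self, text: str) -> np.ndarray:
        """Fold an interrogation term into term space.

        Multi-token terms become the centroid of their token axes, each
        scaled by its global weight and the local weight of a single
        occurrence.
        """
        tokens = [t for t in tokenize(text, self.stopwords) if t in self._vocab_index]
        if not tokens:
            raise ValueError(f"term {text!r} has no in-vocabulary token")
        q = np.zeros(len(self.vocabulary))
        for tok in tokens:
            i = self._vocab_index[tok]
            q[i] += self.global_weights[i] * math.log2(2.0)
        return q / len(tokens)


def _weight_matrix(tf: np.ndarray, weighting: str) -> tuple[np.ndarray, np.ndarray]:
    """Apply log-entropy or tf-idf weighting; returns (A, global_weights)."""
    n_docs = tf.shape[1]
    if weighting == "log-entropy":
        local = np.log2(1.0 + tf)
        gf = tf.sum(axis=1, keepdims=True)  # global term frequency
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(gf > 0, tf / gf, 0.0)
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        denom = math.log2(n_docs) if n_docs > 1 else 1.0
        g = 1.0 + plogp.sum(axis=1) / denom
        g = np.clip(g, 0.0, 1.0)
    elif weighting == "tf-idf":
        local = tf.astype(float)
        df = (tf > 0).sum(axis=1)
        g = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0  # smoothed idf
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return g[:, None] * local, g


def build_index(
    corpus: Corpus,
    k: int | None = None,
    weighting: Literal["log-entropy", "tf-idf"] = "log-entropy",
) -> LsiModel:
    """Build the weighted term-document matrix and factorize it to rank k.

    ``k`` defaults to min(300, matrix rank) and is always capped at the
    numerical rank, so requesting full rank reproduces the weighted matrix
    exactly.  The deterministic LAPACK SVD is used (no randomized solver).
    """
    if k is not None and k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not corpus.documents:
        raise ValueError("empty corpus")
    vocab = corpus.vocabulary()
    if not vocab:
        raise ValueError("empty vocabulary after tokenization/stopword removal")
    vocab_index = {t: i for i, t in enumerate(vocab)}
    tf = np.zeros((len(vocab), len(corpus.documents)))
    for j, (_, text) in enumerate(corpus.documents):
        for tok in tokenize(text, corpus.stopwords):
            tf[vocab_index[tok], j] += 1.0
    A, g = _weight_matrix(tf, weighting)

    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("weighted matrix has rank 0")
    k_eff = min(k if k is not None else 300, rank)
    return LsiModel(
        vocabulary=vocab,
        doc_ids=corpus.doc_ids,
        weighting=weighting,
        k=k_eff,
        term_factors=U[:, :k_eff],
        singular_values=s[:k_eff],
        doc_coords=s[:k_eff, None] * Vt[:k_eff],
        global_weights=g,
        presence=(tf > 0),
        stopwords=corpus.stopwords,
    )


def map_genes_to_documents(
    corpus: Corpus,
    symbols: Sequence[str],
    aliases: AliasMap | None = None,
) -> dict[str, set[str]]:
    """Link each gene to the documents mentioning it as a whole-word token.

    A document is linked to a gene iff the symbol, or a synonym declared in
    the alias map, occurs as a case-insensitive whole token ("IGF1R" does
    not link "IGF1").  Genes with no document are returned with an empty
    set and logged.
    """
    name_to_gene: dict[str, str] = {}
    for sym in symbols:
        name_to_gene[sym.lower()] = sym
        if aliases:
            for syn, official in aliases.items():
                if official == sym:
                    name_to_gene[syn.lower()] = sym
    out: dict[str, set[str]] = {sym: set() for sym in symbols}
    for doc_id, text in corpus.documents:
        toks = set(_TOKEN_RE.findall(text.lower()))
        for tok in toks & name_to_gene.keys():
            out[name_to_gene[tok]].add(doc_id)
    for sym, docs in out.items():
        if not docs:
            logger.warning("gene %s has no linked documents", sym)
    return out


def _gene_coords(model: LsiModel, gene: str) -> np.ndarray | None:
    doc_ids = model.gene_doc_map.get(gene, set())
    cols = [model._doc_index[d] for d in doc_ids if d in model._doc_index]
    if not cols:
        return None
    return model.doc_coords[:, cols].mean(axis=1)


def gene_term_score(model: LsiModel, gene: str, term: str) -> float:
    """Cosine association between a gene and an interrogation term.

    The gene vector is the centroid of its documents' rank-k smoothed
    columns; because U_k has orthonormal columns the cosine reduces to a
    k-dimensional dot product against the projected query.  Genes with no
    linked document return the NaN sentinel and are excluded downstream.
    """
    q = model.query_vector(term)  # raises for out-of-vocabulary terms
    c = _gene_coords(model, gene)
    if c is None:
        return NO_SCORE
    nq, nc = np.linalg.norm(q), np.linalg.norm(c)
    if nq == 0 or nc == 0:
        return 0.0
    # cos(q, U_k c) = (U_k' q) . c / (|q| |c|)  since |U_k c| = |c|
    return float((model.term_factors.T @ q) @ c / (nq * nc))


@dataclass
class LsiScoreMatrix:
    """Genes x interrogation-terms score matrix with association flags.

    ``explicit`` marks scores at/above the threshold; ``implicit`` marks
    the explicit associations where the gene never co-occurs with any
    token of the term in a single document (association inferred purely
    through latent structure).
    """

    scores: pd.DataFrame
    threshold: float
    explicit: pd.DataFrame
    implicit: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def terms(self) -> list[str]:
        return list(self.scores.columns)


def score_matrix(
    model: LsiModel,
    genes: Sequence[str],
    terms: Sequence[str] = DEFAULT_INTERROGATION_TERMS,
    threshold: float = 0.1,
) -> LsiScoreMatrix:
    """Score every gene against every interrogation term."""
    data = np.full((len(genes), len(terms)), np.nan)
    cooccur = np.zeros((len(genes), len(terms)), dtype=bool)
    for j, term in enumerate(terms):
        toks = [t for t in tokenize(term, model.stopwords) if t in model._vocab_index]
        if not toks:
            logger.warning("term %r has no in-vocabulary token; column left unscored", term)
            continue
        tok_rows = [model._vocab_index[t] for t in toks]
        for i, gene in enumerate(genes):
            data[i, j] = gene_term_score(model, gene, term)
            doc_cols = [
                model._doc_index[d]
                for d in model.gene_doc_map.get(gene, set())
                if d in model._doc_index
            ]
            if doc_cols and tok_rows:
                cooccur[i, j] = bool(model.presence[np.ix_(tok_rows, doc_cols)].any())
    scores = pd.DataFrame(data, index=list(genes), columns=list(terms))
    explicit = scores >= threshold  # NaN (unscored) compares False
    implicit = explicit & ~pd.DataFrame(cooccur, index=list(genes), columns=list(terms))
    return LsiScoreMatrix(scores=scores, threshold=threshold, explicit=explicit, implicit=implicit)


@dataclass
class MultidimensionalFilterResult:
    """Outcome of the >= min_terms explicit-association filter."""

    kept: pd.DataFrame  # gene, label, n_explicit_terms + per-term scores
    per_term_unique_counts: pd.DataFrame  # term, case_unique, control_unique


def multidimensional_filter(
    case_scores: LsiScoreMatrix,
    control_scores: LsiScoreMatrix,
    threshold: float = 0.1,
    min_terms: int = 2,
) -> MultidimensionalFilterResult:
    """Keep genes explicitly associated with >= min_terms interrogation terms.

    Both matrices must share the term list.  Kept genes are labelled
    ``case-unique`` / ``control-unique`` / ``common`` according to which
    condition's matrix they pass in (the heatmap red/blue/yellow coding);
    per-term counts of unique passing genes are reported alongside.
    """
    terms = case_scores.terms
    if control_scores.terms != terms:
        raise ValueError("case and control matrices use different term lists")
    if min_terms > len(terms):
        raise ValueError(f"min_terms={min_terms} exceeds {len(terms)} interrogation terms")

    def passing(m: LsiScoreMatrix) -> dict[str, pd.Series]:
        expl = m.scores >= threshold
        keep = expl.sum(axis=1) >= min_terms
        return {g: m.scores.loc[g] for g in m.scores.index[keep]}

    case_pass = passing(case_scores)
    ctrl_pass = passing(control_scores)
    rows = []
    for gene in sorted(set(case_pass) | set(ctrl_pass)):
        in_case, in_ctrl = gene in case_pass, gene in ctrl_pass
        label = "common" if (in_case and in_ctrl) else ("case-unique" if in_case else "control-unique")
        sc = case_pass.get(gene, ctrl_pass.get(gene))
        rows.append({"gene": gene, "label": label,
                     "n_explicit_terms": int((sc >= threshold).sum()),
                     **{t: sc[t] for t in terms}})
    kept = pd.DataFrame(rows, columns=["gene", "label", "n_explicit_terms", *terms])

    counts = []
    for t in terms:
        cu = sum(1 for g, sc in case_pass.items() if g not in ctrl_pass and sc[t] >= threshold)
        ku = sum(1 for g, sc in ctrl_pass.items() if g not in case_pass and sc[t] >= threshold)
        counts.append((t, cu, ku))
    per_term = pd.DataFrame(counts, columns=["term", "case_unique", "control_unique"])
    return MultidimensionalFilterResult(kept=kept, per_term_unique_counts=per_term)


def cumulative_score(
    scores: LsiScoreMatrix, term: str, genes: Iterable[str] | None = None
) -> float:
    """Sum of explicit (>= threshold) scores for one term over the given genes."""
    if term not in scores.scores.columns:
        raise ValueError(f"unknown term {term!r}; known: {', '.join(scores.terms)}")
    col = scores.scores[term]
    if genes is not None:
        genes = [g for g in genes if g in col.index]
        col = col.loc[genes]
    col = col[col >= scores.threshold]
    return float(col.sum())
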