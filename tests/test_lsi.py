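import numpy as np
import pandas as pd
import pytest

from raftomics.core import AliasMap
from raftomics.lsi import (
    Corpus,
    LsiScoreMatrix,
    build_index,
    cumulative_score,
    gene_term_score,
    map_genes_to_documents,
    multidimensional_filter,
    score_matrix,
    tokenize,
)


def weighted_matrix(corpus, weighting="log-entropy"):
    """Independent oracle: rebuild the weighted term-document matrix directly."""
    vocab = corpus.vocabulary()
    vi = {t: i for i, t in enumerate(vocab)}
    tf = np.zeros((len(vocab), len(corpus.documents)))
    for j, (_, text) in enumerate(corpus.documents):
        for tok in tokenize(text, corpus.stopwords):
            tf[vi[tok], j] += 1
    n = tf.shape[1]
    if weighting == "log-entropy":
        gf = tf.sum(axis=1, keepdims=True)
        p = np.divide(tf, gf, out=np.zeros_like(tf), where=gf > 0)
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        g = np.clip(1.0 + plogp.sum(axis=1) / np.log2(n), 0, 1)
        return g[:, None] * np.log2(1 + tf), vocab, g
    raise NotImplementedError


TOY_DOCS = [
    ("d1", "fyn phosphorylates tau in neurons"),
    ("d2", "fyn kinase regulates synaptic signaling"),
    ("d3", "oxidation damages mitochondria badly"),
    ("d4", "oxidation stress alters mitochondria"),
    ("d5", "ribosome translation elongation factor"),
]


class TestCorpusAndTokenize:
    def test_tokenize_drops_short_and_stopwords(self):
        assert tokenize("The Fyn-kinase, a tau!", frozenset({"the"})) == ["fyn", "kinase", "tau"]

    def test_duplicate_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            Corpus(documents=[("d1", "a b"), ("d1", "c d")])

    def test_jsonl_roundtrip(self, tmp_path):
        c = Corpus(documents=TOY_DOCS)
        c.to_jsonl(tmp_path / "c.jsonl")
        c2 = Corpus.from_jsonl(tmp_path / "c.jsonl")
        assert c2.documents == c.documents


class TestBuildIndex:
    def test_full_rank_reconstructs_weighted_matrix(self):
        corpus = Corpus(documents=TOY_DOCS)
        model = build_index(corpus, k=10**6)
        A, vocab, _ = weighted_matrix(corpus)
        assert model.vocabulary == vocab
        recon = model.term_factors @ model.doc_coords
        assert np.max(np.abs(recon - A)) < 1e-8

    def test_singular_values_positive_nonincreasing(self):
        model = build_index(Corpus(documents=TOY_DOCS), k=4)
        sv = model.singular_values
        assert np.all(sv > 0) and np.all(np.diff(sv) <= 1e-12)

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            build_index(Corpus(documents=TOY_DOCS), k=0)

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            build_index(Corpus(documents=[("d1", "a")]), k=2)  # all tokens too short

    def test_two_topic_blocks_separate_at_k2(self):
        """Docs of one topic block stay mutually closer than cross-block
        pairs in the rank-2 space (brute-force cosine on coordinates)."""
        block_a = [(f"a{i}", "kinase signaling receptor phosphorylation") for i in range(3)]
        block_b = [(f"b{i}", "glycolysis pyruvate metabolism mitochondria") for i in range(3)]
        model = build_index(Corpus(documents=block_a + block_b), k=2)
        X = model.doc_coords
        cos = lambda u, v: float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        within = cos(X[:, 0], X[:, 1])
        across = cos(X[:, 0], X[:, 3])
        assert within > across


class TestGeneDocumentMapping:
    def test_whole_word_match(self):
        corpus = Corpus(documents=[("d1", "Fyn phosphorylates tau")])
        assert map_genes_to_documents(corpus, ["FYN"])["FYN"] == {"d1"}

    def test_substring_is_not_a_match(self):
        corpus = Corpus(documents=[("d1", "IGF1R signaling")])
        assert map_genes_to_documents(corpus, ["IGF1"])["IGF1"] == set()

    def test_alias_synonym_links(self):
        corpus = Corpus(documents=[("d1", "frap1 complex activity")])
        amap = AliasMap({"FRAP1": "MTOR"})
        assert map_genes_to_documents(corpus, ["MTOR"], amap)["MTOR"] == {"d1"}

    def test_zero_document_gene_flagged_empty(self):
        corpus = Corpus(documents=TOY_DOCS)
        assert map_genes_to_documents(corpus, ["ABSENT1"])["ABSENT1"] == set()


class TestGeneTermScore:
    def _model(self, k=10**6):
        corpus = Corpus(documents=TOY_DOCS)
        model = build_index(corpus, k=k)
        model.gene_doc_map = map_genes_to_documents(corpus, ["FYN", "ABSENT1"])
        return corpus, model

    def test_full_rank_equals_direct_cosine(self):
        """Untruncated oracle: cosine between the fold-in query and the
        gene's document centroid on the raw weighted matrix."""
        corpus, model = self._model()
        A, vocab, g = weighted_matrix(corpus)
        di = {d: j for j, (d, _) in enumerate(corpus.documents)}
        centroid = A[:, [di[d] for d in model.gene_doc_map["FYN"]]].mean(axis=1)
        for term in ("tau", "synaptic signaling", "oxidation"):
            toks = [t for t in tokenize(term) if t in vocab]
            q = np.zeros(len(vocab))
            for t in toks:
                q[vocab.index(t)] += g[vocab.index(t)] * np.log2(2.0)
            q /= len(toks)
            direct = float(q @ centroid / (np.linalg.norm(q) * np.linalg.norm(centroid)))
            assert gene_term_score(model, "FYN", term) == pytest.approx(direct, abs=1e-8)

    def test_score_bounded_by_one(self):
        _, model = self._model(k=2)
        for term in ("tau", "oxidation", "mitochondria"):
            assert abs(gene_term_score(model, "FYN", term)) <= 1.0 + 1e-12

    def test_gene_without_documents_gets_nan_sentinel(self):
        _, model = self._model()
        assert np.isnan(gene_term_score(model, "ABSENT1", "tau"))

    def test_out_of_vocabulary_term_is_error(self):
        _, model = self._model()
        with pytest.raises(ValueError):
            gene_term_score(model, "FYN", "zz9qx7")

    def test_invariant_to_document_order(self):
        docs = list(TOY_DOCS)
        m1 = build_index(Corpus(documents=docs), k=3)
        m2 = build_index(Corpus(documents=docs[::-1]), k=3)
        for m in (m1, m2):
            m.gene_doc_map = {"FYN": {"d1", "d2"}}
        assert gene_term_score(m1, "FYN", "tau") == pytest.approx(
            gene_term_score(m2, "FYN", "tau"), abs=1e-9
        )


def _mat(rows, terms, threshold=0.1):
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=terms)
    scores = scores.astype(float)
    explicit = scores >= threshold
    return LsiScoreMatrix(scores=scores, threshold=threshold, explicit=explicit,
                          implicit=explicit & False)


class TestMultidimensionalFilter:
    TERMS = ["alzheimer", "oxidation", "gpcr"]

    def test_two_term_rule(self):
        case = _mat({"KEEP": [0.25, 0.15, 0.0], "DROP": [0.9, 0.05, 0.0]}, self.TERMS)
        ctrl = _mat({}, self.TERMS)
        res = multidimensional_filter(case, ctrl)
        assert list(res.kept["gene"]) == ["KEEP"]
        assert list(res.kept["label"]) == ["case-unique"]

    def test_threshold_inclusive(self):
        case = _mat({"EDGE": [0.1, 0.1, 0.0]}, self.TERMS)
        res = multidimensional_filter(case, _mat({}, self.TERMS))
        assert list(res.kept["gene"]) == ["EDGE"]

    def test_common_and_unique_labels_and_counts(self):
        case = _mat({"BOTH": [0.3, 0.3, 0.0], "CASEONLY": [0.2, 0.2, 0.0]}, self.TERMS)
        ctrl = _mat({"BOTH": [0.3, 0.3, 0.0], "CTRLONLY": [0.0, 0.4, 0.4]}, self.TERMS)
        res = multidimensional_filter(case, ctrl)
        labels = dict(zip(res.kept["gene"], res.kept["label"]))
        assert labels == {"BOTH": "common", "CASEONLY": "case-unique", "CTRLONLY": "control-unique"}
        counts = res.per_term_unique_counts.set_index("term")
        assert counts.loc["alzheimer", "case_unique"] == 1
        assert counts.loc["gpcr", "control_unique"] == 1

    def test_min_terms_above_term_count_is_error(self):
        m = _mat({"A": [0.2, 0.2, 0.2]}, self.TERMS)
        with pytest.raises(ValueError):
            multidimensional_filter(m, m, min_terms=4)


class TestCumulativeScore:
    def test_sum_of_explicit_scores(self):
        m = _mat({"A": [0.5, 0, 0], "B": [0.4, 0, 0], "C": [0.3, 0, 0], "D": [0.05, 0, 0]},
                 ["alzheimer", "oxidation", "gpcr"])
        assert cumulative_score(m, "alzheimer") == pytest.approx(1.2)

    def test_no_explicit_genes_gives_zero(self):
        m = _mat({"A": [0.01, 0, 0]}, ["alzheimer", "oxidation", "gpcr"])
        assert cumulative_score(m, "alzheimer") == 0.0

    def test_unknown_term_is_error(self):
        m = _mat({"A": [0.5, 0, 0]}, ["alzheimer", "oxidation", "gpcr"])
        with pytest.raises(ValueError):
            cumulative_score(m, "prion")

    def test_gene_subset_restriction(self):
        m = _mat({"A": [0.5, 0, 0], "B": [0.4, 0, 0]}, ["alzheimer", "oxidation", "gpcr"])
        assert cumulative_score(m, "alzheimer", genes={"A"}) == pytest.approx(0.5)


class TestScoreMatrixFlags:
    def test_explicit_and_implicit_flags(self):
        """A gene co-occurring with a term is explicit-but-not-implicit; an
        association arising only through latent structure is implicit."""
        docs = [
            ("d1", "fyn tau alzheimer memory decline"),
            ("d2", "fyn tau synapse kinase"),
            ("d3", "mapt tau alzheimer tangles pathology"),
            ("d4", "mapt tau tangles neurons"),
        ]
        corpus = Corpus(documents=docs)
        model = build_index(corpus, k=2)
        model.gene_doc_map = map_genes_to_documents(corpus, ["FYN", "MAPT"])
        mat = score_matrix(model, ["FYN", "MAPT"], terms=["alzheimer"], threshold=0.1)
        assert bool(mat.explicit.loc["FYN", "alzheimer"])
        assert not bool(mat.implicit.loc["FYN", "alzheimer"])  # co-occurs in d1
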