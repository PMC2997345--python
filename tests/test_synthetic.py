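import dataclasses

import numpy as np
import pytest

from raftomics.filtering import consensus_set, filter_identifications
from raftomics.sets import overlap_stats
from raftomics.synthetic import (
    SyntheticConfig,
    make_band_image,
    make_condition_sets,
    make_corpus,
    make_gene_sets,
    make_spectral_counts,
    shared_core_size,
)


class TestConditionSets:
    def test_receptor_scale_construction_gives_printed_commonality(self):
        """Sizes (47, 30) at target 0.116 realize 8 shared / union 69 -> 11.6%."""
        assert shared_core_size(47, 30, 0.116) == 8
        cfg = SyntheticConfig(seed=0, universe_size=100, control_size=47,
                              case_size=30, target_commonality=0.116)
        cs = make_condition_sets(cfg)
        ov = overlap_stats(cs.truth.control_symbols, cs.truth.case_symbols)
        assert (ov.common, ov.union_size, ov.rounded_percent()) == (8, 69, 11.6)

    def test_full_commonality_identical_sets(self):
        cfg = SyntheticConfig(seed=0, universe_size=100, control_size=30,
                              case_size=30, target_commonality=1.0)
        cs = make_condition_sets(cfg)
        assert cs.truth.control_symbols == cs.truth.case_symbols

    def test_zero_commonality_disjoint_sets(self):
        cfg = SyntheticConfig(seed=0, universe_size=100, control_size=30,
                              case_size=30, target_commonality=0.0)
        cs = make_condition_sets(cfg)
        assert not (cs.truth.control_symbols & cs.truth.case_symbols)

    def test_infeasible_target_reports_range(self):
        with pytest.raises(ValueError, match="feasible"):
            cfg = SyntheticConfig(seed=0, universe_size=100, control_size=10,
                                  case_size=50, target_commonality=0.9)
            make_condition_sets(cfg)

    def test_pipeline_reproduces_intended_sets(self, condition_sets):
        """Running the real filter + consensus on the emitted records recovers
        the planted consensus sets exactly."""
        kept = filter_identifications(condition_sets.records)
        for cond, want in (("control", condition_sets.truth.control_symbols),
                           ("case", condition_sets.truth.case_symbols)):
            assert consensus_set(kept, cond).consensus_symbols == want

    def test_filters_are_actually_exercised(self, condition_sets):
        kept = filter_identifications(condition_sets.records)
        assert len(kept) < len(condition_sets.records)  # decoys got rejected


class TestDeterminism:
    def test_same_config_byte_identical_outputs(self):
        cfg = SyntheticConfig(seed=7)
        a, b = make_condition_sets(cfg), make_condition_sets(cfg)
        assert a.records == b.records
        ca, _ = make_corpus(cfg)
        cb, _ = make_corpus(cfg)
        assert ca.documents == cb.documents
        ia, _ = make_band_image(cfg)
        ib, _ = make_band_image(cfg)
        assert np.array_equal(ia, ib)

    def test_streams_independent_of_each_other(self):
        """Generating the corpus does not perturb the band image stream."""
        cfg = SyntheticConfig(seed=7)
        img_alone, _ = make_band_image(cfg)
        make_corpus(cfg)
        img_after, _ = make_band_image(cfg)
        assert np.array_equal(img_alone, img_after)

    def test_different_seeds_differ(self):
        a = make_condition_sets(SyntheticConfig(seed=1))
        b = make_condition_sets(SyntheticConfig(seed=2))
        assert a.truth.control_symbols != b.truth.control_symbols


class TestGeneSets:
    def test_planted_sets_lean_on_target_condition(self, condition_sets):
        cfg = SyntheticConfig(seed=1)
        coll, truth = make_gene_sets(cfg, condition_sets)
        case_unique = condition_sets.truth.case_symbols - condition_sets.truth.control_symbols
        for gs in coll.sets:
            if truth.planted_signs.get(gs.name) == +1:
                frac = len(gs.members & case_unique) / len(gs.members)
                assert frac >= 0.5  # strength 0.8 in expectation

    def test_strength_bounds_enforced(self, condition_sets):
        cfg = dataclasses.replace(SyntheticConfig(seed=1), planted_strength=1.5)
        with pytest.raises(ValueError):
            make_gene_sets(cfg, condition_sets)

    def test_members_within_universe(self, condition_sets):
        coll, _ = make_gene_sets(SyntheticConfig(seed=1), condition_sets)
        for gs in coll.sets:
            assert gs.members <= coll.universe


class TestCorpus:
    def test_planted_pairs_cooccur_in_required_documents(self):
        cfg = SyntheticConfig(seed=3)
        corpus, truth = make_corpus(cfg)
        text_by_doc = dict(corpus.documents)
        for gene, term in truth.planted_pairs:
            term_tok = term.lower().split()[0].replace("'s", "")
            n_co = sum(
                1 for text in text_by_doc.values()
                if gene.lower() in text.split() and term_tok in text
            )
            assert n_co >= cfg.cooccur_docs

    def test_zero_documents_is_error(self):
        with pytest.raises(ValueError):
            make_corpus(dataclasses.replace(SyntheticConfig(seed=0), corpus_docs=0))

    def test_oversubscribed_corpus_is_error(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=0), corpus_docs=30)
        with pytest.raises(ValueError):
            make_corpus(cfg)


class TestSpectralCounts:
    def test_counts_written_back_to_datasets(self, condition_sets):
        cfg = SyntheticConfig(seed=1)
        table, truth = make_spectral_counts(cfg, condition_sets)
        shared = condition_sets.truth.shared
        assert set(table["symbol"]) == shared
        some = next(iter(shared))
        reps = table[(table["symbol"] == some) & (table["condition"] == "case")]
        assert condition_sets.case.spectral_counts[some] == reps["spectral_count"].sum()

    def test_nonpositive_lambda_is_error(self, condition_sets):
        cfg = dataclasses.replace(SyntheticConfig(seed=1), poisson_lambda=0.0)
        with pytest.raises(ValueError):
            make_spectral_counts(cfg, condition_sets)


class TestBandImage:
    def test_zero_amplitude_measures_noise_only(self):
        cfg = SyntheticConfig(seed=2, image_noise_sd=0.005)
        img, truth = make_band_image(cfg, amplitude=0.0)
        from raftomics.densitometry import quantify_band

        m = quantify_band(img, (30, 20, 50, 40), (0, 0, 10, 10))
        assert abs(m.au_per_px2) < 0.01

    def test_amplitude_ordering_preserved(self):
        cfg = SyntheticConfig(seed=2)
        from raftomics.densitometry import quantify_band

        vals = []
        for amp in (0.2, 0.5):
            img, t = make_band_image(cfg, amplitude=amp)
            cx, cy = int(t.center[0]), int(t.center[1])
            vals.append(quantify_band(img, (cx - 10, cy - 10, cx + 11, cy + 11), (0, 0, 8, 8)).au_per_px2)
        assert vals[0] < vals[1]

    def test_nonpositive_sigma_is_error(self):
        cfg = dataclasses.replace(SyntheticConfig(seed=0), band_sigma=0.0)
        with pytest.raises(ValueError):
            make_band_image(cfg)
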