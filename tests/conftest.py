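import pytest
from hypothesis import settings

from raftomics.core import AliasMap, ProteinIdentification

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from raftomics.synthetic import SyntheticConfig, make_condition_sets


@pytest.fixture(scope="session")
def alias_map() -> AliasMap:
    return AliasMap({"FRAP1": "MTOR", "PYK2": "PTK2B", "FAK": "PTK2"})


def _rec(symbol, peptides, score, conf, replicate, condition="control", spectral=5):
    return ProteinIdentification(
        symbol=symbol, accession=f"ACC_{symbol}", peptide_count=peptides,
        id_score=score, confidence=conf, spectral_count=spectral,
        replicate_id=replicate, condition=condition,
    )


@pytest.fixture(scope="session")
def boundary_records() -> list[ProteinIdentification]:
    """Twelve hand-written records spanning every filter boundary.

    GOOD2 passes in exactly 2 of 3 animals (kept by consensus); GOOD3 in
    all 3; EDGE sits exactly on every inclusive threshold; ONEREP passes
    the identification filter but only in one animal; the rest each fail
    one identification criterion.
    """
    return [
        _rec("GOOD2", 3, 40.0, 0.99, "A"),          # 1 pass, replicate A
        _rec("GOOD2", 2, 30.0, 0.97, "B"),          # 2 pass, replicate B
        _rec("GOOD3", 4, 50.0, 0.99, "A"),          # 3 pass
        _rec("GOOD3", 2, 26.0, 0.96, "B"),          # 4 pass
        _rec("GOOD3", 2, 25.5, 0.98, "C"),          # 5 pass
        _rec("EDGE", 2, 25.0, 0.95, "A"),           # 6 pass: all boundaries inclusive
        _rec("EDGE", 2, 25.0, 0.95, "B"),           # 7 pass
        _rec("ONEREP", 5, 60.0, 0.99, "A"),         # 8 pass, but single replicate
        _rec("LOWPEP", 1, 40.0, 0.99, "A"),         # 9 fail: one peptide
        _rec("LOWPEP", 1, 45.0, 0.99, "B"),         # 10 fail: one peptide
        _rec("LOWSCORE", 3, 24.9, 0.99, "A"),       # 11 fail: score below 25
        _rec("LOWCONF", 3, 30.0, 0.90, "A"),        # 12 fail: confidence below 95%
    ]


@pytest.fixture(scope="session")
def condition_sets():
    """Default synthetic study (seed 1), shared across the suite."""
    return make_condition_sets(SyntheticConfig(seed=1))
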