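import pytest
from hypothesis import HealthCheck, settings

import truncguide as tg

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The bundled on/off-target benchmark table, parsed."""
    df = tg.load_table1()
    tg.validate_table1(df)
    return df


@pytest.fixture(scope="session")
def table1_annotated(table1):
    return tg.annotate_table1_mismatches(table1).set_index("target_id")


@pytest.fixture(scope="session")
def amplicon():
    """A synthetic 240 nt reference amplicon with the cut site at 120."""
    return tg.random_dna(240, seed=20160624)


ON_TARGET_PAIRS = [
    ("sgGFP42-On", "GCCGTCCAGCTCGACCAGGA", "GTCCAGCTCGACCAGGA", "TGG"),
    ("sgGFP101-On", "GGCGAGGGCGATGCCACCTA", "GAGGGCGATGCCACCTA", "AGG"),
    ("sgGFP261-On", "GACGTAGCCTTCGGGCATGG", "GTAGCCTTCGGGCATGG", "CGG"),
    ("sgGFP379-On", "GAAGGGCATCGACTTCAAGG", "GGGCATCGACTTCAAGG", "AGG"),
]
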