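import pytest

from protstab import AlignmentSet, VariantRecord
from protstab.mutations import parse_mutation
from protstab.variants import load_half_life_table

#: The 14 first-generation library substitutions (11 positions, duplicates
#: at 40, 85 and 200), reconstructed from the half-life table.
LIBRARY_SUBSTITUTIONS = (
    "T35S", "Q40L", "Q40M", "E41Q", "S43P", "A46S", "Q84P",
    "Q85R", "Q85K", "C102S", "S106T", "S185C", "V200L", "V200A",
)


@pytest.fixture(scope="session")
def library_candidates():
    return tuple(parse_mutation(s) for s in LIBRARY_SUBSTITUTIONS)


@pytest.fixture(scope="session")
def background():
    return parse_mutation("Y109H")


@pytest.fixture(scope="session")
def half_life_records():
    return load_half_life_table()


@pytest.fixture(scope="session")
def first_generation(half_life_records):
    """First-generation library rows plus the parent (model training set)."""
    return [
        r for r in half_life_records if r.group in ("gen1", "parent")
    ]


@pytest.fixture
def toy_alignment():
    """Small hand-built ungapped alignment: seed plus four homologs.

    Column 2 (0-based 1) varies Q/R/K; column 5 (0-based 4) varies D/E and
    co-varies with column 2 (R pairs with E).
    """
    return AlignmentSet(
        seed_id="seed",
        sequences=[
            ("seed", "MQAKDLFG"),
            ("h1", "MRAKELFG"),
            ("h2", "MRAKELFG"),
            ("h3", "MQAKDLFG"),
            ("h4", "MKAKDLFG"),
        ],
    )
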