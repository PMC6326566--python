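import datetime as dt
from pathlib import Path

import pytest

import odofuzz as oz

DEMO_KB_PATH = Path(oz.__file__).parent / "data" / "demo_kb.yaml"


def d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


@pytest.fixture(scope="session")
def demo_kb():
    return oz.load_knowledge_base(DEMO_KB_PATH)


@pytest.fixture(scope="session")
def toy_records():
    """Hand-made records over the demo knowledge base.

    Commonality: hawker 4/4 = 1.0, darter and bluet 2/4 = 0.5.
    Biotopes: hawker pond x3 + lake x1, darter pond x2, bluet brook x2.
    """
    R = oz.OccurrenceRecord
    return [
        R("demo_hawker", "male", d("2015-07-20"), 50.05, 14.05, 400.0, "pond", "1"),
        R("demo_hawker", "female", d("2016-07-10"), 50.05, 14.05, 350.0, "pond", "2-5"),
        R("demo_hawker", "male", d("2017-08-01"), 50.05, 14.25, 500.0, "pond", "1"),
        R("demo_hawker", "female", d("2018-07-05"), 49.55, 14.05, 300.0, "lake", "1"),
        R("demo_darter", "male", d("2015-08-15"), 50.05, 14.05, 250.0, "pond", "1"),
        R("demo_darter", "female", d("2016-08-20"), 50.05, 14.05, 200.0, "pond", "1"),
        R("demo_bluet", "male", d("2015-06-15"), 49.05, 15.05, 300.0, "brook", "1"),
        R("demo_bluet", "female", d("2016-06-20"), 49.05, 15.05, 350.0, "brook", "1"),
    ]


@pytest.fixture(scope="session")
def toy_model(demo_kb, toy_records):
    return oz.fit_model(demo_kb, toy_records)


@pytest.fixture(scope="session")
def synth_small():
    """Mid-sized synthetic world for property and equivalence tests."""
    cfg = oz.GeneratorConfig(n_species=20, n_records=3000, seed=5)
    kb = oz.generate_knowledge_base(cfg)
    records = oz.augment_colours(oz.generate_records(kb, cfg), kb, seed=6)
    model = oz.fit_model(kb, records)
    return cfg, kb, records, model


@pytest.fixture(scope="session")
def synth_full():
    """The full study conditions: 74 species, 20,000 augmented records."""
    cfg = oz.GeneratorConfig(seed=7)
    kb = oz.generate_knowledge_base(cfg)
    records = oz.augment_colours(oz.generate_records(kb, cfg), kb, seed=9)
    return cfg, kb, records
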