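import json
from pathlib import Path

import pytest

from phagenn.ensemble import NetworkConfig, cross_validate
from phagenn.features import get_schema
from phagenn.homology_split import SplitConfig, build_split
from phagenn.seqio import ClassList
from phagenn.synthetic import SyntheticConfig, generate_corpus, generate_worked_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_fixture():
    """The 36-sequence deterministic corpus with frozen expectations."""
    corpora, truth = generate_worked_fixture()
    return corpora, truth


@pytest.fixture(scope="session")
def worked_expected():
    with open(DATA_DIR / "worked_fixture_expected.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def tiny_pipeline():
    """A small trained pipeline shared across scoring/CLI-level tests:
    4 classes (3 signal + background), 11 families x 2 members each,
    short sequences, a narrow network. Quality is not asserted here —
    it exists to exercise the full data path cheaply."""
    config = SyntheticConfig(
        n_classes=4,
        families_per_class=11,
        members_per_family=2,
        length_range=(60, 150),
        rng_seed=42,
    )
    corpora, truth = generate_corpus(config)
    classes = ClassList(config.resolved_class_names())
    others = corpora.pop("others")
    split = build_split(corpora, others, SplitConfig(rng_seed=5))
    records = {r.id: r for recs in list(corpora.values()) + [others] for r in recs}
    schema = get_schema("di_sc_p")
    net_config = NetworkConfig(
        n_features=schema.total_dim,
        n_classes=len(classes),
        hidden_width=24,
        max_epochs=40,
        rng_seed=1,
    )
    ensemble = cross_validate(split, records, schema, classes, net_config)
    return {
        "classes": classes,
        "records": records,
        "truth": truth,
        "split": split,
        "schema": schema,
        "ensemble": ensemble,
    }
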