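import pytest

from hicnet import io, synth
from hicnet.model import MultiExperimentGraph

TIMEPOINT_EXPERIMENTS = ("T0_Rep1", "T_16_Rep1", "T_32_Rep1")


@pytest.fixture
def fig1_store():
    """Two genes linked by one contact under each of three experiments."""
    store = MultiExperimentGraph()
    store.upsert_gene("AADACL3", "chr1", 12776118, 12788726)
    store.upsert_gene("AADACL4", "chr1", 12704565, 12727097)
    for name in TIMEPOINT_EXPERIMENTS:
        store.add_contact(name, "AADACL3", "AADACL4", 3, 0.8)
    return store


@pytest.fixture
def star_store():
    """Star around A: A-B w=1, A-C w=2, A-D w=3 in experiment 'exp1'."""
    store = MultiExperimentGraph()
    for i, s in enumerate("ABCD"):
        store.upsert_gene(s, "chr1", 1000 * i, 1000 * i + 500)
    store.add_contact("exp1", "A", "B", 1, 0.9)
    store.add_contact("exp1", "A", "C", 2, 0.8)
    store.add_contact("exp1", "A", "D", 3, 0.7)
    return store


def store_from_records(named_records):
    """Build a store from {experiment: [ContactRecord, ...]}."""
    store = MultiExperimentGraph()
    for name, records in named_records.items():
        io.load_contacts_into_store(store, name, records)
    return store


@pytest.fixture
def synth_store():
    """Small synthetic base experiment plus two rewired pseudo-replicates."""
    cfg = synth.SynthConfig(n_genes=60, n_chromosomes=3, seed=11)
    base, _genes = synth.generate_experiment(cfg)
    return store_from_records({
        "T0_Rep1": base,
        "T_16_Rep1": synth.perturb_experiment(base, 0.2, seed=12),
        "T_32_Rep1": synth.perturb_experiment(base, 0.2, seed=13),
    })
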