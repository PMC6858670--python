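import numpy as np
import pandas as pd
import pytest

from codaplot.io import CountTable, MetadataTable
from codaplot.synthgen import SynthSpec, generate_counts


@pytest.fixture
def plain_table_file(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text(
        "feature_id\tS1\tS2\n"
        "gene1\t10\t0\n"
        "gene2\t5\t5\n"
        "gene3\t100\t1\n"
    )
    return p


@pytest.fixture
def taxonomy_table_file(tmp_path):
    p = tmp_path / "counts_tax.tsv"
    p.write_text(
        "feature_id\tS1\tS2\ttaxonomy\n"
        "otu1\t10\t0\tk__Bacteria;p__Firmicutes\n"
        "otu2\t5\t5\tk__Bacteria;p__Actinobacteria\n"
        "otu3\t100\t1\tk__Archaea;p__Euryarchaeota\n"
    )
    return p


@pytest.fixture
def goslim_table_file(tmp_path):
    p = tmp_path / "counts_go.tsv"
    p.write_text(
        "go_id\tdescription\tcategory\tS1\tS2\n"
        "GO:0008150\tbiological process\tbiological_process\t40\t7\n"
        "GO:0003674\tmolecular function\tmolecular_function\t60\t93\n"
    )
    return p


@pytest.fixture
def metadata_file(tmp_path):
    p = tmp_path / "meta.tsv"
    p.write_text(
        "sample_id\tbv\tph\n"
        "S1\tpositive\t4.2\n"
        "S2\tnegative\t5.0\n"
    )
    return p


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[10, 0, 0], [5, 5, 5], [100, 100, 1]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3"],
    )
    return CountTable(counts)


@pytest.fixture
def small_metadata():
    data = pd.DataFrame(
        {
            "bv": ["positive", "negative", "positive", "negative"],
            "ph": [4.0, 4.5, 5.0, 5.5],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return MetadataTable(data)


@pytest.fixture(scope="session")
def synth_spiked():
    """A spiked two-group synthetic table shared across tests."""
    ids = SynthSpec().feature_ids()
    rng = np.random.default_rng(42)
    spikes = tuple(sorted(rng.choice(ids, 10, replace=False)))
    spec = SynthSpec(spike_ids=spikes, fold_change=8.0, seed=7)
    table, metadata, truth = generate_counts(spec)
    return table, metadata, truth
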