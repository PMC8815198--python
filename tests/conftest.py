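import pytest

from apoeqc import adjudicate as adj
from apoeqc.simulate import default_config, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest multi-cohort dataset under the standard study conditions."""
    return simulate_dataset(default_config(seed=42, n_total=1500))


@pytest.fixture(scope="session")
def small_subjects(small_dataset):
    """Harmonized subjects from the small dataset, before adjudication."""
    ds = small_dataset
    samples = adj.build_sample_table(ds.manifest, ds.vcf_calls, ds.dosages)
    return adj.harmonize_duplicates(samples, ds.dup_pairs)
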