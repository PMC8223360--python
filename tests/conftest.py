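import numpy as np
import pytest

from mlocmrna import DEFAULT_LOCALIZATIONS
from mlocmrna.io import LocalizationCatalog, LocalizedDataset, SequenceRecord
from mlocmrna.simulate import SyntheticConfig, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Planted-signal corpus: 9 locations x 40 records, high enrichment."""
    cfg = SyntheticConfig(counts={n: 40 for n in DEFAULT_LOCALIZATIONS}, seed=7)
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Hand-built 3-location dataset for I/O-level tests."""
    catalog = LocalizationCatalog(("nucleus", "cytoplasm", "ribosome"))
    rng = np.random.default_rng(0)
    records = []
    for i, loc in enumerate(["nucleus"] * 4 + ["cytoplasm"] * 4 + ["ribosome"] * 4):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        records.append(SequenceRecord(f"r{i}", seq, frozenset({loc})))
    return LocalizedDataset(records, catalog)
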