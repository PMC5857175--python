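import numpy as np
import pytest
from hypothesis import settings

from absquant.tables import FeatureTable, TaxonLineage

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Spike-in validation series: marker-gene qPCR quantities (copies/g dry soil)
# for the six addition levels, highest to lowest, and the nominal additions
# they correspond to (1 mL of 2.1e11..2.1e6 CFU/mL into 30 g soil).
MARKER_QPCR = (4.79e9, 5.96e8, 5.28e7, 5.70e6, 5.65e5, 8.11e4)
NOMINAL_ADDED = (7.0e9, 7.0e8, 7.0e7, 7.0e6, 7.0e5, 7.0e4)
TREATMENT_IDS = ("E9", "E8", "E7", "E6", "E5", "E4")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def lineage(*names):
    padded = tuple(names) + (None,) * (6 - len(names))
    return TaxonLineage(padded)


@pytest.fixture
def small_table():
    """2 samples x 3 taxa with counts S1=(2,5,1), S2=(3,0,7)."""
    taxa = (
        lineage("Bacteria", "Proteobacteria", "Gamma", "Ord1", "Fam1", "GenusA"),
        lineage("Bacteria", "Proteobacteria", "Gamma", "Ord1", "Fam2", "GenusB"),
        lineage("Bacteria", "Firmicutes", "Bacilli", "Ord2", "Fam3", "GenusC"),
    )
    counts = np.array([[2, 5, 1], [3, 0, 7]])
    return FeatureTable(("S1", "S2"), taxa, counts)


def random_feature_table(rng, n_samples=4, n_taxa=20, max_count=500):
    phyla = ["P1", "P2", "P3"]
    taxa = tuple(
        lineage("Bacteria", phyla[i % 3], f"C{i % 4}", f"O{i % 5}",
                f"F{i % 6}", f"G{i:02d}")
        for i in range(n_taxa)
    )
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # ensure positive sample totals
    samples = tuple(f"S{i}" for i in range(n_samples))
    return FeatureTable(samples, taxa, counts)
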