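import numpy as np
import pandas as pd
import pytest

from commtype.simulate import (
    CohortSpec,
    generate_counts,
    three_cluster_preset,
)
from commtype.tables import TaxaCountTable


@pytest.fixture
def toy_counts() -> TaxaCountTable:
    """3 samples x 4 taxa with lineages (two species share a genus)."""
    counts = pd.DataFrame(
        [[3, 4, 10, 0], [1, 0, 5, 2], [7, 2, 0, 1]],
        index=pd.Index(["A", "B", "C"], name="sample_id"),
        columns=["sp1", "sp2", "sp3", "sp4"],
    )
    lineage = pd.Series(
        {
            "sp1": "k__Bacteria;p__Bacteroidota;c__;o__;f__;g__Bacteroides;s__x",
            "sp2": "k__Bacteria;p__Bacteroidota;c__;o__;f__;g__Bacteroides;s__y",
            "sp3": "k__Bacteria;p__Bacteroidota;c__;o__;f__;g__Prevotella;s__z",
            "sp4": "k__Bacteria;p__Firmicutes;c__;o__;f__;;s__w",
        }
    )
    return TaxaCountTable(counts, lineage)


@pytest.fixture(scope="session")
def two_component_cohort():
    """Well-separated 2-component DM cohort with ground truth."""
    rng = np.random.default_rng(0)
    G = 20
    a1 = 0.1 + 0.1 * rng.random(G)
    a1[0] += 15.0
    a2 = 0.1 + 0.1 * rng.random(G)
    a2[1] += 15.0
    spec = CohortSpec(
        n_samples=400,
        n_genera=G,
        K_true=2,
        mixing_weights=np.array([0.6, 0.4]),
        alpha_matrix=np.vstack([a1, a2]),
        depth_log_mean=float(np.log(5e3)),
        depth_log_sd=0.3,
        named_genus_indices={"Bacteroides": 0, "Prevotella": 1, "Clostridium": 2},
        seed=9,
    )
    counts, truth = generate_counts(spec)
    return spec, counts, truth


@pytest.fixture(scope="session")
def three_component_cohort():
    """The default well-separated 3-component preset (N=600, G=40)."""
    spec = three_cluster_preset(n_samples=600, n_genera=40, seed=1)
    counts, truth = generate_counts(spec)
    return spec, counts, truth
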