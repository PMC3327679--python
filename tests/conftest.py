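import numpy as np
import pytest

from triomics.io_tables import ExpressionMatrix, SampleMeta
from triomics.synthetic_data import SimConfig, generate


def make_matrix(values, layer="mRNA", conditions=None, feature_ids=None, dyes=None):
    """Small ExpressionMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if conditions is None:
        half = n_samp // 2
        conditions = ["sensitive"] * half + ["resistant"] * (n_samp - half)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    counters = {}
    samples = []
    for j, cond in enumerate(conditions):
        counters[cond] = counters.get(cond, 0) + 1
        samples.append(
            SampleMeta(
                name=f"s{j}",
                condition=cond,
                bio_rep=counters[cond],
                tech_rep=1,
                dye=dyes[j] if dyes else "none",
            )
        )
    return ExpressionMatrix(layer, feature_ids, samples, values)


SMALL_SIM = dict(
    n_genes=1500,
    n_mirnas=250,
    n_proteins=350,
    n_de_genes=150,
    n_de_mirnas=25,
    n_de_proteins=110,
    n_low_signal=40,
    n_decoy_targets=120,
    n_gene_gene_edges=60,
    loops_per_type={"A": 8, "B": 7, "C": 6, "unclassified": 2},
)


@pytest.fixture(scope="session")
def small_bundle():
    """One scaled-down synthetic study shared across tests."""
    return generate(SimConfig(seed=11, **SMALL_SIM))
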