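import numpy as np
import pytest

import connmkl as ck


@pytest.fixture(scope="session")
def small_cohort():
    """20-node, 12+12-subject cohort with a strong MD effect on 5 edges."""
    cfg = ck.make_reference_config(seed=11, n_per_group=(12, 12), n_nodes=20,
                                   density=0.3, n_affected=5, effect_md=2.5)
    return cfg, ck.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, cohort = small_cohort
    return ck.vectorize(cohort)


@pytest.fixture(scope="session")
def reference_run():
    """The seeded recovery condition: 40+40 subjects, 90 nodes, 12 affected
    edges with an MD-only 1.5 SD shift; one complete multi-kernel LOOCV."""
    cfg = ck.make_reference_config(seed=1)
    cohort = ck.generate_cohort(cfg)
    table = ck.vectorize(cohort)
    report = ck.loocv(table, C=1.0, count_or_fraction=0.0014,
                      kernel=ck.KernelSpec("linear"), selection="fscore",
                      mode="multi_kernel", seed=1)
    return cfg, table, report


def relabel(table, labels):
    """Same features, new labels (used by permutation tests)."""
    return ck.FeatureTable(
        features=table.features, labels=np.asarray(labels, dtype=int),
        subject_ids=table.subject_ids, n_nodes=table.n_nodes,
        node_labels=table.node_labels, provenance=table.provenance,
    )
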