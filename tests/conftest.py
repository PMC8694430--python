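import numpy as np
import pytest

import midgae as mg


@pytest.fixture(scope="session")
def planted():
    """The default planted fixture (60 miRNAs x 40 diseases, 4 clusters)."""
    return mg.make_fixture()


@pytest.fixture(scope="session")
def planted_sims(planted):
    """Sequence and semantic similarity matrices for the planted fixture."""
    sm1 = mg.sequence_similarity(planted.sequences)
    sd1 = mg.semantic_similarity(planted.dag, registry=planted.associations.diseases)
    return sm1, sd1


@pytest.fixture(scope="session")
def worked():
    return mg.make_worked_example()


@pytest.fixture(scope="session")
def tiny_subnetwork(worked):
    """A 5-node miRNA-based sub-network built from the worked example."""
    a = worked.associations
    sm2 = mg.gip_kernel(a, "miRNA")
    sd2 = mg.gip_kernel(a, "disease")
    sm = mg.integrate(mg.SimilarityMatrix(worked.sm1, a.mirnas, "sequence"), sm2)
    sd = mg.integrate(mg.SimilarityMatrix(worked.sd1, a.diseases, "semantic"), sd2)
    sub_m, _ = mg.build_both_subnetworks(sm, sd, a, tm=0.5, td=0.5)
    return sub_m


def random_associations(rng, nm, nd, p=0.3):
    """A random nonzero binary association matrix with generic registries."""
    values = (rng.random((nm, nd)) < p).astype(float)
    if values.sum() == 0:
        values[0, 0] = 1.0
    mirnas = mg.EntityRegistry.from_names("miRNA", [f"m{i}" for i in range(nm)])
    diseases = mg.EntityRegistry.from_names("disease", [f"d{j}" for j in range(nd)])
    return mg.AssociationMatrix(values=values, mirnas=mirnas, diseases=diseases)
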