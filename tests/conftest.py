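import numpy as np
import pytest

import gcsenet as g


@pytest.fixture(scope="session")
def tiny_ds():
    """Small synthetic dataset exercising every pipeline stage quickly."""
    return g.generate_hetnet(12, 30, 15, latent_dim=4, seed=7, knn_k=4,
                             dag_extra_edges=5, label_fraction=0.1)


@pytest.fixture(scope="session")
def study_ds():
    """The full-size study-condition dataset all end-to-end checks share."""
    return g.generate_hetnet(seed=42)


@pytest.fixture(scope="session")
def tiny_net(tiny_ds):
    return tiny_ds.hetnet


@pytest.fixture(scope="session")
def tiny_encoder(tiny_net):
    cfg = g.RunConfig(embed_dim=8, encoder_epochs=5, seed=3)
    params, trace = g.train_encoder(tiny_net, cfg)
    return params, trace, g.encode(tiny_net, params)


@pytest.fixture()
def worked_net():
    """Hand-built 3-disease / 2-gene / 2-miRNA network with known edges."""
    dd = g.SimilarityMatrix(("d1", "d2", "d3"),
                            np.array([[1.0, 0.6, 0.1],
                                      [0.6, 1.0, 0.3],
                                      [0.1, 0.3, 1.0]]))
    mm = g.SimilarityMatrix(("m1", "m2"), np.array([[1.0, 0.4], [0.4, 1.0]]))
    gg = [("g1", "g2", 0.9)]
    dg = [("d1", "g1", 1.0), ("d2", "g1", 1.0), ("d2", "g2", 1.0), ("d3", "g2", 1.0)]
    mg = [("m1", "g1", 1.0), ("m2", "g1", 1.0), ("m2", "g2", 1.0)]
    return g.build_hetnet(dd, mm, gg, dg, mg, k=1)
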