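import numpy as np
import pytest

import pbac


@pytest.fixture(scope="session")
def tiny_collection() -> pbac.PathwayCollection:
    return pbac.PathwayCollection(
        [
            pbac.Pathway("P1", "first", frozenset({"g1", "g2"})),
            pbac.Pathway("P2", "second", frozenset({"g3"})),
            pbac.Pathway("P3", "third", frozenset({"g2", "g3", "g4"})),
        ]
    )


@pytest.fixture(scope="session")
def small_synth() -> pbac.SynthDataset:
    """A small but learnable cohort for training-behaviour tests."""
    cfg = pbac.SynthConfig(
        n_samples=80,
        n_genes=120,
        n_pathways=20,
        pathway_size_range=(4, 10),
        n_driver_pathways=2,
        driver_pathway_size=8,
        delta=2.0,
        seed=7,
    )
    return pbac.generate(cfg)


@pytest.fixture(scope="session")
def fitted_small_model(small_synth):
    ds = small_synth
    mask = pbac.build_mask(ds.collection, ds.expression.gene_ids)
    model = pbac.make_variant(mask, seed=3)
    model, history = pbac.train(model, ds.expression, ds.labels, pbac.TrainingConfig(seed=3))
    return model


def hand_model(seed: int = 0):
    """A fully hand-parameterised 3-pathway model over 4 genes (P=3, H=2,
    C=1, K=2) with no standardization, for scalar-arithmetic oracles."""
    mask = pbac.MaskMatrix(
        ["A", "B", "C"],
        ["g1", "g2", "g3", "g4"],
        np.array(
            [
                [1.0, 1.0, 0.0, 0.0],
                [0.0, 1.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        ),
    )
    model = pbac.PBACModel.init(mask, latent_dim=2, conv_channels=1, seed=seed)
    model.params["W1"] = np.array([[0.5, -0.2], [0.1, 0.3], [-0.4, 0.2]])
    model.params["W2"] = np.array([[0.3, -0.1, 0.2], [0.4, 0.2, -0.3]])
    model.params["Wk"] = np.array([[0.2, 1.0, -0.5]])
    model.params["bk"] = np.array([0.1])
    model.params["Wf"] = np.array([[0.5, -0.5], [0.2, 0.1], [-0.3, 0.4]])
    model.params["bf"] = np.array([0.05, -0.05])
    model.standardizer = None
    return model
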