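import numpy as np
import pytest

import adenoconserv as ac


@pytest.fixture(scope="session")
def small_config():
    return ac.SynthConfig(
        n_genes=400,
        n_conserved_up=20,
        n_conserved_down=10,
        n_private_up=25,
        n_private_down=25,
        n_categories=20,
        n_planted_categories=4,
        category_size_range=(6, 12),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    omap = ac.generate_universe(small_config)
    annotation = ac.generate_annotation(small_config, omap)
    studies, truth = ac.generate_studies(small_config, omap, annotation)
    return omap, annotation, studies, truth


@pytest.fixture(scope="session")
def small_universe(small_dataset):
    omap, _, studies, _ = small_dataset
    return ac.link_universe(omap, {g: set(s.gene_ids) for g, s in studies.items()})


def identity_universe(n: int) -> ac.LinkedUniverse:
    """A linked universe of n anchors where every genus id equals the anchor."""
    anchors = [f"g{i:05d}" for i in range(n)]
    ident = {a: a for a in anchors}
    return ac.LinkedUniverse(
        anchors=frozenset(anchors),
        to_anchor={g: dict(ident) for g in ("mouse", "rat", "human")},
        from_anchor={g: dict(ident) for g in ("mouse", "rat", "human")},
    )


@pytest.fixture
def make_identity_universe():
    return identity_universe
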