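import warnings

import pytest

from stromarch import synthetic, zoning


@pytest.fixture(scope="session")
def seg_tissue():
    """Default small dense tissue with rendered image and spot grid."""
    return synthetic.generate_tissue(synthetic.segmentation_config(seed=0))


def zoned_tissue(cfg):
    tissue = synthetic.generate_tissue(cfg)
    boundary = zoning.detect_boundary(tissue.mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = zoning.assign_layers(tissue.cells, boundary)
    table = zoning.assign_zones(table, cfg.archetype, fr_width_um=cfg.fr_width_um)
    return tissue, boundary, table


@pytest.fixture(scope="session")
def frpos_zoned():
    """FR+ tissue with boundary, layers and zones attached."""
    return zoned_tissue(synthetic.frpos_config(seed=11))


@pytest.fixture(scope="session")
def frneg_zoned():
    """FR- tissue with boundary, layers and zones attached."""
    return zoned_tissue(synthetic.frneg_config(seed=12))
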