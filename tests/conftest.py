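import numpy as np
import pandas as pd
import pytest

import bkgating as bk


@pytest.fixture(scope="session")
def small_cfg():
    """A small synthetic study: fast enough for per-module tests."""
    return bk.SyntheticConfig(n_positions=60, n_mutations=150, seed=7, n_frames=60)


@pytest.fixture(scope="session")
def small_records(small_cfg):
    return bk.generate_mutation_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_curated(small_records):
    table, audit = bk.curate_dataset(small_records)
    return table


@pytest.fixture(scope="session")
def small_feature_matrix(small_cfg, small_records, small_curated):
    """Fully assembled (unpruned, unstandardized) matrix for the small study."""
    ids = small_curated["mutation"].tolist()
    tables = bk.generate_energy_tables(small_cfg, ids)
    dddg, missing = bk.dddg_matrix(tables, ids)
    assert not missing
    ens, spec = bk.generate_ensemble(small_cfg)
    dyn = bk.dynamic_feature_table(ens, [c[0] for c in spec.couplings])
    ann = bk.generate_annotations(small_cfg)
    fm, report = bk.assemble(dddg, dyn, ann, small_curated, allow_drop=True)
    assert len(report) == 0
    return fm


@pytest.fixture(scope="session")
def study():
    """The full-scale synthetic study: 473 labeled mutations, tetramer ensemble."""
    cfg = bk.SyntheticConfig(seed=1)
    records = bk.generate_mutation_dataset(cfg)
    table, _ = bk.curate_dataset(records)
    ids = table["mutation"].tolist()
    tables = bk.generate_energy_tables(cfg, ids)
    dddg, missing = bk.dddg_matrix(tables, ids)
    assert not missing
    ens, spec = bk.generate_ensemble(cfg)
    dyn = bk.dynamic_feature_table(ens, [c[0] for c in spec.couplings])
    ann = bk.generate_annotations(cfg)
    fm, _ = bk.assemble(dddg, dyn, ann, table, allow_drop=True)
    return cfg, records, table, fm


@pytest.fixture(scope="session")
def small_model(small_feature_matrix):
    pruned, _ = bk.prune_features(small_feature_matrix)
    scaled = bk.standardize(pruned)
    model = bk.train_forest(scaled.X, scaled.y, seed=0)
    return model, scaled
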