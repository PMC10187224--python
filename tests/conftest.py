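"""Shared fixtures: one default synthetic dataset processed end to end."""

import pytest

import morphosig as m


@pytest.fixture(scope="session")
def default_config():
    return m.SyntheticConfig()


@pytest.fixture(scope="session")
def dataset(default_config):
    """(platemap, cells, truth) for the default generator config."""
    return m.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def selected_wells(dataset):
    """Feature-selected, normalized, annotated well profiles + report."""
    platemap, cells, _ = dataset
    wells = m.annotate(m.aggregate_wells(cells), platemap)
    return m.select_features(m.normalize(wells))


@pytest.fixture(scope="session")
def discovered(selected_wells):
    """(model1, model2, signature) discovered on the full default dataset."""
    wells, _ = selected_wells
    model1 = m.fit_covariate_model(wells)
    model2 = m.fit_confluence_model(wells)
    signature = m.build_signature(model1, model2)
    return model1, model2, signature
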