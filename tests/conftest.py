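import logging

import pytest

import mirdose as m
from mirdose.io import write_voi_csv
from mirdose.synthetic_data import administered_activities


@pytest.fixture(scope="session")
def scenario():
    return m.default_scenario(seed=1)


@pytest.fixture(scope="session")
def svalues_male():
    return m.generate_toy_svalue_matrix(m.default_phantom("male_2.0"), seed=1)


@pytest.fixture(scope="session")
def svalues_female():
    return m.generate_toy_svalue_matrix(m.default_phantom("female_2.0"), seed=1)


@pytest.fixture(scope="session")
def voi_csv(tmp_path_factory, scenario):
    path = tmp_path_factory.mktemp("study") / "voi.csv"
    write_voi_csv(m.generate_voi_table(scenario), path)
    return path


@pytest.fixture(scope="session")
def run_config(voi_csv, scenario, svalues_male, svalues_female):
    return m.RunConfig(
        voi_csv=voi_csv,
        administered_mbq=administered_activities(scenario),
        svalues_male=svalues_male,
        svalues_female=svalues_female,
        schemes=("ICRP103", "ICRP60"),
        voiding_intervals_h=(0.5, 1.0),
    )


@pytest.fixture(scope="session")
def pipeline_result(run_config):
    logging.disable(logging.WARNING)  # expected uptake-phase fallbacks
    try:
        return m.run_pipeline(run_config)
    finally:
        logging.disable(logging.NOTSET)
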