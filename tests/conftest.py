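import numpy as np
import pandas as pd
import pytest

from faerspv import SimConfig, generate_database, write_database


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A modest universe with one planted signal, duplicates and bad dates."""
    return SimConfig(n_reports=3000, n_pts=50, target_drug_share=0.1,
                     planted_rr={"PT0007": 10.0}, duplicate_rate=0.05,
                     bad_date_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def small_db(small_config):
    return generate_database(small_config)


@pytest.fixture(scope="session")
def small_db_dir(small_db, tmp_path_factory):
    d = tmp_path_factory.mktemp("faers")
    write_database(small_db, d)
    return d


@pytest.fixture()
def toy_universe():
    """Four reports, six drug-event pairs, laid out for hand counting.

    Reports 1 and 2 are target cases; report 1 has PTs {X, Y}, report 2
    {X}; report 3 (comparator) has {Y, Z}, report 4 {Z}.
    """
    events = pd.DataFrame({
        "PRIMARYID": [1, 1, 2, 3, 3, 4],
        "PT": ["X", "Y", "X", "Y", "Z", "Z"],
    })
    return events, {1, 2}
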