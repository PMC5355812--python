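import dataclasses

import numpy as np
import pytest

import silutil as s


@pytest.fixture(scope="session")
def wap():
    return s.WAP_SYSTEM


@pytest.fixture(scope="session")
def preset_record():
    """One synthetic Holocene record shared by read-only tests."""
    return s.generate_record(s.holocene_preset(seed=1))


@pytest.fixture(scope="session")
def isotope_only_config():
    """Preset without covariates, for fast zonation-recovery replicates."""
    return dataclasses.replace(s.holocene_preset(seed=1), covariate_specs=())


def recover_zonation(config, seed):
    """Generate a record, run convert -> zones, return pieces used by
    recovery checks: detected result, recovered utilization, truth."""
    record = s.generate_record(dataclasses.replace(config, seed=seed))
    conv = s.convert_dataframe(record.isotopes, config.system, clamp=True)
    util = conv["utilization_pct"].to_numpy() / 100.0
    res = s.coniss_cluster(util, conv["age_kyr"].to_numpy())
    return record, util, res
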