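import numpy as np
import pandas as pd
import pytest

from opeair import CensorFlag, CongenerSpec, Registry, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def registry(config):
    return config.build_registry()


@pytest.fixture(scope="session")
def mini_registry():
    return Registry(
        [
            CongenerSpec("A", sampling_rate=1.0, mdl=1.0, family="chlorinated",
                         idl=2.0, rfd=7000.0, csf=0.02),
            CongenerSpec("B", sampling_rate=1.0, mdl=1.0, family="alkyl",
                         idl=2.0, rfd=10000.0),
            CongenerSpec("C", sampling_rate=1.0, mdl=1.0, family="aryl", idl=2.0),
        ]
    )


def make_table(records):
    """records: (site, env, congener, value, flag) tuples."""
    return pd.DataFrame(
        records,
        columns=["site_id", "microenvironment", "congener", "value_ng_m3", "censor"],
    )


@pytest.fixture
def toy_table():
    """Four-site, one-congener table with each censor flag represented."""
    return make_table(
        [
            ("s1", "home", "A", 0.0, CensorFlag.NOT_DETECTED.value),
            ("s2", "home", "A", 0.0, CensorFlag.NOT_DETECTED.value),
            ("s3", "home", "A", 2.0, CensorFlag.DETECTED.value),
            ("s4", "home", "A", 4.0, CensorFlag.DETECTED.value),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200901)
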