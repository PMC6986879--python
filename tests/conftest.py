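"""Shared fixtures: small synthetic sessions analyzed once per test run.

Sessions are generated at 500 Hz with 8 electrodes — large enough for
every recovery property to be measurable, small enough that the full
PAC -> PRP -> decoding chain runs in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from prpdecode import AnalysisConfig, decode_timecourse, session_pac, session_prp
from prpdecode.synthetic import (
    naive_config,
    null_config,
    proficient_config,
    simulate_session,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def _analyze(cfg, config, decode_seed=None):
    sess, table, truth = simulate_session(cfg)
    pac = session_pac(
        sess, table, config.bands["theta"], config.bands["high_gamma"], config
    )
    tensors = session_prp(
        sess, table, config.bands["high_gamma"], config, pac_series=pac
    )
    out = {
        "session": sess,
        "table": table,
        "truth": truth,
        "pac": pac,
        "tensors": tensors,
    }
    if decode_seed is not None:
        out["decoding"] = decode_timecourse(
            tensors["peak"], config, seed=decode_seed
        )
    return out


@pytest.fixture(scope="session")
def proficient(config):
    """40-trial proficient-profile session, fully analyzed."""
    return _analyze(
        proficient_config(n_trials=40, seed=1, n_electrodes=8, rate=500.0),
        config,
        decode_seed=3,
    )


@pytest.fixture(scope="session")
def null_session(config):
    """100-trial matched-null session (S+ and S- statistically identical)."""
    return _analyze(
        null_config(n_trials=100, seed=111, n_electrodes=8, rate=500.0),
        config,
        decode_seed=5,
    )
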