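import numpy as np
import pytest
from hypothesis import settings

from paleocmr.simulate import SimConfig, make_fixture, simulate_histories
from paleocmr.timescale import load_stage_table, make_toy_table

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_table():
    return load_stage_table()


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """The tiny synthetic fixture written to disk once per session."""
    outdir = tmp_path_factory.mktemp("tiny")
    occ, traits, truth, cfg = make_fixture("tiny", seed=0, outdir=outdir)
    return {
        "occ": occ,
        "traits": traits,
        "truth": truth,
        "config": cfg,
        "dir": outdir,
    }


@pytest.fixture(scope="session")
def small_histories():
    """A small simulated history set with known coefficients (truth attached)."""
    cfg = SimConfig(
        n_genera=400,
        stage_table=make_toy_table(12, mass_extinction_indices=(5,)),
        beta_size_bg=0.4,
        beta_range_bg=0.4,
        alpha_p=1.5,
        seed=42,
    )
    hist, truth = simulate_histories(cfg)
    return hist, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(20230795)
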