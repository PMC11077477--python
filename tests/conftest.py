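import numpy as np
import pytest

import rewardmap as rm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def consumption_session():
    """A 5-min consumption session with reward/motor/silent populations."""
    spec = rm.CalciumSimSpec(seed=3)
    session, truth = rm.gen_calcium_session(spec)
    return session, truth


@pytest.fixture(scope="session")
def drug_session():
    """A drug session on the 1-min-every-10-min imaging schedule."""
    spec = rm.CalciumSimSpec(
        seed=5,
        duration=3720.0,
        event_times={"injection": 60.0},
        record_windows=rm.drug_record_windows(),
        populations={"reward": (20, 5.0), "motor": (20, 5.0), "silent": (20, 0.0)},
    )
    session, truth = rm.gen_calcium_session(spec)
    return session, truth


@pytest.fixture(scope="session")
def null_atlas_screen():
    """FOS-Seq screen over a pure-null atlas (shared across tests)."""
    gen = np.random.default_rng(777)
    contrast = rm.RegionVector(
        [f"R{i:03d}" for i in range(100)], gen.standard_normal(100)
    )
    spec = rm.IshSimSpec(n_genes=2000, frac_positive=0.0, frac_negative=0.0,
                         seed=11)
    atlas, truth = rm.gen_ish_atlas(spec, contrast)
    records, null = rm.fosseq_screen(contrast, atlas)
    return contrast, atlas, truth, records, null
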