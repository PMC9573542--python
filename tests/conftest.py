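import numpy as np
import pytest

from emotiwin import GeneratorConfig, generate_session, prepare_bundle


def make_bundles(seed: int, k: int = 4, duration_s: float = 45.0):
    """Generate and preprocess a small cohort of synthetic sessions."""
    return [
        prepare_bundle(
            generate_session(
                GeneratorConfig(seed=seed * 100 + i, duration_s=duration_s,
                                subject_id=f"s{i:02d}")
            )
        )
        for i in range(k)
    ]


@pytest.fixture(scope="session")
def bundle():
    """One preprocessed 60 s default session."""
    return prepare_bundle(generate_session(GeneratorConfig(seed=7)))


@pytest.fixture(scope="session")
def small_cohort():
    """Four short preprocessed sessions from distinct subjects."""
    return make_bundles(seed=0, k=4, duration_s=45.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
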