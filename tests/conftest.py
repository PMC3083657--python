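import numpy as np
import pytest

import platescreen as ps


@pytest.fixture(scope="session")
def ec_library() -> ps.TargetLibrary:
    """The seven printed coral-extract characterizations."""
    return ps.ec_reference_library()


@pytest.fixture(scope="session")
def small_library() -> ps.TargetLibrary:
    """A 12-entry synthetic library with MS/MS spectra, fixed seed."""
    return ps.synthetic_library(seed=11, n_entries=12)


def random_features(rng: np.random.Generator, n: int) -> list[ps.ChromatographicFeature]:
    feats = []
    for _ in range(n):
        rt = float(rng.uniform(0.2, 5.8))
        width = float(rng.uniform(0.02, 0.1))
        feats.append(
            ps.ChromatographicFeature(
                mz=float(rng.uniform(100, 900)),
                rt_apex=rt,
                rt_start=rt - width,
                rt_end=rt + width,
                area=float(rng.lognormal(np.log(1e4), 1.0)),
                height=float(rng.lognormal(np.log(1e5), 1.0)),
            )
        )
    return feats
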