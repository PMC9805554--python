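"""Shared fixtures: small phantom suites sized for fast, deterministic tests."""

from __future__ import annotations

import numpy as np
import pytest

from scintimtl.phantom import PhantomConfig, generate_phantom
from scintimtl.training import StudyRecord, prepare_mas


@pytest.fixture()
def numgrad():
    """Central finite-difference gradient of a scalar function of an array."""

    def _numgrad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp = x.copy()
            xp[i] += eps
            xm = x.copy()
            xm[i] -= eps
            g[i] = (f(xp) - f(xm)) / (2 * eps)
        return g

    return _numgrad


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    return PhantomConfig(
        height=160, width=48, n_regions=10,
        lesion_count_range=(1, 3), lesion_sigma_range=(1.2, 2.5),
        lesion_amplitude_range=(30.0, 100.0),
    )


@pytest.fixture(scope="session")
def tiny_sample(tiny_config):
    return generate_phantom(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_records(tiny_config):
    """8 train / 2 val / 2 test studies with MAS precomputed (3 atlases)."""
    roles = ["train"] * 8 + ["val"] * 2 + ["test"] * 2
    records = []
    for i, role in enumerate(roles):
        sample = generate_phantom(tiny_config, seed=500 + i)
        labeled = (role != "train") or (i < 3)
        records.append(StudyRecord(sample=sample, mas=None, labeled=labeled, role=role))
    prepare_mas(records, k=3)
    return records
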