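"""Shared fixtures: small synthetic genomes, elements and read sets.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from retromob import synth


@pytest.fixture(scope="session")
def rng0() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_element():
    """One structurally complete element plus its LTRs (deterministic)."""
    rng = np.random.default_rng(42)
    spec = synth.ElementSpec(name="el", ltr_len=300, internal_len=3500,
                             tsd_len=5)
    elem, ltr5, ltr3 = synth.build_element(spec, rng)
    return spec, elem, ltr5, ltr3


@pytest.fixture(scope="session")
def planted_genome():
    """Two-chromosome genome with five recoverable planted copies."""
    specs = tuple(
        [synth.ElementSpec(name=f"id{i}", ltr_len=400, internal_len=3200,
                           tsd_len=4 + i) for i in range(3)]
        + [synth.ElementSpec(name=f"div{i}", ltr_len=2500, internal_len=3500,
                             tsd_len=5, target_K=0.02) for i in range(2)]
    )
    cfg = synth.SynthConfig(seed=1, n_chrom=2, chrom_len=300_000,
                            elements=specs)
    genome, truth = synth.build_genome(cfg)
    return genome, truth


@pytest.fixture(scope="session")
def circle_element():
    """Short-LTR element suitable for one-LTR junction detection."""
    rng = np.random.default_rng(7)
    spec = synth.ElementSpec(name="alex", ltr_len=100, internal_len=600,
                             tsd_len=5)
    elem, _, _ = synth.build_element(spec, rng)
    return spec, elem
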