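"""Shared fixtures: a toy-scale marker geometry and simulated genomes.

Unit tests run on a reduced geometry (10-kb spacing, 500-bp markers on
~200-kb chromosomes) which exercises the same code paths as the
genome-scale defaults at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vmk import MarkerSetSpec, generate_markers, random_genome

settings.register_profile(
    "vmk",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vmk")

TOY_SPACING = 10_000
TOY_MARKER_LEN = 500


@pytest.fixture(scope="session")
def toy_spec() -> MarkerSetSpec:
    return MarkerSetSpec(spacing=TOY_SPACING, marker_len=TOY_MARKER_LEN)


@pytest.fixture(scope="session")
def toy_ref():
    """Two random chromosomes, 200 kb and 150 kb."""
    return random_genome([200_000, 150_000], seed=11)


@pytest.fixture(scope="session")
def toy_markers(toy_ref, toy_spec):
    return generate_markers(toy_ref, toy_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def write_fastq(path, reads):
    """reads: iterable of (id, seq) or (id, seq, qual)."""
    with open(path, "w") as fh:
        for read in reads:
            rid, seq = read[0], read[1]
            qual = read[2] if len(read) > 2 else "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
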