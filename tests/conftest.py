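"""Shared fixtures: seeded random sequences and simulated genome sets.

The full-size simulation (the 258,473 bp preset) is session-scoped because
several stages are scored against the same truth catalogue; the small
simulation keeps per-module tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from cybridmt.simulate import SimConfig, simulate_cybrid, table_echo_config

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    arr = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


@pytest.fixture(scope="session")
def echo_sim():
    """Full-scale simulation: 258,473 bp cybrid with the printed-table donor
    and plastid segment lengths."""
    cfg = table_echo_config(seed=1)
    return cfg, simulate_cybrid(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down cybrid (60 kb recipient) for fast per-module tests."""
    cfg = SimConfig(
        seed=7,
        recipient_len=60_000,
        n_blocks=5,
        n_inversions=2,
        large_repeat_len=4000,
        donor_segments=(1500, 2500, 800),
        cp_segments=(900, 500),
        short_repeat_spec=((60, 0.95, 3), (150, 0.92, 3)),
        n_coding_snps=12,
        n_genes=6,
        n_comparators=3,
        donor_len=40_000,
        cp_len=30_000,
    )
    return cfg, simulate_cybrid(cfg)
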