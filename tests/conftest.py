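"""Shared fixtures: seeded synthetic datasets run through the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from poolsnp._seq import string_to_phred
from poolsnp.calling import CallPolicy, fallback_mask
from poolsnp.mapping import ContigIndex, build_pileup, map_reads
from poolsnp.pipeline import call_and_screen
from poolsnp.simulate import (
    SimConfig,
    SimTruth,
    simulate_pools,
    simulate_references,
)


@dataclass
class Dataset:
    """A simulated two-pool experiment carried through calling/screening."""

    config: SimConfig
    contigs: dict
    truth: SimTruth
    reads_channel: list
    reads_blue: list
    placements: list = field(default_factory=list)
    unmapped: list = field(default_factory=list)
    pileup: object = None
    policy: CallPolicy = field(default_factory=CallPolicy)
    mask: dict = field(default_factory=dict)
    screened: dict = field(default_factory=dict)
    neighbors: dict = field(default_factory=dict)

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def make_dataset(call_policy: CallPolicy | None = None, **sim_kwargs) -> Dataset:
    config = SimConfig(**sim_kwargs)
    contigs, truth = simulate_references(config)
    ch, bl, truth = simulate_pools(contigs, truth, config)
    index = ContigIndex(contigs)
    pl_ch, un_ch = map_reads(ch, index)
    pl_bl, un_bl = map_reads(bl, index)
    ds = Dataset(
        config=config, contigs=contigs, truth=truth,
        reads_channel=ch, reads_blue=bl,
        placements=pl_ch + pl_bl, unmapped=un_ch + un_bl,
        policy=call_policy or CallPolicy(),
    )
    store = {n: (s, string_to_phred(q)) for n, s, q in ch + bl}
    ds.pileup = build_pileup(
        ds.placements, store, contigs, flank_window=ds.policy.flank_window
    )
    ds.mask = fallback_mask(contigs)
    ds.screened, ds.neighbors = call_and_screen(
        ds.pileup, contigs, ds.policy, ds.mask
    )
    return ds


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """20 contigs at 100x per species: the standard in-silico conditions."""
    return make_dataset(n_contigs=20, rng_seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
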