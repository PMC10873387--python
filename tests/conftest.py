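"""Shared fixtures: one modest simulated dataset and a caller run over it.

Session-scoped so the simulation and feature extraction cost is paid once;
tests must not mutate these objects.
"""

from __future__ import annotations

import numpy as np
import pytest
from pyfaidx import Fasta

from squigmeth import calling, nn_model, signal_io, simulator


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    cfg = simulator.SimConfig(seed=11, ref_length=12_000, n_cpg=120,
                              n_reads=140, read_length_mean=2_000,
                              read_length_sd=300)
    return simulator.generate_dataset(cfg, tmp_path_factory.mktemp("smallds"))


@pytest.fixture(scope="session")
def untrained_model():
    return nn_model.build_model(nn_model.ModelSpec(), seed=7)


@pytest.fixture(scope="session")
def small_calls(small_dataset, untrained_model):
    """All per-read calls of the untrained model on the small dataset."""
    ref = Fasta(str(small_dataset.ref_fasta))
    signals = signal_io.load_signal_index([small_dataset.signal_container])
    moves = signal_io.container_move_tables(small_dataset.signal_container)
    bundles = calling.iter_read_bundles(small_dataset.bam, signals,
                                        ref_fasta=ref, container_moves=moves)
    all_calls, by_read = [], {}
    for read_calls in calling.call_reads(bundles, untrained_model):
        all_calls.extend(read_calls)
        by_read[read_calls[0].read_id] = read_calls
    return all_calls, by_read


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
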