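"""Raw-signal input, normalization, and move-table segmentation.

A nanopore read arrives as an integer DAC sample series ("squiggle") plus a
basecaller *move table*: one 0/1 flag per fixed-size signal block (*stride*
samples) marking whether a new base begins in that block.  This module reads
squiggles from supported containers, removes per-read offset/scale by
median/MAD normalization, and expands the move table into per-base half-open
sample spans that downstream feature extraction slices.

Two container dialects are supported:

* a versioned JSON fixture container (one file per batch; see
  :data:`FIXTURE_CONTAINER_VERSION`), and
* multi-read FAST5, i.e. HDF5 with one ``read_<id>`` group per read holding
  ``Raw/Signal``.

POD5 is not read; the fixture container emulates its role at desk scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Version stamp written into / required from JSON fixture containers.
FIXTURE_CONTAINER_VERSION = 1


class SignalError(ValueError):
    """Structural problem in a signal container, read, or move table."""


@dataclass(frozen=True)
class PoreSignal:
    """One read's raw current samples in integer DAC units."""

    read_id: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if not self.read_id:
            raise SignalError("read_id must be non-empty")
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size == 0:
            raise SignalError(f"read {self.read_id}: samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class NormalizedSignal:
    """Unitless median/MAD-normalized current values for one read."""

    values: np.ndarray


@dataclass(frozen=True)
class MoveMap:
    """Per-base half-open spans into the (normalized) signal array.

    ``spans[k] = (start, end)`` delimits the samples emitted while base ``k``
    of the basecall occupied the pore, in basecall orientation.  Spans are
    contiguous, strictly increasing, and each a positive multiple of
    ``stride`` long; the first starts at ``trim_offset``.
    """

    stride: int
    trim_offset: int
    spans: np.ndarray  # (n_bases, 2) int64

    @property
    def n_bases(self) -> int:
        return int(self.spans.shape[0])

    def span(self, base_index: int) -> tuple[int, int]:
        s, e = self.spans[base_index]
        return int(s), int(e)


def mad_normalize(signal: PoreSignal) -> NormalizedSignal:
    """Center by the median and scale by the (unscaled) MAD.

    ``values = (x - median(x)) / median(|x - median(x)|)``.  No 1.4826
    consistency factor is applied; any fixed factor is absorbed by model
    training.  A read with MAD = 0 (constant or near-constant signal) carries
    no usable level information and is rejected.
    """
    x = np.asarray(signal.samples, dtype=np.float64)
    if x.size < 2:
        raise SignalError(f"read {signal.read_id}: need at least 2 samples to normalize")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        raise SignalError(
            f"read {signal.read_id}: MAD is zero (constant signal), read rejected"
        )
    return NormalizedSignal(values=(x - med) / mad)


def build_move_map(
    moves: Sequence[int] | np.ndarray,
    stride: int,
    trim_offset: int,
    seq_len: int,
    read_id: str = "?",
) -> MoveMap:
    """Expand a 0/1 move vector into per-base sample spans.

    Base ``k`` starts at ``trim_offset + stride * (index of k-th 1)`` and ends
    where base ``k+1`` starts; the last base ends at
    ``trim_offset + stride * len(moves)``.
    """
    moves = np.asarray(moves, dtype=np.int64)
    if stride < 1:
        raise SignalError(f"read {read_id}: stride must be >= 1, got {stride}")
    if trim_offset < 0:
        raise SignalError(f"read {read_id}: trim_offset must be >= 0, got {trim_offset}")
    if moves.size == 0 or moves[0] != 1:
        raise SignalError(f"read {read_id}: move table must start with 1")
    if not np.isin(moves, (0, 1)).all():
        raise SignalError(f"read {read_id}: move table must be 0/1")
    ones = np.flatnonzero(moves)
    if ones.size != seq_len:
        raise SignalError(
            f"read {read_id}: move table has {ones.size} ones but basecall "
            f"has {seq_len} bases"
        )
    starts = trim_offset + stride * ones
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    ends[-1] = trim_offset + stride * moves.size
    return MoveMap(stride=int(stride), trim_offset=int(trim_offset),
                   spans=np.stack([starts, ends], axis=1))


# ---------------------------------------------------------------------------
# Container readers
# ---------------------------------------------------------------------------

def _iter_fixture_container(path: Path) -> Iterator[PoreSignal]:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("version")
    if version != FIXTURE_CONTAINER_VERSION:
        raise SignalError(
            f"{path}: unsupported fixture container version {version!r} "
            f"(expected {FIXTURE_CONTAINER_VERSION})"
        )
    for rec in payload.get("reads", []):
        yield PoreSignal(read_id=rec["read_id"],
                         samples=np.asarray(rec["samples"], dtype=np.int32))


def _iter_fast5(path: Path) -> Iterator[PoreSignal]:
    import h5py

    with h5py.File(path, "r") as fh:
        for key in fh:
            if not key.startswith("read_"):
                continue
            grp = fh[key]
            read_id = grp.attrs.get("read_id")
            if isinstance(read_id, bytes):
                read_id = read_id.decode()
            if not read_id:
                read_id = key[len("read_"):]
            yield PoreSignal(read_id=str(read_id),
                             samples=np.asarray(grp["Raw/Signal"][()], dtype=np.int32))


def load_signals(container: str | Path) -> Iterator[PoreSignal]:
    """Iterate every read in a signal container exactly once.

    The dialect is sniffed from the file: JSON fixture containers start with
    ``{``, anything else is opened as HDF5 (multi-read FAST5).
    """
    path = Path(container)
    if not path.is_file():
        raise SignalError(f"signal container not found or unreadable: {path}")
    with open(path, "rb") as fh:
        head = fh.read(1)
    if head == b"{":
        yield from _iter_fixture_container(path)
    else:
        yield from _iter_fast5(path)


def load_signal_index(containers: Sequence[str | Path]) -> dict[str, PoreSignal]:
    """Load all reads from one or more containers into a read_id-keyed dict."""
    index: dict[str, PoreSignal] = {}
    for container in containers:
        for sig in load_signals(container):
            if sig.read_id in index:
                raise SignalError(f"duplicate read_id across containers: {sig.read_id}")
            index[sig.read_id] = sig
    return index


def write_fixture_container(path: str | Path, reads: Sequence[dict]) -> None:
    """Write the versioned JSON fixture container (one file per batch).

    Each record holds ``read_id``, integer ``samples``, and the basecaller
    metadata (``stride``, ``moves``, ``trim_offset``) for readers that take
    the move table from the container instead of the BAM.
    """
    payload = {
        "version": FIXTURE_CONTAINER_VERSION,
        "reads": [
            {
                "read_id": rec["read_id"],
                "samples": np.asarray(rec["samples"]).astype(int).tolist(),
                "stride": int(rec["stride"]),
                "moves": np.asarray(rec["moves"]).astype(int).tolist(),
                "trim_offset": int(rec.get("trim_offset", 0)),
            }
            for rec in reads
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_fast5(path: str | Path, reads: Sequence[dict]) -> None:
    """Write a minimal multi-read FAST5 (HDF5) container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for rec in reads:
            grp = fh.create_group(f"read_{rec['read_id']}")
            grp.attrs["read_id"] = rec["read_id"]
            grp.create_dataset("Raw/Signal",
                               data=np.asarray(rec["samples"], dtype=np.int32))


def container_move_tables(path: str | Path) -> dict[str, dict]:
    """Move-table metadata stored in a JSON fixture container, by read_id.

    Used as a fallback when the BAM lacks ``mv`` tags; the BAM wins ties.
    """
    p = Path(path)
    with open(p, "rb") as fh:
        if fh.read(1) != b"{":
            return {}
    with open(p) as fh:
        payload = json.load(fh)
    out = {}
    for rec in payload.get("reads", []):
        if "moves" in rec:
            out[rec["read_id"]] = {
                "stride": int(rec["stride"]),
                "moves": np.asarray(rec["moves"], dtype=np.int64),
                "trim_offset": int(rec.get("trim_offset", 0)),
            }
    return out
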