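"""CpG candidate enumeration on reads.

Two candidate sources are combined per read:

* **set A** — positions where the basecalled sequence itself contains a CG
  dinucleotide (works on unmapped reads too), and
* **set B** — read positions that align to a reference CpG, recovered through
  the CIGAR even when a basecall error destroyed the read's own CG motif.

All read coordinates are in *basecall orientation* (the orientation the
signal was produced in); reverse-strand BAM records store the reverse
complement, so positions are mirrored back before use.  Reference
coordinates are 0-based and always name the position of the stranded C:
for a reverse-strand CpG that is the forward-strand G position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNPHASED = 0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentError(ValueError):
    """CIGAR / reference inconsistency."""


@dataclass(frozen=True)
class ReadAlignment:
    """Mapping metadata for one read, lifted from a BAM record."""

    is_mapped: bool
    ref_name: Optional[str]
    ref_start: Optional[int]
    strand: Optional[str]  # '+' or '-'
    is_primary: bool
    phase: int  # 1, 2, or UNPHASED

    @classmethod
    def from_pysam(cls, record) -> "ReadAlignment":
        phase = UNPHASED
        if record.has_tag("HP"):
            phase = int(record.get_tag("HP"))
        if record.is_unmapped:
            return cls(False, None, None, None, not (record.is_secondary or
                                                     record.is_supplementary), phase)
        return cls(
            is_mapped=True,
            ref_name=record.reference_name,
            ref_start=record.reference_start,
            strand="-" if record.is_reverse else "+",
            is_primary=not (record.is_secondary or record.is_supplementary),
            phase=phase,
        )


@dataclass
class CpGCandidate:
    """A cytosine of interest on one read.

    ``ref_pos``/``ref_strand`` give the stranded reference C coordinate when
    the read base is aligned; ``ref_cpg`` records whether the reference
    itself carries a CG at that stranded position (set-B membership implies
    it, set-A-only candidates at SNV loci do not).
    """

    read_pos: int
    ref_pos: Optional[int] = None
    ref_strand: Optional[str] = None
    source: frozenset = field(default_factory=frozenset)
    ref_cpg: bool = False

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("candidate source must be non-empty")
        if (self.ref_pos is None) != (self.ref_strand is None):
            raise ValueError("ref_pos and ref_strand must be present together")


def find_read_motif_sites(sequence: str) -> set[int]:
    """Indices ``i`` with ``sequence[i:i+2] == 'CG'`` (set A)."""
    seq = sequence.upper()
    return {i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"}


def _aligned_ref_positions(record) -> np.ndarray:
    """Reference position aligned to each stored-query position (-1 if none)."""
    n = len(record.query_sequence)
    out = np.full(n, -1, dtype=np.int64)
    for qpos, rpos in record.get_aligned_pairs(matches_only=True):
        out[qpos] = rpos
    return out


def per_base_reference(record, ref_seq: str, ref_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Reference base and coordinate per *basecall-orientation* read position.

    Returns ``(ref_bases, ref_pos)`` arrays of the read's length: the
    reference base assigned to each read base by the CIGAR (complemented for
    reverse-strand alignments so it matches the basecall orientation), with
    ``'N'``/``-1`` for insertions and clipped bases.

    ``ref_seq`` must cover the alignment footprint, starting at reference
    coordinate ``ref_offset``.
    """
    n = len(record.query_sequence)
    rpos_stored = _aligned_ref_positions(record)
    bases_stored = np.full(n, "N", dtype="<U1")
    aligned = rpos_stored >= 0
    idx = rpos_stored[aligned] - ref_offset
    if idx.size and (idx.min() < 0 or idx.max() >= len(ref_seq)):
        raise AlignmentError(
            f"read {record.query_name}: reference window does not cover alignment"
        )
    ref_arr = np.frombuffer(ref_seq.upper().encode(), dtype="S1").astype("<U1")
    bases_stored[aligned] = ref_arr[idx]
    if record.is_reverse:
        bases_stored = np.array([b.translate(_COMPLEMENT) for b in bases_stored[::-1]],
                                dtype="<U1")
        rpos = rpos_stored[::-1].copy()
    else:
        rpos = rpos_stored
    return bases_stored, rpos


def find_ref_anchored_sites(record, ref_seq: str, ref_offset: int) -> dict[int, CpGCandidate]:
    """Set B: read positions aligned to a reference CpG cytosine.

    For forward alignments these are read bases aligned to the C of a
    forward-strand CG; for reverse alignments, read bases whose aligned
    reference base is the G of a forward-strand CG (the reverse-strand C).
    The read base itself need not be a C (basecall errors, SNVs).
    """
    if record.is_unmapped:
        raise AlignmentError(f"read {record.query_name}: cannot anchor an unmapped read")
    ref = ref_seq.upper()
    n = len(record.query_sequence)
    rpos_stored = _aligned_ref_positions(record)
    out: dict[int, CpGCandidate] = {}
    for i in range(n):
        r = rpos_stored[i]
        if r < 0:
            continue
        j = r - ref_offset
        if record.is_reverse:
            # reverse-strand C sits where the forward reference shows CG's G
            if ref[j] == "G" and j - 1 >= 0 and ref[j - 1] == "C":
                read_pos = n - 1 - i
                out[read_pos] = CpGCandidate(read_pos=read_pos, ref_pos=int(r),
                                             ref_strand="-",
                                             source=frozenset({"ref_anchor"}),
                                             ref_cpg=True)
        else:
            if ref[j] == "C" and j + 1 < len(ref) and ref[j + 1] == "G":
                out[i] = CpGCandidate(read_pos=i, ref_pos=int(r), ref_strand="+",
                                      source=frozenset({"ref_anchor"}),
                                      ref_cpg=True)
    return out


def merge_candidates(
    set_a: Iterable[int],
    set_b: dict[int, CpGCandidate],
    read_ref_pos: Optional[np.ndarray] = None,
    strand: Optional[str] = None,
) -> list[CpGCandidate]:
    """Union of sets A and B keyed on read position, sorted by read position.

    ``read_ref_pos`` (basecall-orientation reference coordinate per read
    base, -1 where unaligned) lets mapped set-A-only candidates carry their
    aligned coordinate, so non-reference-CpG loci can be piled up when
    requested.
    """
    merged: dict[int, CpGCandidate] = {}
    for pos, cand in set_b.items():
        merged[pos] = cand
    for pos in set_a:
        if pos in merged:
            c = merged[pos]
            merged[pos] = CpGCandidate(read_pos=pos, ref_pos=c.ref_pos,
                                       ref_strand=c.ref_strand,
                                       source=c.source | {"read_motif"},
                                       ref_cpg=c.ref_cpg)
        else:
            ref_pos = ref_strand = None
            if read_ref_pos is not None and read_ref_pos[pos] >= 0:
                ref_pos, ref_strand = int(read_ref_pos[pos]), strand
            merged[pos] = CpGCandidate(read_pos=pos, ref_pos=ref_pos,
                                       ref_strand=ref_strand,
                                       source=frozenset({"read_motif"}),
                                       ref_cpg=False)
    return [merged[p] for p in sorted(merged)]


def window_identity(read_window: str, ref_window: str) -> float:
    """Fraction of matching bases in the positionally paired 21-bp windows.

    A reference ``N`` (unaligned, clipped, insertion, or off-read padding)
    counts as a mismatch.  Used to exclude poorly aligned training matrices
    (threshold 0.75).
    """
    if len(read_window) != len(ref_window):
        raise ValueError("windows must have equal length")
    matches = sum(1 for a, b in zip(read_window.upper(), ref_window.upper())
                  if b != "N" and a == b)
    return matches / len(read_window)


def read_filters(
    read_length: int,
    mean_qscore: float,
    min_length: Optional[int] = None,
    min_mean_q: Optional[float] = None,
) -> bool:
    """Keep/drop decision for one read; True means keep.

    Dropping is strict (``<`` the threshold), so a read exactly at a
    threshold is kept.  Absent thresholds keep everything.
    """
    if min_length is not None and read_length < min_length:
        return False
    if min_mean_q is not None and mean_qscore < min_mean_q:
        return False
    return True


def mean_phred(qualities: np.ndarray) -> float:
    """Arithmetic mean of per-base Phred values."""
    q = np.asarray(qualities, dtype=np.float64)
    return float(q.mean()) if q.size else 0.0
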