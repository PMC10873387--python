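"""Per-base signal features and 21x19 feature matrices.

Each candidate cytosine is described by a 21-row window (row 10 = the
cytosine) of 19 features per read base:

====  ======================================================================
cols  feature
====  ======================================================================
0     log10 of span length (raw sample count)
1     mean of the base's normalized signal span
2     standard deviation (population) of the span
3-6   means of the four index-quadrants of the span
7     median of the span
8     median absolute deviation of the span
9     basecall probability from the Phred quality, 1 - 10^(-q/10)
10-13 one-hot of the read base over ACGT (all zero on padded rows)
14-18 one-hot of the assigned reference base over ACGTN
====  ======================================================================

Matrices are always built in basecall orientation.  Because move-table
segmentation is approximate (a span may straddle two signal clusters),
several redundant location statistics — mean, median, quadrant means — are
kept to stay informative when the boundary is off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal_io import MoveMap, NormalizedSignal

WINDOW = 21  #: window length in read bases; row WINDOW//2 is the cytosine
N_FEATURES = 19

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_REF_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

COL_QPROB = 9
COL_READ_ONEHOT = slice(10, 14)
COL_REF_ONEHOT = slice(14, 19)
_COL_REF_N = 18


class FeatureError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """One candidate's 21x19 model input plus its provenance."""

    values: np.ndarray  # (21, 19) float32
    center_read_pos: int
    read_id: str
    ref_pos: Optional[int] = None
    ref_strand: Optional[str] = None


def phred_to_prob(q: float) -> float:
    """Probability the basecall is correct, from its Phred quality."""
    if q < 0:
        raise FeatureError(f"negative Phred score: {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def quadrant_bounds(n: int) -> list[tuple[int, int]]:
    """Four half-open index intervals splitting ``range(n)`` by floored quarters."""
    if n < 1:
        raise FeatureError("span length must be >= 1")
    return [(j * n // 4, (j + 1) * n // 4) for j in range(4)]


def base_feature_vector(
    span_values: np.ndarray,
    q: float,
    read_base: str,
    ref_base: str = "N",
) -> np.ndarray:
    """The 19 features for one read base (reference implementation).

    The vectorized path in :func:`read_base_features` must agree with this
    exactly; tests hold it to a brute-force oracle.  Standard deviation and
    MAD are population statistics (divide by n), stable on tiny spans.
    Quadrants that are empty (span length < 4) take the whole-span mean.
    """
    x = np.asarray(span_values, dtype=np.float64)
    if x.size == 0:
        raise FeatureError("empty signal span on a non-padded row")
    out = np.zeros(N_FEATURES, dtype=np.float64)
    mean = x.mean()
    out[0] = np.log10(x.size)
    out[1] = mean
    out[2] = x.std()
    for j, (a, b) in enumerate(quadrant_bounds(x.size)):
        out[3 + j] = x[a:b].mean() if b > a else mean
    med = np.median(x)
    out[7] = med
    out[8] = np.median(np.abs(x - med))
    out[9] = phred_to_prob(q)
    rb = read_base.upper()
    if rb in _BASE_INDEX:
        out[10 + _BASE_INDEX[rb]] = 1.0
    out[14 + _REF_INDEX.get(ref_base.upper(), 4)] = 1.0
    return out


def read_base_features(
    normalized: NormalizedSignal,
    move_map: MoveMap,
    qualities: np.ndarray,
    sequence: str,
    ref_bases: Optional[np.ndarray] = None,
    exclude_ref: bool = False,
) -> np.ndarray:
    """Per-base 19-feature rows for a whole read, vectorized.

    Spans are grouped by length so medians and quadrant means run as single
    array reductions per distinct dwell.  ``ref_bases`` is the per-base
    reference assignment in basecall orientation (``None`` or
    ``exclude_ref`` encode every reference base as N, the dual "reference
    free" view used for unmapped reads and dual-view training).
    """
    values = np.asarray(normalized.values, dtype=np.float64)
    spans = move_map.spans
    n = move_map.n_bases
    if len(sequence) != n or len(qualities) != n:
        raise FeatureError("sequence/qualities length does not match move map")
    if spans[-1, 1] > values.size:
        raise FeatureError("move map extends past the signal array")
    out = np.zeros((n, N_FEATURES), dtype=np.float64)

    lengths = spans[:, 1] - spans[:, 0]
    if (lengths <= 0).any():
        raise FeatureError("non-positive signal span")
    for L in np.unique(lengths):
        rows = np.flatnonzero(lengths == L)
        block = values[spans[rows, 0][:, None] + np.arange(L)[None, :]]
        mean = block.mean(axis=1)
        out[rows, 0] = np.log10(L)
        out[rows, 1] = mean
        out[rows, 2] = block.std(axis=1)
        for j, (a, b) in enumerate(quadrant_bounds(int(L))):
            out[rows, 3 + j] = block[:, a:b].mean(axis=1) if b > a else mean
        med = np.median(block, axis=1)
        out[rows, 7] = med
        out[rows, 8] = np.median(np.abs(block - med[:, None]), axis=1)

    out[:, 9] = 1.0 - 10.0 ** (-np.asarray(qualities, dtype=np.float64) / 10.0)
    seq_arr = np.frombuffer(sequence.upper().encode(), dtype="S1").astype("<U1")
    for base, k in _BASE_INDEX.items():
        out[seq_arr == base, 10 + k] = 1.0
    if ref_bases is None or exclude_ref:
        out[:, _COL_REF_N] = 1.0
    else:
        ref_arr = np.asarray(ref_bases, dtype="<U1")
        if ref_arr.size != n:
            raise FeatureError("ref_bases length does not match read")
        hit = np.zeros(n, dtype=bool)
        for base, k in _BASE_INDEX.items():
            sel = ref_arr == base
            out[sel, 14 + k] = 1.0
            hit |= sel
        out[~hit, _COL_REF_N] = 1.0
    return out


def build_feature_matrix(
    per_base: np.ndarray,
    read_pos: int,
    read_id: str = "?",
    ref_pos: Optional[int] = None,
    ref_strand: Optional[str] = None,
) -> FeatureMatrix:
    """Slice the 21-row window centered at ``read_pos`` out of per-base rows.

    Window positions that fall off either end of the read become padded
    rows: zero signal features, zero quality, all-zero read one-hot, and
    reference base N.
    """
    n = per_base.shape[0]
    half = WINDOW // 2
    values = np.zeros((WINDOW, N_FEATURES), dtype=np.float32)
    values[:, _COL_REF_N] = 1.0  # padded rows default to reference N
    lo = max(0, read_pos - half)
    hi = min(n, read_pos + half + 1)
    if not (0 <= read_pos < n):
        raise FeatureError(f"read {read_id}: candidate position {read_pos} off read")
    values[lo - (read_pos - half): hi - (read_pos - half)] = per_base[lo:hi]
    return FeatureMatrix(values=values, center_read_pos=read_pos, read_id=read_id,
                         ref_pos=ref_pos, ref_strand=ref_strand)


def window_strings(sequence: str, ref_bases: Optional[np.ndarray], read_pos: int
                   ) -> tuple[str, str]:
    """Positionally paired 21-mer read and reference windows (N-padded)."""
    half = WINDOW // 2
    n = len(sequence)
    read_chars, ref_chars = [], []
    for p in range(read_pos - half, read_pos + half + 1):
        if 0 <= p < n:
            read_chars.append(sequence[p].upper())
            ref_chars.append(str(ref_bases[p]).upper() if ref_bases is not None else "N")
        else:
            read_chars.append("N")
            ref_chars.append("N")
    return "".join(read_chars), "".join(ref_chars)
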