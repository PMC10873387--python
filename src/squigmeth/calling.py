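"""Per-read methylation calls and per-site pileups.

The caller walks primary BAM records, pairs each with its raw signal,
builds feature matrices for every CpG candidate, and scores them with the
classifier.  Outputs:

* a per-read TSV (one row per read x CpG, with probability, mapping locus
  and phase),
* an MM/ML-tagged copy of the input BAM (primary records only, byte-level
  passthrough of everything else),
* stranded and strand-aggregated per-site count TSVs, with per-haplotype
  breakdowns when reads carry HP tags.

Coordinates are 0-based half-open; a per-site row names the position of the
stranded C (for a reverse-strand CpG that is the forward-strand G).
"""

from __future__ import annotations

import array
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import candidates as cand
from . import features as feat
from . import signal_io
from .candidates import UNPHASED, revcomp
from .nn_model import predict

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5

PER_READ_COLUMNS = ["read_id", "ref_name", "ref_pos", "ref_strand", "read_pos",
                    "probability", "label", "read_length", "mean_qscore", "phase"]


@dataclass
class PerReadCall:
    """One (read, CpG) methylation probability with mapping metadata."""

    read_id: str
    read_pos: int
    probability: float
    read_length: int
    mean_qscore: float
    phase: int = UNPHASED
    ref_name: Optional[str] = None
    ref_pos: Optional[int] = None
    ref_strand: Optional[str] = None
    ref_cpg: bool = False
    read_base_is_c: bool = True

    def label(self, threshold: float = DEFAULT_THRESHOLD) -> str:
        # ties at the threshold count as methylated
        return "methylated" if self.probability >= threshold else "unmethylated"


@dataclass
class SiteCounts:
    """Stranded methylated/total read counts at one reference CpG cytosine."""

    ref_name: str
    pos: int
    strand: str
    total: int = 0
    meth: int = 0
    phase1_total: int = 0
    phase1_meth: int = 0
    phase2_total: int = 0
    phase2_meth: int = 0

    @property
    def frequency(self) -> float:
        return self.meth / self.total if self.total else float("nan")


@dataclass
class AggregatedSite:
    """Strand-combined counts keyed on the forward-strand C coordinate."""

    ref_name: str
    cpg_pos: int
    total: int = 0
    meth: int = 0
    phase1_total: int = 0
    phase1_meth: int = 0
    phase2_total: int = 0
    phase2_meth: int = 0

    @property
    def frequency(self) -> float:
        return self.meth / self.total if self.total else float("nan")


# ---------------------------------------------------------------------------
# Read traversal and per-read calling
# ---------------------------------------------------------------------------

@dataclass
class ReadBundle:
    """Everything the classifier needs for one read."""

    read_id: str
    candidates: list
    matrices: np.ndarray  # (n_candidates, 21, 19)
    read_length: int
    mean_qscore: float
    phase: int
    ref_name: Optional[str]
    sequence: str = ""
    ref_bases: Optional[np.ndarray] = None  # basecall orientation, N where unaligned


def basecall_orientation(record) -> tuple[str, np.ndarray]:
    """Sequence and qualities in basecall (signal) orientation.

    Reverse-strand records store the reverse complement; move tables are
    defined over the original basecall, so both are restored before span
    assignment.
    """
    seq = record.query_sequence
    quals = np.asarray(record.query_qualities, dtype=np.int32)
    if record.is_reverse:
        return revcomp(seq), quals[::-1].copy()
    return seq, quals


def move_table_from_record(record) -> Optional[tuple[np.ndarray, int, int]]:
    """(moves, stride, trim_offset) from mv:B:c / ts:i tags, if present."""
    if not record.has_tag("mv"):
        return None
    mv = np.asarray(record.get_tag("mv"), dtype=np.int64)
    stride, moves = int(mv[0]), mv[1:]
    trim = int(record.get_tag("ts")) if record.has_tag("ts") else 0
    return moves, stride, trim


def iter_read_bundles(
    bam_path: str | Path,
    signal_index: dict[str, signal_io.PoreSignal],
    ref_fasta=None,
    exclude_ref: bool = False,
    min_length: Optional[int] = None,
    min_mean_q: Optional[float] = None,
    container_moves: Optional[dict] = None,
) -> Iterator[ReadBundle]:
    """Yield one :class:`ReadBundle` per usable primary BAM record.

    Reads absent from every signal container, filtered out, or with a
    degenerate signal are skipped with a logged warning/diagnostic.
    Secondary and supplementary alignments are skipped silently.
    """
    save = pysam.set_verbosity(0)
    bam = pysam.AlignmentFile(str(bam_path), check_sq=False)
    pysam.set_verbosity(save)
    with bam:
        for record in bam.fetch(until_eof=True):
            if record.is_secondary or record.is_supplementary:
                continue
            read_id = record.query_name
            sig = signal_index.get(read_id)
            if sig is None:
                logger.warning("read %s referenced by BAM but absent from signal "
                               "containers; skipped", read_id)
                continue
            bundle = _bundle_for_record(record, sig, ref_fasta, exclude_ref,
                                        min_length, min_mean_q, container_moves)
            if bundle is not None:
                yield bundle


def _bundle_for_record(record, sig, ref_fasta, exclude_ref, min_length,
                       min_mean_q, container_moves) -> Optional[ReadBundle]:
    seq, quals = basecall_orientation(record)
    mq = cand.mean_phred(quals)
    if not cand.read_filters(len(seq), mq, min_length, min_mean_q):
        return None
    mv = move_table_from_record(record)
    if mv is None and container_moves and record.query_name in container_moves:
        meta = container_moves[record.query_name]
        mv = meta["moves"], meta["stride"], meta["trim_offset"]
    if mv is None:
        logger.warning("read %s has no move table in BAM or container; skipped",
                       record.query_name)
        return None
    moves, stride, trim = mv
    try:
        move_map = signal_io.build_move_map(moves, stride, trim, len(seq),
                                            read_id=record.query_name)
        norm = signal_io.mad_normalize(sig)
    except signal_io.SignalError as exc:
        logger.warning("%s", exc)
        return None

    mapped = (not record.is_unmapped) and ref_fasta is not None
    ref_bases = rpos_bc = None
    set_b: dict = {}
    strand = None
    if mapped:
        ref_window = str(ref_fasta[record.reference_name]
                         [record.reference_start:record.reference_end])
        ref_bases, rpos_bc = cand.per_base_reference(record, ref_window,
                                                     record.reference_start)
        set_b = cand.find_ref_anchored_sites(record, ref_window,
                                             record.reference_start)
        strand = "-" if record.is_reverse else "+"
    set_a = cand.find_read_motif_sites(seq)
    cands = cand.merge_candidates(set_a, set_b, rpos_bc, strand)
    if not cands:
        return None
    per_base = feat.read_base_features(norm, move_map, quals, seq,
                                       ref_bases, exclude_ref)
    matrices = np.stack([
        feat.build_feature_matrix(per_base, c.read_pos, read_id=record.query_name,
                                  ref_pos=c.ref_pos, ref_strand=c.ref_strand).values
        for c in cands
    ])
    aln = cand.ReadAlignment.from_pysam(record)
    return ReadBundle(read_id=record.query_name, candidates=cands,
                      matrices=matrices, read_length=len(seq), mean_qscore=mq,
                      phase=aln.phase,
                      ref_name=record.reference_name if mapped else None,
                      sequence=seq, ref_bases=ref_bases)


def call_reads(
    bundles: Iterable[ReadBundle],
    model,
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 512,
) -> Iterator[list[PerReadCall]]:
    """Score every candidate of every read; yields one call list per read."""
    for bundle in bundles:
        probs = predict(model, bundle.matrices, batch_size=batch_size)
        calls = []
        for c, p in zip(bundle.candidates, probs):
            calls.append(PerReadCall(
                read_id=bundle.read_id, read_pos=c.read_pos,
                probability=float(p), read_length=bundle.read_length,
                mean_qscore=bundle.mean_qscore, phase=bundle.phase,
                ref_name=bundle.ref_name if c.ref_pos is not None else None,
                ref_pos=c.ref_pos, ref_strand=c.ref_strand, ref_cpg=c.ref_cpg,
                read_base_is_c="read_motif" in c.source,
            ))
        yield calls


# ---------------------------------------------------------------------------
# MM/ML tagging
# ---------------------------------------------------------------------------

def encode_mm_ml(seq_basecall: str, calls: Sequence[PerReadCall]
                 ) -> Optional[tuple[str, list[int]]]:
    """MM/ML tag payloads for one read's calls (explicit-skip '?' mode).

    Only calls whose read base is a C (set-A membership) are taggable.  MM
    deltas count skipped C's over the basecall-orientation sequence; ML
    stores ``floor(p * 256)`` clipped to 255.
    """
    taggable = sorted((c for c in calls if c.read_base_is_c),
                      key=lambda c: c.read_pos)
    if not taggable:
        return None
    c_positions = [i for i, b in enumerate(seq_basecall.upper()) if b == "C"]
    c_rank = {p: r for r, p in enumerate(c_positions)}
    deltas, probs = [], []
    prev_rank = -1
    for c in taggable:
        rank = c_rank.get(c.read_pos)
        if rank is None:
            raise ValueError(f"read {c.read_id}: taggable call at non-C position "
                             f"{c.read_pos}")
        deltas.append(rank - prev_rank - 1)
        prev_rank = rank
        probs.append(min(255, int(np.floor(c.probability * 256))))
    mm = "C+m?," + ",".join(map(str, deltas)) + ";"
    return mm, probs


def tag_bam(
    bam_in: str | Path,
    bam_out: str | Path,
    calls_by_read: dict[str, list[PerReadCall]],
) -> None:
    """Copy a BAM, adding MM/ML tags to primary records with calls.

    All other fields are preserved; secondary and supplementary alignments
    are never tagged.
    """
    save = pysam.set_verbosity(0)
    src = pysam.AlignmentFile(str(bam_in), check_sq=False)
    pysam.set_verbosity(save)
    with src, pysam.AlignmentFile(str(bam_out), "wb", template=src) as dst:
        for record in src.fetch(until_eof=True):
            if not (record.is_secondary or record.is_supplementary):
                calls = calls_by_read.get(record.query_name)
                if calls:
                    seq = record.query_sequence
                    if record.is_reverse:
                        seq = revcomp(seq)
                    encoded = encode_mm_ml(seq, calls)
                    if encoded is not None:
                        mm, ml = encoded
                        record.set_tag("MM", mm, "Z")
                        record.set_tag("ML", array.array("B", ml))
            dst.write(record)


# ---------------------------------------------------------------------------
# Per-site pileup
# ---------------------------------------------------------------------------

def phase_split(calls: Sequence[PerReadCall], threshold: float
                ) -> tuple[int, int, int, int]:
    """(phase1_total, phase1_meth, phase2_total, phase2_meth) for one site.

    Unphased reads contribute to the overall counts only.
    """
    p1t = p1m = p2t = p2m = 0
    for c in calls:
        meth = c.probability >= threshold
        if c.phase == 1:
            p1t += 1
            p1m += meth
        elif c.phase == 2:
            p2t += 1
            p2m += meth
    return p1t, p1m, p2t, p2m


def pileup(
    calls: Iterable[PerReadCall],
    threshold: float = DEFAULT_THRESHOLD,
    include_non_cpg_ref: bool = False,
) -> list[SiteCounts]:
    """Stranded per-site counts over all reference-anchored calls.

    The denominator at a locus is every read with an aligned base there —
    substitutions included (counted methylated only if called so), deletions
    naturally excluded because a deleted base generates no candidate.  By
    default only reference-CpG loci are reported; ``include_non_cpg_ref``
    adds loci where only the reads carry the CG motif.
    """
    grouped: dict[tuple[str, int, str], list[PerReadCall]] = {}
    for c in calls:
        if c.ref_pos is None or c.ref_name is None:
            continue
        if not (c.ref_cpg or include_non_cpg_ref):
            continue
        grouped.setdefault((c.ref_name, c.ref_pos, c.ref_strand), []).append(c)
    out = []
    for (ref_name, pos, strand) in sorted(grouped):
        site_calls = grouped[(ref_name, pos, strand)]
        meth = sum(c.probability >= threshold for c in site_calls)
        p1t, p1m, p2t, p2m = phase_split(site_calls, threshold)
        out.append(SiteCounts(ref_name=ref_name, pos=pos, strand=strand,
                              total=len(site_calls), meth=meth,
                              phase1_total=p1t, phase1_meth=p1m,
                              phase2_total=p2t, phase2_meth=p2m))
    return out


def aggregate_strands(stranded: Iterable[SiteCounts]) -> list[AggregatedSite]:
    """Combine (+ at p) with (- at p+1) into one CpG-dinucleotide record.

    Sites covered on only one strand are still emitted.
    """
    agg: dict[tuple[str, int], AggregatedSite] = {}
    for s in stranded:
        cpg_pos = s.pos if s.strand == "+" else s.pos - 1
        a = agg.setdefault((s.ref_name, cpg_pos),
                           AggregatedSite(ref_name=s.ref_name, cpg_pos=cpg_pos))
        a.total += s.total
        a.meth += s.meth
        a.phase1_total += s.phase1_total
        a.phase1_meth += s.phase1_meth
        a.phase2_total += s.phase2_total
        a.phase2_meth += s.phase2_meth
    return [agg[k] for k in sorted(agg)]


# ---------------------------------------------------------------------------
# Text outputs and merge
# ---------------------------------------------------------------------------

def write_per_read_tsv(calls: Iterable[PerReadCall], path: str | Path,
                       threshold: float = DEFAULT_THRESHOLD) -> None:
    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id,
            "ref_name": c.ref_name if c.ref_name is not None else ".",
            "ref_pos": c.ref_pos if c.ref_pos is not None else ".",
            "ref_strand": c.ref_strand if c.ref_strand is not None else ".",
            "read_pos": c.read_pos,
            "probability": f"{c.probability:.6f}",
            "label": c.label(threshold),
            "read_length": c.read_length,
            "mean_qscore": f"{c.mean_qscore:.2f}",
            "phase": c.phase,
        })
    pd.DataFrame(rows, columns=PER_READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_per_read_tsv(path: str | Path) -> list[PerReadCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        mapped = row.ref_pos != "."
        calls.append(PerReadCall(
            read_id=row.read_id, read_pos=int(row.read_pos),
            probability=float(row.probability),
            read_length=int(row.read_length), mean_qscore=float(row.mean_qscore),
            phase=int(row.phase),
            ref_name=row.ref_name if mapped else None,
            ref_pos=int(row.ref_pos) if mapped else None,
            ref_strand=row.ref_strand if mapped else None,
            ref_cpg=mapped,  # refined against the reference at merge time
        ))
    return calls


def write_stranded_tsv(sites: Iterable[SiteCounts], path: str | Path) -> None:
    rows = [{
        "ref_name": s.ref_name, "start": s.pos, "end": s.pos + 1,
        "strand": s.strand, "total": s.total, "meth": s.meth,
        "frequency": f"{s.frequency:.6f}",
        "phase1_total": s.phase1_total, "phase1_meth": s.phase1_meth,
        "phase2_total": s.phase2_total, "phase2_meth": s.phase2_meth,
    } for s in sites]
    pd.DataFrame(rows, columns=["ref_name", "start", "end", "strand", "total",
                                "meth", "frequency", "phase1_total", "phase1_meth",
                                "phase2_total", "phase2_meth"]).to_csv(
        path, sep="\t", index=False)


def write_aggregated_tsv(sites: Iterable[AggregatedSite], path: str | Path) -> None:
    rows = [{
        "ref_name": s.ref_name, "start": s.cpg_pos, "end": s.cpg_pos + 2,
        "total": s.total, "meth": s.meth, "frequency": f"{s.frequency:.6f}",
        "phase1_total": s.phase1_total, "phase1_meth": s.phase1_meth,
        "phase2_total": s.phase2_total, "phase2_meth": s.phase2_meth,
    } for s in sites]
    pd.DataFrame(rows, columns=["ref_name", "start", "end", "total", "meth",
                                "frequency", "phase1_total", "phase1_meth",
                                "phase2_total", "phase2_meth"]).to_csv(
        path, sep="\t", index=False)


def refine_ref_cpg(calls: Sequence[PerReadCall], ref_fasta) -> None:
    """Recompute each anchored call's reference-CpG flag from the FASTA."""
    for c in calls:
        if c.ref_pos is None:
            continue
        contig = str(ref_fasta[c.ref_name][:])
        if c.ref_strand == "+":
            c.ref_cpg = contig[c.ref_pos:c.ref_pos + 2].upper() == "CG"
        else:
            c.ref_cpg = (c.ref_pos >= 1 and
                         contig[c.ref_pos - 1:c.ref_pos + 1].upper() == "CG")


def merge(
    per_read_paths: Sequence[str | Path],
    threshold: float = DEFAULT_THRESHOLD,
    min_mean_q: Optional[float] = None,
    ref_fasta=None,
    include_non_cpg_ref: bool = False,
) -> tuple[list[SiteCounts], list[AggregatedSite]]:
    """Combine per-read TSVs from several runs and recompute per-site output.

    Re-applies the probability threshold and the mean-quality cutoff, then
    rebuilds the stranded and aggregated pileups.  Duplicate
    (read_id, read_pos) rows across runs indicate double counting and are
    an error.  Without a reference FASTA every anchored locus is kept (the
    TSV schema does not record reference context); pass ``ref_fasta`` to
    restrict to reference-CpG loci again.
    """
    calls: list[PerReadCall] = []
    for path in per_read_paths:
        calls.extend(read_per_read_tsv(path))
    seen = set()
    for c in calls:
        key = (c.read_id, c.read_pos)
        if key in seen:
            raise ValueError(f"duplicate per-read call across runs: {key}")
        seen.add(key)
    if min_mean_q is not None:
        calls = [c for c in calls if c.mean_qscore >= min_mean_q]
    if ref_fasta is not None:
        refine_ref_cpg(calls, ref_fasta)
    else:
        include_non_cpg_ref = True
    stranded = pileup(calls, threshold=threshold,
                      include_non_cpg_ref=include_non_cpg_ref)
    return stranded, aggregate_strands(stranded)
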