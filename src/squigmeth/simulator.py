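"""Synthetic squiggle datasets with known per-site methylation truth.

The generator emulates the statistical structure the caller relies on:
k-mer-dependent expected current levels, a constant level shift ``delta``
added to every k-mer that covers a 5-methylcytosine, stochastic per-base
dwell (geometric, in stride-sized blocks), Gaussian sample noise, basecall
substitution errors with depressed quality scores, move tables, and an
affine transform to integer DAC units so that MAD normalization is
genuinely exercised.  It does not attempt realistic pore kinetics,
homopolymer errors, or indels (all-M CIGARs in this version).

A dataset is a self-consistent trio — signal container, BAM with mv/ts
(and optionally HP) tags, reference FASTA — plus truth tables recording
each site's methylation frequency and each read's Bernoulli state at every
site it covers.
"""

from __future__ import annotations

import json
from array import array as _array
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .candidates import revcomp
from .signal_io import write_fixture_container, write_fast5

_BASES = np.array(list("ACGT"))


@dataclass
class SiteFreqModel:
    """Per-CpG truth-frequency distribution: point masses at 0 and 1 for
    confidently un/methylated sites plus a Beta-distributed intermediate
    component (partially methylated / heterogeneous sites)."""

    p_zero: float = 0.4
    p_one: float = 0.5
    beta_a: float = 2.0
    beta_b: float = 2.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        freq = rng.beta(self.beta_a, self.beta_b, size=n)
        freq[u < self.p_zero] = 0.0
        freq[u >= 1.0 - self.p_one] = 1.0
        return freq


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the desk-scale conditions used throughout the test suite:
    a 50 kb single-contig reference carrying ~500 CpGs, ~40x coverage of
    3 kb reads, a methylation level shift of 2 normalized units against
    per-sample noise of SD 1, 2% substitution errors.
    """

    seed: int = 0
    k: int = 6
    # the k-mer level table is a property of the pore chemistry, shared by
    # every dataset of the same "flowcell type"; it gets its own seed so that
    # independent datasets (new reads, new reference) keep the same physics,
    # as real training and calling runs do
    pore_seed: int = 7878
    level_sd: float = 1.0
    noise_sd: float = 1.0
    delta: float = 2.0
    dwell_mean: float = 2.0  # mean stride-blocks per base (geometric, >= 1)
    stride: int = 5
    sub_error_rate: float = 0.02
    q_correct: int = 20
    q_error: int = 7
    ref_length: int = 50_000
    n_cpg: int = 500
    # planted CpGs are kept further apart than the pore footprint plus the
    # feature window so that *independently* drawn per-site frequencies stay
    # identifiable: closer spacing makes one site's level shift bleed into a
    # neighbor's window, which no caller could disentangle without the
    # neighbor-correlation structure of real genomes
    min_cpg_spacing: int = 25
    n_reads: int = 650
    read_length_mean: int = 3000
    read_length_sd: int = 500
    read_length_min: int = 500
    fraction_reverse: float = 0.5
    fraction_unmapped: float = 0.0
    dac_scale: float = 20.0
    dac_offset: float = 600.0
    contig: str = "sim1"
    site_freq_model: SiteFreqModel = field(default_factory=SiteFreqModel)
    # diploid / imprinting scenario: within the region, haplotype 1 is fully
    # methylated and haplotype 2 fully unmethylated
    diploid: bool = False
    imprinted_region: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")


def make_pore_model(k: int, seed: int, level_sd: float = 1.0) -> np.ndarray:
    """Expected normalized level per k-mer, ~ Normal(0, level_sd).

    Indexed by the base-4 encoding of the k-mer (A=0, C=1, G=2, T=3).
    Methylated variants are not stored: a methylated C adds ``delta`` to
    every k-mer whose window covers it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, level_sd, size=4 ** k)


_ENC = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 code of the k-mer starting at each position (end padded with A)."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("fragment contains non-ACGT base")
    padded = np.concatenate([codes, np.zeros(k - 1, dtype=np.int64)])
    out = np.zeros(len(seq), dtype=np.int64)
    for j in range(k):
        out = out * 4 + padded[j:j + len(seq)]
    return out


@dataclass
class SimulatedRead:
    read_id: str
    samples: np.ndarray  # integer DAC units
    moves: np.ndarray
    stride: int
    trim_offset: int
    basecalls: str  # molecule orientation
    qualities: np.ndarray
    strand: str
    frag_start: int
    frag_end: int
    phase: int  # 0 unphased
    states: dict  # stranded ref pos of the C -> methylated bool


def simulate_read(
    fragment: str,
    frag_start: int,
    strand: str,
    states: dict[int, bool],
    cfg: SimConfig,
    rng: np.random.Generator,
    pore: np.ndarray,
    read_id: str,
    phase: int = 0,
) -> SimulatedRead:
    """Generate one read's signal, move table, basecalls and metadata.

    ``fragment`` is the forward-strand reference slice; ``states`` maps the
    stranded reference coordinate of each covered C (forward C positions
    for '+', forward G positions for '-') to its methylation state for this
    molecule.
    """
    frag_end = frag_start + len(fragment)
    molecule = fragment if strand == "+" else revcomp(fragment)
    n = len(molecule)
    # molecule-coordinate positions of methylated Cs
    meth_pos = []
    for ref_pos, state in states.items():
        if not state:
            continue
        mpos = (ref_pos - frag_start) if strand == "+" else (frag_end - 1 - ref_pos)
        meth_pos.append(mpos)
    levels = pore[_kmer_codes(molecule, cfg.k)].copy()
    if meth_pos:
        shifted = np.zeros(n, dtype=bool)
        for p in meth_pos:
            shifted[max(0, p - cfg.k + 1):p + 1] = True  # k-mers covering the C
        levels[shifted] += cfg.delta

    dwell = rng.geometric(1.0 / cfg.dwell_mean, size=n)
    moves = np.zeros(int(dwell.sum()), dtype=np.int64)
    starts_blocks = np.concatenate([[0], np.cumsum(dwell)[:-1]])
    moves[starts_blocks] = 1
    per_sample_level = np.repeat(levels, dwell * cfg.stride)
    trim_offset = int(rng.integers(0, 2 * cfg.stride))
    signal = np.concatenate([
        rng.normal(0.0, max(cfg.noise_sd, 1e-12), size=trim_offset),
        per_sample_level + rng.normal(0.0, cfg.noise_sd, size=per_sample_level.size)
        if cfg.noise_sd > 0 else per_sample_level,
    ])
    dac = np.rint(signal * cfg.dac_scale + cfg.dac_offset).astype(np.int32)

    bases = np.frombuffer(molecule.encode(), dtype="S1").astype("<U1")
    quals = np.full(n, cfg.q_correct, dtype=np.int32)
    if cfg.sub_error_rate > 0:
        err = rng.random(n) < cfg.sub_error_rate
        for i in np.flatnonzero(err):
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(0, 3)]
        quals[err] = cfg.q_error
    return SimulatedRead(
        read_id=read_id, samples=dac, moves=moves, stride=cfg.stride,
        trim_offset=trim_offset, basecalls="".join(bases), qualities=quals,
        strand=strand, frag_start=frag_start, frag_end=frag_end, phase=phase,
        states=dict(states),
    )


def _make_reference(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """CG-free random background with exactly ``n_cpg`` CG dinucleotides
    planted at well-separated positions; returns (sequence, forward C
    positions of the CpGs)."""
    seq = rng.choice(_BASES, size=cfg.ref_length)
    # remove incidental CGs so CpG density is controlled
    for _ in range(4):
        cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
        if cg.size == 0:
            break
        seq[cg + 1] = rng.choice(np.array(list("ACT")), size=cg.size)
    candidates_pos = rng.permutation(np.arange(10, cfg.ref_length - 10))
    chosen: list[int] = []
    taken = np.zeros(cfg.ref_length, dtype=bool)
    s = max(2, cfg.min_cpg_spacing)
    for p in candidates_pos:
        if len(chosen) == cfg.n_cpg:
            break
        if not taken[max(0, p - s):p + s + 2].any():
            chosen.append(int(p))
            taken[p:p + 2] = True
    if len(chosen) < cfg.n_cpg:
        raise ValueError(
            f"cannot place {cfg.n_cpg} CpGs with spacing {s} in "
            f"{cfg.ref_length} bp; lower n_cpg or min_cpg_spacing")
    chosen = np.sort(np.array(chosen, dtype=np.int64))
    seq[chosen] = "C"
    seq[chosen + 1] = "G"
    return "".join(seq), chosen


@dataclass
class SimulatedDataset:
    """Paths and in-memory truth for one generated dataset."""

    ref_fasta: Path
    bam: Path
    signal_container: Path
    truth_sites: pd.DataFrame   # ref_name, pos, strand, frequency
    truth_states: pd.DataFrame  # read_id, ref_name, pos, strand, methylated
    truth_reads: pd.DataFrame   # read_id, strand, phase, frag_start, frag_end
    cpg_positions: np.ndarray   # forward-strand C coordinates
    config: SimConfig


def generate_dataset(cfg: SimConfig, outdir: str | Path,
                     container_format: str = "fixture") -> SimulatedDataset:
    """Write a self-consistent dataset under ``outdir``.

    ``container_format`` is ``fixture`` (JSON) or ``fast5`` (HDF5); the
    fixture container also carries the move tables as a BAM-tag fallback.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    pore = make_pore_model(cfg.k, seed=cfg.pore_seed, level_sd=cfg.level_sd)

    ref_seq, cpg_pos = _make_reference(cfg, rng)
    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{cfg.contig}\n")
        for i in range(0, len(ref_seq), 80):
            fh.write(ref_seq[i:i + 80] + "\n")

    # stranded truth frequencies: the CpG dinucleotide's frequency applies
    # to both its forward C (pos p) and reverse C (pos p+1)
    base_freq = cfg.site_freq_model.draw(rng, cpg_pos.size)
    freq_by_hap = {0: base_freq}
    if cfg.diploid:
        f1, f2 = base_freq.copy(), base_freq.copy()
        if cfg.imprinted_region is not None:
            lo, hi = cfg.imprinted_region
            inside = (cpg_pos >= lo) & (cpg_pos < hi)
            f1[inside] = 1.0
            f2[inside] = 0.0
        freq_by_hap = {1: f1, 2: f2}

    pos_to_idx = {int(p): i for i, p in enumerate(cpg_pos)}
    reads, state_rows, read_rows = [], [], []
    for r in range(cfg.n_reads):
        length = int(np.clip(rng.normal(cfg.read_length_mean, cfg.read_length_sd),
                             cfg.read_length_min, cfg.ref_length))
        start = int(rng.integers(0, cfg.ref_length - length + 1))
        strand = "-" if rng.random() < cfg.fraction_reverse else "+"
        phase = int(rng.integers(1, 3)) if cfg.diploid else 0
        freqs = freq_by_hap[phase if cfg.diploid else 0]
        covered = cpg_pos[(cpg_pos >= start) & (cpg_pos + 1 < start + length)]
        states = {}
        for p in covered:
            f = freqs[pos_to_idx[int(p)]]
            state = bool(rng.random() < f)
            stranded_pos = int(p) if strand == "+" else int(p) + 1
            states[stranded_pos] = state
        read_id = f"read_{r:05d}"
        sim = simulate_read(ref_seq[start:start + length], start, strand, states,
                            cfg, rng, pore, read_id, phase=phase)
        reads.append(sim)
        for sp, st in states.items():
            state_rows.append({"read_id": read_id, "ref_name": cfg.contig,
                               "pos": sp, "strand": strand, "methylated": int(st)})
        read_rows.append({"read_id": read_id, "strand": strand, "phase": phase,
                          "frag_start": start, "frag_end": start + length})

    container_path = outdir / ("signals.json" if container_format == "fixture"
                               else "signals.fast5")
    recs = [{"read_id": s.read_id, "samples": s.samples, "stride": s.stride,
             "moves": s.moves, "trim_offset": s.trim_offset} for s in reads]
    if container_format == "fixture":
        write_fixture_container(container_path, recs)
    else:
        write_fast5(container_path, recs)

    bam_path = outdir / "reads.bam"
    _write_bam(bam_path, reads, cfg, rng)

    site_rows = []
    for i, p in enumerate(cpg_pos):
        for strand, pos in (("+", int(p)), ("-", int(p) + 1)):
            row = {"ref_name": cfg.contig, "pos": pos, "strand": strand,
                   "frequency": float(base_freq[i])}
            if cfg.diploid:
                row["frequency_hap1"] = float(freq_by_hap[1][i])
                row["frequency_hap2"] = float(freq_by_hap[2][i])
            site_rows.append(row)

    truth_sites = pd.DataFrame(site_rows)
    truth_states = pd.DataFrame(state_rows)
    truth_reads = pd.DataFrame(read_rows)
    truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth_states.to_csv(outdir / "truth_states.tsv", sep="\t", index=False)
    truth_reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)

    return SimulatedDataset(ref_fasta=fasta_path, bam=bam_path,
                            signal_container=container_path,
                            truth_sites=truth_sites, truth_states=truth_states,
                            truth_reads=truth_reads, cpg_positions=cpg_pos,
                            config=cfg)


def collect_labeled_matrices(
    dataset: SimulatedDataset,
    rule=None,
    identity_threshold: float = 0.75,
    exclude_ref: bool = False,
):
    """Feature matrices + labels from a dataset, for training/evaluation.

    Site-level labels follow the training rule (unanimously >= 90%
    methylated sites are positive, < 10% negative, at >= 10x coverage;
    everything else excluded), and matrices whose 21-bp read window has
    identity below ``identity_threshold`` against the aligned reference are
    dropped, mirroring training-set construction on real data.

    Returns ``(X, y_site, y_read, meta)``: the (n, 21, 19) matrix stack,
    the site-level training labels, each molecule's true Bernoulli state
    (for per-read evaluation), and a per-matrix metadata frame.
    """
    from pyfaidx import Fasta

    from .calling import iter_read_bundles
    from .candidates import window_identity
    from .features import window_strings
    from .nn_model import TrainingLabelRule
    from .signal_io import container_move_tables, load_signal_index

    rule = rule or TrainingLabelRule()
    freq = {(r.pos, r.strand): r.frequency
            for r in dataset.truth_sites.itertuples(index=False)}
    coverage = dataset.truth_states.groupby(["pos", "strand"]).size().to_dict()
    state = {(r.read_id, r.pos, r.strand): r.methylated
             for r in dataset.truth_states.itertuples(index=False)}

    ref = Fasta(str(dataset.ref_fasta))
    signals = load_signal_index([dataset.signal_container])
    moves = container_move_tables(dataset.signal_container)
    mats, y_site, y_read, meta = [], [], [], []
    for bundle in iter_read_bundles(dataset.bam, signals, ref_fasta=ref,
                                    exclude_ref=exclude_ref,
                                    container_moves=moves):
        for i, c in enumerate(bundle.candidates):
            if c.ref_pos is None or not c.ref_cpg:
                continue
            key = (c.ref_pos, c.ref_strand)
            if key not in freq:
                continue
            label = rule.label([coverage.get(key, 0)], [freq[key]])
            if label is None:
                continue
            rw, fw = window_strings(bundle.sequence, bundle.ref_bases, c.read_pos)
            if window_identity(rw, fw) < identity_threshold:
                continue
            truth = state.get((bundle.read_id, c.ref_pos, c.ref_strand))
            if truth is None:
                continue
            mats.append(bundle.matrices[i])
            y_site.append(label)
            y_read.append(int(truth))
            meta.append({"read_id": bundle.read_id, "ref_pos": c.ref_pos,
                         "ref_strand": c.ref_strand})
    X = np.stack(mats) if mats else np.empty((0, 21, 19), dtype=np.float32)
    return (X, np.asarray(y_site, dtype=np.int64),
            np.asarray(y_read, dtype=np.int64), pd.DataFrame(meta))


def _write_bam(path: Path, reads: list[SimulatedRead], cfg: SimConfig,
               rng: np.random.Generator) -> None:
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": cfg.contig, "LN": cfg.ref_length}]}
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for s in reads:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = s.read_id
            unmapped = rng.random() < cfg.fraction_unmapped
            if unmapped:
                rec.is_unmapped = True
                rec.query_sequence = s.basecalls
                rec.query_qualities = _array("B", s.qualities.tolist())
            else:
                rec.reference_id = 0
                rec.reference_start = s.frag_start
                rec.mapping_quality = 60
                rec.cigartuples = [(0, len(s.basecalls))]  # all M, v1 has no indels
                if s.strand == "-":
                    rec.is_reverse = True
                    rec.query_sequence = revcomp(s.basecalls)
                    rec.query_qualities = _array("B", s.qualities[::-1].tolist())
                else:
                    rec.query_sequence = s.basecalls
                    rec.query_qualities = _array("B", s.qualities.tolist())
            rec.set_tag("mv", _array("b", [s.stride] + s.moves.tolist()))
            rec.set_tag("ts", s.trim_offset)
            if s.phase:
                rec.set_tag("HP", s.phase)
            bam.write(rec)
    pysam.sort("-o", str(path), str(tmp))
    pysam.index(str(path))
    tmp.unlink()
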