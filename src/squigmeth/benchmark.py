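"""Evaluation methodology: ground-truth labeling, metrics, stratification.

Implements the rules used to benchmark a methylation caller against
short-read ground truth: unanimity labeling across replicates, per-read
classification metrics at the 0.5 threshold, per-site metrics after
binarizing frequencies at 50%, coverage-filtered Pearson correlation, and
stratification of sites into genomic contexts (CpG islands, shores,
shelves, promoters, exons, introns, intergenic).

Intervals are 0-based half-open throughout.  A site overlapping several
region labels counts in each (per-region rows are computed independently).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score

EXCLUDED = -1

REGION_LABELS = ["islands", "shores", "shelves", "promoters", "exons",
                 "introns", "intergenic"]

#: per-mode unanimity labeling rules: (min coverage, positive >=, negative <)
LABEL_RULES = {
    "per_read": (10, 0.90, 0.10),
    "per_site": (10, 0.80, 0.20),
}


def label_sites(coverage: np.ndarray, frequency: np.ndarray, mode: str,
                min_coverage: Optional[int] = None) -> np.ndarray:
    """Unanimity labels from replicate-level ground truth.

    ``coverage`` and ``frequency`` are (n_sites, n_replicates).  A site is
    kept only if every replicate meets the coverage floor; it is positive
    iff every replicate meets the positive rule, negative iff every
    replicate is below the negative rule, else ``EXCLUDED``.
    """
    if mode not in LABEL_RULES:
        raise ValueError(f"unknown labeling mode {mode!r}")
    min_cov, pos_thr, neg_thr = LABEL_RULES[mode]
    if min_coverage is not None:
        min_cov = min_coverage
    cov = np.atleast_2d(np.asarray(coverage, dtype=float))
    freq = np.atleast_2d(np.asarray(frequency, dtype=float))
    labels = np.full(cov.shape[0], EXCLUDED, dtype=np.int64)
    ok = (cov >= min_cov).all(axis=1)
    labels[ok & (freq >= pos_thr).all(axis=1)] = 1
    labels[ok & (freq < neg_thr).all(axis=1)] = 0
    return labels


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else float("nan"))
    return precision, recall, f1


def per_read_metrics(probabilities: np.ndarray, labels: np.ndarray,
                     threshold: float = 0.5) -> dict:
    """Precision/recall/F1 at the threshold, AUROC and average precision.

    Methylated is the positive class; ties at the threshold are called
    methylated.  AUROC uses the midrank tie convention (equivalent to
    exhaustive positive-negative pair counting).  With a single class it is
    undefined and reported as ``None``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision, recall, f1 = _prf(tp, fp, fn)
    single_class = np.unique(y).size < 2
    return {
        "n": int(y.size),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auroc": None if single_class else float(roc_auc_score(y, p)),
        "average_precision": None if single_class
        else float(average_precision_score(y, p)),
    }


def auroc_confidence_interval(probabilities: np.ndarray, labels: np.ndarray,
                              level: float = 0.95) -> tuple[float, float, float]:
    """AUROC with a Hanley-McNeil normal-approximation confidence interval."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    auc = float(roc_auc_score(y, p))
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(sps.norm.ppf(0.5 + level / 2))
    return auc, auc - z * se, auc + z * se


def auroc_cluster_bootstrap_ci(probabilities: np.ndarray, labels: np.ndarray,
                               clusters: np.ndarray, level: float = 0.95,
                               n_boot: int = 2000, seed: int = 0
                               ) -> tuple[float, float, float]:
    """AUROC with a percentile CI from a bootstrap over clusters.

    Per-read methylation calls are not independent: every read covering a
    CpG shares that site's truth frequency and sequence context, so the
    effective sample size is closer to the number of *sites* than the
    number of calls.  Resampling whole clusters (sites) gives a CI with the
    right coverage for pooled per-read AUROC; a call-level normal
    approximation would be anticonservative.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    cl = np.asarray(clusters)
    auc = float(roc_auc_score(y, p))
    uniq, inverse = np.unique(cl, return_inverse=True)
    by_cluster = [np.flatnonzero(inverse == i) for i in range(uniq.size)]
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, uniq.size, size=uniq.size)
        idx = np.concatenate([by_cluster[i] for i in pick])
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(roc_auc_score(yb, p[idx]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return auc, float(lo), float(hi)


def per_site_metrics(predicted: pd.DataFrame, truth: pd.DataFrame,
                     min_coverage: int = 10) -> dict:
    """Site-level precision/recall/F1.

    ``predicted`` needs columns (ref_name, pos, strand, total, frequency);
    ``truth`` needs (ref_name, pos, strand, label) with 0/1 labels.  Sites
    are intersected after applying the coverage filter to the predictions;
    predicted frequencies >= 0.5 are called methylated.
    """
    pred = predicted[predicted["total"] >= min_coverage]
    merged = pred.merge(truth, on=["ref_name", "pos", "strand"], how="inner",
                        suffixes=("", "_truth"))
    if merged.empty:
        return {"n": 0, "precision": float("nan"), "recall": float("nan"),
                "f1": float("nan")}
    call = merged["frequency"].to_numpy(dtype=float) >= 0.5
    y = merged["label"].to_numpy(dtype=int)
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    precision, recall, f1 = _prf(tp, fp, fn)
    return {"n": int(len(merged)), "precision": precision, "recall": recall,
            "f1": f1}


def correlation(predicted: pd.DataFrame, truth: pd.DataFrame,
                min_coverage_pred: int = 10, min_coverage_truth: int = 0) -> dict:
    """Pearson r of methylation frequencies over the coverage-filtered
    intersection; no frequency-based site exclusion."""
    pred = predicted[predicted["total"] >= min_coverage_pred]
    tr = truth
    if "total" in truth.columns and min_coverage_truth:
        tr = truth[truth["total"] >= min_coverage_truth]
    merged = pred.merge(tr, on=["ref_name", "pos", "strand"], how="inner",
                        suffixes=("_pred", "_truth"))
    n = len(merged)
    if n < 2:
        return {"n_sites": n, "pearson_r": float("nan")}
    x = merged["frequency_pred"].to_numpy(dtype=float)
    y = merged["frequency_truth"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"n_sites": n, "pearson_r": float("nan")}
    return {"n_sites": n, "pearson_r": float(sps.pearsonr(x, y)[0])}


# ---------------------------------------------------------------------------
# Genomic regions
# ---------------------------------------------------------------------------

def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge half-open intervals into a disjoint increasing set."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a - b of half-open interval sets (both merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append([cur, bs])
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def extend_intervals(intervals: np.ndarray, pad: int, contig_length: int
                     ) -> np.ndarray:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2).copy()
    if iv.size == 0:
        return iv
    iv[:, 0] = np.maximum(iv[:, 0] - pad, 0)
    iv[:, 1] = np.minimum(iv[:, 1] + pad, contig_length)
    return merge_intervals(iv)


@dataclass
class RegionSet:
    """Labeled interval collections per contig: label -> contig -> (n, 2)."""

    regions: dict

    def membership(self, label: str, contig: str, positions: np.ndarray
                   ) -> np.ndarray:
        """Boolean mask of positions falling inside a labeled region."""
        iv = self.regions.get(label, {}).get(contig)
        pos = np.asarray(positions, dtype=np.int64)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.size, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < iv[idx[ok], 1]
        return ok


def build_regions(
    islands: dict[str, np.ndarray],
    genes: dict[str, np.ndarray],
    exons: dict[str, np.ndarray],
    tss: dict[str, list[tuple[int, str]]],
    contig_lengths: dict[str, int],
) -> RegionSet:
    """Derive the seven region labels from islands and gene annotation.

    * shores: islands extended by 2 kb each way, minus the islands;
    * shelves: islands extended by 4 kb, minus islands and shores;
    * promoters: the strand-aware 1,000 bp upstream of each TSS;
    * introns: genes minus exons;
    * intergenic: genome minus (genes union promoters).

    All intervals are clipped to contig bounds.
    """
    regions: dict[str, dict[str, np.ndarray]] = {lab: {} for lab in REGION_LABELS}
    empty = np.empty((0, 2), dtype=np.int64)
    for contig, length in contig_lengths.items():
        isl = merge_intervals(islands.get(contig, empty))
        gen = merge_intervals(genes.get(contig, empty))
        exo = merge_intervals(exons.get(contig, empty))
        shores = subtract_intervals(extend_intervals(isl, 2_000, length), isl)
        shelves = subtract_intervals(
            subtract_intervals(extend_intervals(isl, 4_000, length), isl), shores)
        promoter_iv = []
        for t, strand in tss.get(contig, []):
            if strand == "+":
                promoter_iv.append([max(0, t - 1_000), t])
            else:
                promoter_iv.append([t + 1, min(length, t + 1_001)])
        promoters = merge_intervals(np.asarray(promoter_iv, dtype=np.int64)
                                    .reshape(-1, 2))
        regions["islands"][contig] = isl
        regions["shores"][contig] = shores
        regions["shelves"][contig] = shelves
        regions["promoters"][contig] = promoters
        regions["exons"][contig] = exo
        regions["introns"][contig] = subtract_intervals(gen, exo)
        genome = np.array([[0, length]], dtype=np.int64)
        regions["intergenic"][contig] = subtract_intervals(
            genome, merge_intervals(np.concatenate([gen, promoters])
                                    if gen.size or promoters.size else empty))
    return RegionSet(regions=regions)


def read_bed_intervals(path) -> dict[str, np.ndarray]:
    """BED file -> contig-keyed merged interval arrays (first three columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return {chrom: merge_intervals(g[["start", "end"]].to_numpy())
            for chrom, g in df.groupby("chrom")}


def read_gene_annotation(path) -> tuple[dict, dict, dict]:
    """GTF/GFF3 -> (genes, exons, tss) keyed by contig.

    ``genes``/``exons`` are interval arrays; ``tss`` lists (position,
    strand) per gene, the position being the first transcribed base.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, list] = {}
    exons: dict[str, list] = {}
    tss: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype == "gene":
            genes.setdefault(feat.seqid, []).append([feat.start - 1, feat.end])
            t = feat.start - 1 if feat.strand == "+" else feat.end - 1
            tss.setdefault(feat.seqid, []).append((t, feat.strand))
        elif feat.featuretype == "exon":
            exons.setdefault(feat.seqid, []).append([feat.start - 1, feat.end])
    to_iv = lambda d: {k: np.asarray(v, dtype=np.int64) for k, v in d.items()}
    return to_iv(genes), to_iv(exons), tss


def stratify(sites: pd.DataFrame, regions: RegionSet,
             metric: Callable[[pd.DataFrame], dict]) -> pd.DataFrame:
    """Recompute a metric on the sites intersecting each region label.

    A site may fall in several labels and then counts in each row; a label
    with no sites yields an empty row.
    """
    rows = []
    for label in REGION_LABELS:
        mask = np.zeros(len(sites), dtype=bool)
        for contig, grp in sites.groupby("ref_name"):
            mask[grp.index.to_numpy()] |= regions.membership(
                label, contig, grp["pos"].to_numpy())
        sub = sites[mask].reset_index(drop=True)
        row = {"region": label, "n_sites": int(mask.sum())}
        if len(sub):
            row.update(metric(sub))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent MM/ML decoding (round-trip check against the TSV pileup)
# ---------------------------------------------------------------------------

def pileup_from_tagged_bam(bam_path, threshold: float = 0.5) -> pd.DataFrame:
    """Stranded per-site counts recomputed from MM/ML tags alone.

    Decoding goes through pysam's ``modified_bases`` parser, independent of
    this package's encoder, so agreement with the TSV pileup checks the
    whole MM/ML round trip.  Only read-CG cytosines are taggable, so this
    matches the pileup restricted to set-A calls.
    """
    import pysam

    counts: dict[tuple[str, int, str], list[int]] = {}
    save = pysam.set_verbosity(0)
    bam = pysam.AlignmentFile(str(bam_path), check_sq=False)
    pysam.set_verbosity(save)
    with bam:
        for record in bam.fetch(until_eof=True):
            if record.is_unmapped or record.is_secondary or record.is_supplementary:
                continue
            mods = record.modified_bases  # keyed (base, strand flag, mod code)
            if not mods:
                continue
            strand = "-" if record.is_reverse else "+"
            aligned = {q: r for q, r in record.get_aligned_pairs(matches_only=True)}
            for key, entries in mods.items():
                if key[0] != "C" or key[2] != "m":
                    continue
                for qpos, ml in entries:
                    # pysam reports positions on the stored (aligned) sequence
                    rpos = aligned.get(qpos)
                    if rpos is None:
                        continue
                    c = counts.setdefault((record.reference_name, rpos, strand),
                                          [0, 0])
                    c[0] += 1
                    c[1] += (ml + 0.5) / 256.0 >= threshold
    rows = [{"ref_name": k[0], "pos": k[1], "strand": k[2],
             "total": v[0], "meth": v[1],
             "frequency": v[1] / v[0]} for k, v in sorted(counts.items())]
    return pd.DataFrame(rows)
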