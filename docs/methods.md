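# Methods

## Pipeline model and assumptions

squigmeth treats methylation calling as supervised per-molecule
classification followed by counting. The assumptions behind each stage:

* **Signal normalization.** Per-read current offset and scale are nuisance
  parameters; centering by the median and dividing by the *unscaled* median
  absolute deviation removes them. The 1.4826 Gaussian consistency factor
  is deliberately omitted — it is a constant the classifier absorbs — and
  normalization runs over the full raw read before trimming, with
  move-table spans indexing into the normalized array offset by the trim
  (`ts`) value. A read with MAD = 0 carries no level information and is
  rejected with a diagnostic rather than propagated as NaNs.
* **Move tables are trusted but approximate.** Spans are taken exactly as
  the move table dictates (one span per basecalled base, lengths a multiple
  of the stride). Because span boundaries are known to be imprecise, the
  feature set keeps several redundant location statistics per span (mean,
  median, quadrant means) rather than trusting any single one. When both
  the BAM `mv` tag and a container-stored table exist, the BAM wins;
  container tables are a fallback.
* **Orientation.** Matrices are always built in basecall orientation.
  Reverse-strand BAM records are reverse-complemented back (and their
  qualities reversed) before span assignment, since move tables are defined
  over the original basecall.
* **Candidate sets.** Set A (read CG motifs) works without any reference;
  set B (reference-anchored CpGs) tolerates basecall errors at the site
  itself. A set-A candidate on a mapped read that is *not* a reference CpG
  still records its aligned coordinate, so `--include-non-cpg-ref` pileups
  are possible.
* **Per-site counting.** The denominator at a stranded site is the number
  of reads with an aligned base there: substitutions count (as
  unmethylated unless called methylated), deletions contribute nothing
  because a deleted base never generates a candidate. Ties at the 0.5
  probability threshold count as methylated. Unphased reads enter the
  overall counts only.

## Classifier

The default BiLSTM: input 19 features × 21 timesteps → two stacked
bidirectional recurrent layers, hidden 128, each direction with separate
input and recurrent bias vectors (the convention of mainstream deep
learning frameworks, which the parameter identities below require) → all 21
timestep outputs concatenated and flattened to 5376 → dense to 128 →
rectifier (configurable) → dense to 1 → sigmoid. Total 1,236,225 trainable
parameters; the final layer alone has 129. A Transformer variant (4
post-layer-norm encoder layers, 8 heads, sinusoidal positions, default
d_model 64, feed-forward 256) sits behind the same interface; its head
reuses the flatten→dense→dense design so the same pruning applies.

Both networks, their backpropagation, and Adam are implemented directly on
numpy arrays; gradient correctness is property-tested against central
finite differences in float64. Training and inference run in float32.

**Pruning.** `round(fraction × 688,128)` smallest-|w| entries of the
5376×128 weight matrix are masked to zero (stable argsort, so ties break by
flat index, deterministically). The mask is stored in the checkpoint and
applied in the forward pass — weights are not destroyed, which is what lets
`--disable-pruning` recover the dense model — and masked entries receive
zero gradient if training continues. At the default fraction 0.95 the whole
model retains 582,503 nonzero parameters.

**Training.** Adam, learning rate 5e-5, L2 coefficient 1e-5 (added to the
gradient, the usual `weight_decay` semantics), binary cross-entropy from
logits, at most 10 epochs. Early stopping monitors accuracy at threshold
0.5 on a held-out validation split (10% by default); because that estimate
has ~0.5% standard error at desk scale, up to three non-improving epochs
are tolerated before stopping (`patience=3`), and the best epoch's weights
are restored. Batch size 64 — chosen in a pilot so the small fixed learning
rate still yields enough optimizer steps per epoch to converge at
~10⁴-matrix scale. With `dual_view` (default) every training matrix is used
twice, once as-is and once with the reference one-hot forced to N, so one
model serves mapped and unmapped reads; validation uses the original view.
Site-level training labels require every ground-truth replicate to show
≥90% methylation (positive) or <10% (negative) at ≥10× coverage; matrices
whose 21-bp read window has <0.75 identity to the aligned reference are
excluded from training. The identity filter is applied at training only,
not at inference.

## The simulator: what it emulates, what it does not

`simulator.generate_dataset` produces a reference FASTA, a coordinate-sorted
BAM with `mv`/`ts` (and optionally `HP`) tags, a signal container (versioned
JSON fixture or multi-read FAST5 via HDF5), and truth tables (per-site
frequency, per-(read, site) Bernoulli state, per-read strand/phase).

Emulated, with defaults chosen as realistic desk-scale conditions:

* k-mer-dependent levels: a level table over all 4⁶ 6-mers, i.i.d.
  Normal(0, 1) in normalized units. The table is seeded by `pore_seed`,
  *separate from the dataset seed*, because it models the flowcell
  chemistry that independent runs share.
* methylation: a constant shift `delta` (default 2.0 normalized units)
  added to every k-mer covering a methylated C.
* dwell: geometric number of stride-blocks per base, mean 2.0 blocks of
  stride 5 (~10 samples/base, in the range of R9/R10 translocation).
* noise: i.i.d. Gaussian per sample, SD 1.0 in normalized units, then an
  affine map to integer DAC units (per-read scale/offset fixed by config)
  so MAD normalization is genuinely exercised.
* basecall errors: substitutions at 2% with depressed quality (Q7 vs Q20);
  the signal always reflects the true molecule, only the basecall string
  and qualities are corrupted.
* truth frequencies: mixture of point masses at 0 (40%) and 1 (50%) and a
  Beta(2, 2) intermediate component (10%), applied identically to both
  strands of a CpG; per-read states are independent Bernoulli draws.
  A diploid mode assigns reads to haplotypes and supports an imprinted
  region (haplotype 1 fully methylated, haplotype 2 fully unmethylated).

Deliberately not emulated: indels (CIGARs are all-M; set-B anchoring and
the SNV denominator rule are still exercised through substitutions),
realistic pore kinetics and homopolymer artifacts, inter-site correlation
of methylation state, and POD5 containers. Consequently, passing tests
show the *machinery* is correct and that the classifier recovers planted
signal under known conditions; they do not certify accuracy on real
flowcell data.

One generator constraint deserves emphasis: planted CpGs keep a minimum
spacing of 25 bp (configurable). Because the simulator draws neighboring
site frequencies independently, a methylated neighbor inside the pore
footprint would shift signal within another site's feature window and make
that site's truth unidentifiable for *any* caller — a cross-talk regime
real genomes escape through correlated neighbor methylation, which this
generator does not model. The spacing keeps the generator's independence
assumption self-consistent; the close-spacing regime remains reachable via
`min_cpg_spacing`.

## Numerical and format choices

* Population (divide-by-n) SD and MAD per span; empty quadrants (span < 4
  samples) take the whole-span mean; log span length uses the raw sample
  count (≥ stride, never log 0).
* Window rows off either read end are padded: zero signal features, zero
  quality, all-zero read one-hot, reference N.
* Coordinates are 0-based half-open everywhere; per-site TSVs are BED-like;
  a stranded row names the stranded C position, an aggregated row the
  forward C with end = start + 2.
* MM tags use explicit-skip semantics (`C+m?`) over basecall-orientation
  C's; ML stores `floor(p·256)` clipped to 255, so threshold-0.5 decisions
  survive the round trip exactly. Only primary alignments are tagged, and
  only calls whose read base is C are taggable (reference-anchored calls at
  substituted bases appear in the TSV but cannot be expressed in MM/ML).
* `merge` re-applies the probability threshold and quality cutoff and
  rejects duplicate (read, position) rows. The per-read TSV schema does not
  record reference context, so merge restricts output to reference CpGs
  only when given the FASTA; otherwise it keeps all anchored loci.
* Mean read quality is the arithmetic mean of per-base Phred values.
* AUROC uses midrank ties. For pooled per-read calls the package provides a
  cluster bootstrap CI (resampling CpG sites), because calls sharing a site
  share its truth frequency and sequence context and a call-level normal
  CI is anticonservative by roughly the ratio of calls to sites.

## Test-suite study conditions

The end-to-end tests train and evaluate at the package's standard
conditions: 50 kb single-contig reference, 500 CpGs, ~650 reads of ~3 kb
(≈40× coverage), delta 2.0, noise SD 1.0, 10,000 training matrices
(dual-view doubled), ≤10 epochs; evaluation uses an independently generated
dataset with the same configuration and chemistry. The null control uses
delta 0 at a 12 kb / 120 CpG / 300 read scale. Unit tests run on a 12 kb /
120 CpG / 140 read dataset shared across the suite.

## Known limitations

* **Per-site exactness at degenerate frequencies.** With truth frequencies
  of exactly 0 or 1 (most sites under the default mixture), the exact
  binomial 99% interval of the truth degenerates to a single count, so a
  40× site tolerates zero read errors. The desk-scale classifier reaches
  ~98–99% held-out per-read accuracy (AUROC ≈ 0.998) under the standard
  conditions — errors are scale-limited, not format- or strand-driven —
  which places ~85–92% of ≥30× sites inside their intervals rather than
  the ~97%+ a near-perfect caller would achieve. The corresponding
  acceptance test is intentionally left failing rather than weakened; even
  a 99%-accurate caller would only put ~70% of 40× degenerate sites inside
  such intervals, so the all-sites-inside reading is unattainable for any
  realistic classifier.
* Edge candidates (within 10 bp of a read end) are markedly less accurate
  (~12% error vs ~2% interior) because half their window is padding.
* The Transformer head's published parameter counts are not reproduced;
  its internals beyond layer/head counts are configurable choices here.
* No indel simulation, no POD5 reading, no bedMethyl output, no
  differential-methylation testing (counts are DSS-ready; see README).
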