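# Methods

`hoxtale` reimplements, as a tested pipeline, the computational analyses by
which paralog-selective HOX enhancer binding is characterized: degenerate
HOX-PBX motif-variant enrichment across fold-enrichment-ranked ChIP-seq
peaks, motif co-occurrence statistics, a simplified differential-binding
test, a multitask sequence-to-signal convolutional regressor, and in-silico
binding-site knockout. Because the underlying ChIP-seq datasets are not
redistributable, every analysis is exercised end-to-end on a synthetic-data
generator with fully known ground truth; this note describes the models,
the defaults, and what the synthetic results do and do not establish.

## Coordinates, peaks and overlap

All coordinates are 0-based half-open (BED convention); readers convert
1-based inputs. A peak is an interval plus a summit and a fold enrichment
(FE, signal over background); every ranking uses FE with ties broken by
(chrom, start, name) so "top N" is deterministic. Two peaks are *shared*
when their 200 nt summit windows intersect by at least `min_overlap` bases
(default 1); each peak is counted once however many windows of the other
set it touches. Windows running past a chromosome start are clipped and
flagged, never dropped. Nearest-peak distances are summit-to-summit by
default (edge-to-edge is an option) and binned into unit log10 intervals
with a separate zero bin. FE distributions are compared on the log2 scale
with a one-sided Welch t-test; two identical constant samples return
p = 0.5, flagged as degenerate.

## Motif scanning

Motifs are IUPAC consensus patterns with a mismatch budget, or exact k-mer
sets (KSM-style; an internal N is a one-position wildcard). Mismatches are
counted only at fixed (non-N) positions — "1 mismatch in TGATNNAT" means
one of the six fixed bases differs. A genomic N never satisfies a fixed
position. Both strands are scanned by default; reverse-strand hits report
their sequence in motif orientation, so the 16 NN-concretizations of
TGATNNAT pool both strands in variant tables. Presence statistics count a
peak once however many hits it contains; variant count tables count every
hit. Inter-motif distances are edge-to-edge gaps (overlapping spans → 0).

Class enrichment (e.g. motif content of differential-binding classes) is
hypergeometric on motif presence against the union of classes as
background, BH-corrected across all (class, pattern) cells.

## Differential binding

The reference treatment of this step in the field is an edgeR NB-GLM on a
DiffBind consensus. Here it is deliberately replaced by a transparent
two-step with honest error control: TMM normalization (trim 30% on M, 5%
on A, precision-weighted; validated against edgeR's `calcNormFactors` in
the test suite), then, per region, the exact conditional binomial
(two-sample Poisson) test on replicate-summed counts — conditional on the
region total, the tissue-A count is binomial with null probability given by
the effective library sizes. The *mid-p* variant is the default: discrete
exact p-values are conservative and visibly non-uniform under the null,
while mid-p restores calibration; the suite verifies both uniformity
(KS against uniform at 10^4 regions) and family-wise error of BH under the
global null. A region is called up/down only when BH q < 0.05 **and**
|log2 fold change| ≥ 1 (both configurable); six-class labels (per-tissue
up/down) require consistent calls against both other tissues.

Known limitation: the exact test models counting noise only. Replicate-level
biological variability (the generator's `replicate_sd`) is overdispersion
that an NB model would absorb and this test does not; null-calibration
claims therefore hold under shared Poisson rates, and on strongly
overdispersed data the test is anticonservative — exactly the regime where
edgeR's dispersion estimation earns its complexity.

## Sequence-to-signal regressor

A single-convolution-layer network maps one-hot 600 nt sequence to log2
RPKM in seven tasks (two HOXA2-BA2 replicates, two HOXA3-PBA replicates,
MEIS in BA1/BA2/PBA): convolution (64 filters, width 12, stride 2) → ReLU →
global average pooling → dense ReLU (64) → linear head. Discovery of rare
long motifs by the convolution layer is a lottery over filter
initializations, so the filter count is kept comfortably above the number
of planted patterns. Three further choices matter and were made on measured
behaviour:

- **Average pooling, global window.** Pooled ReLU activations are linear in
  motif copy number, the correct inductive bias for an additive
  motif-content regression. Max pooling starves the convolution of gradient
  (only argmax positions update) and a positional dense layer (58 pooled
  blocks × filters) memorizes the training set instead of learning motifs.
- **Reverse-complement augmentation** (half of each batch complemented;
  prediction averages both orientations). Motifs occur on either strand;
  without augmentation a forward-only network has half the examples per
  orientation and in practice never discovered the 10-mer Forkhead k-mers.
- **Stride 2.** A stride up to `filter_width − L + 1` still scores every
  motif of length L at full strength in some window; stride 2 with width-12
  filters covers all motifs up to 11 nt and halves compute.

Training: Adam, MSE averaged over tasks (missing values maskable), lr 3e-2
with cosine decay to 5%, batch 64, weight decay 1e-5 (heavier decay
visibly shrinks effect estimates recovered by knockout), random 80/20
validation split, best-validation weights restored. All hyperparameters are
exposed; a fixed seed reproduces weights exactly on one thread. Transfer
learning copies convolution filters from a single-task source model and
optionally freezes them for the first fine-tuning epochs. Sensitivity maps
report the predicted per-task change for every single-base substitution;
reference-base entries are exactly zero. Checkpoints are self-describing
JSON (architecture, task list, seed, training log, weights).

## In-silico knockout

A 25 nt site centred on the motif midpoint (odd width: the extra base falls
left; edge sites shift inward, width preserved) is rewritten with 13
dinucleotides sampled uniformly with replacement from the non-overlapping
dinucleotide tiling of the rest of the region (each outside segment tiled
separately so no junction dinucleotide is invented), truncated to 25 nt.
The predicted change is averaged over 100 seeded replacements.

Replacement is not effect-neutral: a random 25 nt patch occasionally
creates chance motif instances and the erased window may carry near-miss
instances, so every knockout has a small (~±0.03 log2) sign-consistent
background shift. Over 50 tightly averaged sites a Wilcoxon signed-rank
test detects such shifts even for features with no effect. Two measures
keep the attribution clean, and both are defaults in the pipeline:

- **Cross-class exclusion.** A candidate Forkhead/GATA site is kept only if
  its whole 25 nt erasure window is free of matches to every *other* known
  site class (HOX-PBX, MEIS, Forkhead, GATA, bHLH), extending the original
  internal-HOX-PBX filter, so erasure never clips a neighbouring known site.
- **Background normalization.** Each candidate is paired with a control
  knockout of a motif-free 25 nt window in the same region; the reported
  delta is candidate minus control per repeat. The GATA negative control is
  expected to be null only on this adjusted scale.

Two bookkeeping details follow from the heavy overlap of the Forkhead KSM
k-mers. One genomic site typically matches several members at shifted
offsets, so candidate hits are deduplicated per overlapping cluster (most
central hit kept) to avoid pseudo-replicating sites; and since each
distinct match carries one effect unit in the additive model, erasing a
site removes multiplicity × β. Per-copy effect recovery therefore divides
the summed knockout deltas by the summed in-window match multiplicities
rather than naively by the number of sites.

Cohorts are summarized per (feature class, task) with a two-sided
one-sample Wilcoxon signed-rank test against zero, BH across groups;
groups under 5 sites (or with all-zero deltas) are flagged untested.

## Synthetic data generator

Each of `n_regions` (default 6795) 600 nt regions gets a tissue context
(BA1/BA2/PBA, exact thirds by default) that sets planting probabilities:
TGATTCAT 0.20 in PBA and 0 in BA2; TGATGGAT and TGATTGAT 0.25 each in BA2;
the shared variant TGATTAAT 0.30 everywhere; MEIS TGACA 0.40 everywhere;
the Forkhead KSM set (one of the ten k-mers per planting) 0.30 in PBA;
GATA (AGATAA) 0.30 in PBA with **no** effect — the negative control; bHLH
CATCTG 0.20 in BA2. HOX-PBX variants plant within ±90 nt of the region
centre (inside the 200 nt summit window), cofactors within ±150 nt; strands
are random; a ±25 nt guard around plantings is cleaned of chance HOX-PBX
matches (submatches intrinsic to a planted motif's own sequence — e.g. the
reverse-strand TGATNNAT core inside some Forkhead k-mers — are real and
retained). Chance matches elsewhere are left in place and **count toward
the signal**, so expected binding is an exact function of the emitted
sequence.

Expected log2 RPKM per task is `b0 + Σ β·n + ε`, with b0 = 2.0, region
noise ε ~ N(0, 0.15²) shared across tasks, replicate noise N(0, 0.10²) per
column, and n the total match count of each catalogue motif. Effects (log2
per copy): tissue-restricted variants 2.0 on their HOX tasks and 1.5 on the
matching MEIS task; TGATTAAT 1.0 everywhere; TGACA 1.0 on MEIS and 0.5 on
HOX tasks; Forkhead 1.0 on the HOXA3-PBA tasks and 0.75 on MEIS-PBA
(mirroring the observed Forkhead dependence of posterior-arch binding);
bHLH 0.5 on the HOXA2-BA2 tasks. These values were fixed once as a
realistic strong-enhancer regime — per-task signal variance ≈ 0.5–1.5
against ≈ 0.05 noise — and give the CNN a learnable but non-trivial target.
Counts are Poisson with library size 5×10^7; FE is expected RPKM over a
0.5 RPKM background; acetylation log2 fold change is ρ·z + √(1−ρ²)·noise
with ρ = 0.73 against the standardized true MEIS PBA-vs-BA2 fold change,
and acetylation counts are Poisson around a 200-read base. `truth_check`
verifies every recorded planting verbatim and the count means against their
Poisson expectation.

What the generator does **not** emulate: mappability and GC biases,
fragment-level read placement, peak-calling artefacts, chromatin
accessibility, inter-motif spacing preferences and cooperative (non-additive)
motif interactions. Passing tests establish that the pipeline recovers
known structure from data of this statistical shape, not that the
biological conclusions transfer to any particular real dataset.

## Verification battery and problem sizes

The acceptance script regenerates everything from one seed: scanner vs
brute-force oracle on 1,000×1 kb sequences; TGATTCAT top-variant recovery
over 100 seeds of a 250+250-peak bundle; null FDR and p-value uniformity at
10^4 regions × 100 replicates with per-sample Poisson rate 500 (the survey
depth of the synthetic study); ρ-recovery at 5,000 regions (computed
without the |lfc| > 1 filter, since conditioning on the correlated variable
inflates r above the generator's coupling); CNN training at the full 6,795
regions (250 epochs, ≈ 10–12 min on one CPU) with 50-site Forkhead and GATA
knockout cohorts; and bit-level determinism checks. These sizes keep the
whole battery inside a coffee break while exercising every claim at the
scale it is stated for.
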