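# hoxtale

Analytics for paralog-selective HOX/TALE enhancer binding from ChIP-seq.

HOX transcription factors recognize nearly identical DNA sequences in
vitro, yet bind distinct genomic targets in vivo. In embryonic branchial
arches this selectivity is visible in the fine structure of the bipartite
HOX-PBX recognition site `TGATNNAT`: the 16 concretizations of its two
variable bases are used differently by HOX paralogs (e.g. `TGATTCAT` is
frequent among the strongest HOXA3 peaks and nearly absent from HOXA2
peaks), MEIS sites (`TGACA`) cluster within ~20 nt of HOX-PBX sites, and
tissue-specific cofactor motifs (Forkhead, GATA, bHLH) co-occur with HOX
sites in differentially bound enhancers. `hoxtale` implements the complete
computational toolkit for this kind of study:

- **Peak analytics** — fold-enrichment-ranked peak sets, 200 nt summit
  windows, overlap partitions and ranked-overlap curves, nearest-peak
  log10 distance tables, Welch comparison of FE distributions
  (`hoxtale.intervals`).
- **Motif scanning** — degenerate IUPAC consensus and exact k-mer (KSM)
  scanning with mismatch budgets, variant-count tables across FE bins,
  presence fractions, co-occurrence distances, candidate-site selection
  with cross-class exclusion, class-wise motif enrichment
  (`hoxtale.motifs`).
- **Differential binding** — consensus re-centring, read counting, log2
  RPKM, TMM normalization, exact conditional Poisson testing with BH
  control, six-class differential labels, correlation of differential
  binding with H3K27ac, ±100 kb gene association (`hoxtale.diffbind`).
- **Sequence-to-signal CNN** — a one-convolution-layer multitask regressor
  from 600 nt one-hot sequence to per-task log2 RPKM, with transfer
  learning and per-position sensitivity maps (`hoxtale.cnn`).
- **In-silico knockout** — 25 nt binding-site erasure by random
  dinucleotide replacement (100 repeats, background-normalized against
  motif-free control windows), with per-class Wilcoxon cohort statistics
  (`hoxtale.mutagenesis`).
- **Synthetic data** — a seeded generator producing genomes, peak sets,
  counts, acetylation signal and exact ground truth that mirrors the study
  design (tissue-specific variant usage, additive log2 motif effects,
  binding/acetylation coupling ρ = 0.73), so the entire pipeline is
  verifiable without restricted data (`hoxtale.synth`).

The statistical core and the regressor are implemented directly (numpy
forward/backward, Adam) — see `docs/methods.md` for the models, defaults
and their rationale, including the deliberate replacement of the edgeR
NB-GLM by a calibrated exact test.

## Worked example

Generate a two-tissue bundle and ask which `TGATNNAT` variant separates
the HOXA3 (posterior arches) peak set from the HOXA2 (second arch) set:

```sh
hoxtale simulate --seed 21 --n-regions 500 --out fixtures/
hoxtale variants --peaks fixtures/peaks_HOXA3_PBA_r1.narrowPeak \
                 --genome fixtures/genome.fa --top 250 | head -3
```

Programmatically:

```python
from hoxtale.synth import SynthConfig, generate
from hoxtale.motifs import count_variants

bundle = generate(SynthConfig(seed=21, n_regions=500,
                              tissue_probs=(0.0, 0.5, 0.5)))
sw = dict(zip(bundle.region_ids, bundle.summit_sequences()))
presence = {}
for name in ("HOXA3_PBA_r1", "HOXA2_BA2_r1"):
    peaks = bundle.peaksets[name].ranked()
    tab = count_variants(peaks, [sw[p.name] for p in peaks])
    presence[name] = tab.presence
diff = (presence["HOXA3_PBA_r1"] - presence["HOXA2_BA2_r1"])
print(diff.sort_values(ascending=False).head(3))
```

```
TGATTCAT    46
TGATTTAT    11
TGATTAAT     6
dtype: int64
```

46 of the 250 HOXA3-side peaks (≈ 18%, matching the planted 20% rate)
contain `TGATTCAT` while essentially none of the HOXA2-side peaks do — the
variant-selectivity signature the analysis is built to detect. The same
bundle feeds the differential test, the CNN and the knockout stages
(`hoxtale run --seed 21 --out results/` executes all of them and writes a
hashed manifest).

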