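"""Synthetic ChIP-seq data with fully known ground truth.

The generator emulates the statistical structure of a multi-tissue HOX/MEIS
binding study: fixed-width (600 nt) bound regions whose tissue context
(BA1 / BA2 / PBA) sets the planting probability of a catalogue of motifs
(HOX-PBX TGATNNAT variants, the MEIS pentamer, Forkhead, GATA, bHLH); an
additive linear model on the log2 scale turning motif counts into expected
per-task log2 RPKM; Poisson replicate counts; fold enrichments derived from
expected RPKM over a background rate; and an acetylation fold change coupled
to the true differential-binding fold change at a configurable correlation
(0.73 by default).

Planting probabilities follow the study design they emulate: the
PBA-selective variant TGATTCAT at 0.20 in PBA regions and 0 in BA2, the
BA2-preferred variants TGATGGAT/TGATTGAT at 0.25 each in BA2, Forkhead and
GATA at 0.30 in PBA, bHLH at 0.20 in BA2. Effect sizes are log2 units per
motif copy. Everything is driven by one seed; identical seeds give
bit-identical bundles.

Chance motif matches are part of the model: outside a ±25 nt guard around
planned plantings they are left in place, counted, and contribute to the
expected signal exactly like planted copies (signal is a function of the
final sequence). Inside the guard, chance HOX-PBX matches are rejected so
ground-truth bookkeeping stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import DEFAULT_TASKS
from .diffbind import CountMatrix, Sample
from .intervals import GenomicInterval, Peak, PeakSet, write_peaks
from .motifs import HOX_PBX, MotifPattern, revcomp, scan

__all__ = [
    "PlantedMotif",
    "SynthConfig",
    "Bundle",
    "default_motif_catalogue",
    "generate",
    "truth_check",
]

TISSUES = ("BA1", "BA2", "PBA")


@dataclass(frozen=True)
class PlantedMotif:
    """One catalogue entry with per-tissue planting probabilities and
    per-task additive effects (log2 units per copy).

    ``sequence`` may be a single consensus or a tuple of k-mers (a KSM-style
    set): each planting samples one member uniformly, and the effect count
    n_m is the total number of exact matches to *any* member (an N inside a
    k-mer is a one-position wildcard, instantiated at planting time).
    """

    name: str
    sequence: str | tuple
    feature_class: str                   # hoxpbx / meis / forkhead / gata / bhlh
    tissue_probs: dict                   # tissue -> probability
    betas: dict                          # task name -> log2 effect per copy
    placement_halfwindow: int = 150      # max |offset - region centre|

    @property
    def sequences(self) -> tuple:
        return (self.sequence,) if isinstance(self.sequence, str) else tuple(self.sequence)

    @property
    def max_length(self) -> int:
        return max(len(s) for s in self.sequences)


def default_motif_catalogue() -> list[PlantedMotif]:
    """The default study-like catalogue (probabilities per tissue context)."""
    hox2 = {"HOXA2_BA2_r1": 2.0, "HOXA2_BA2_r2": 2.0, "MEIS_BA2_r1": 1.5}
    hox3 = {"HOXA3_PBA_r1": 2.0, "HOXA3_PBA_r2": 2.0, "MEIS_PBA_r1": 1.5}
    all_tasks = {s.name: 1.0 for s in DEFAULT_TASKS}
    meis_b = {s.name: (1.0 if s.factor == "MEIS" else 0.5) for s in DEFAULT_TASKS}
    fork = {"HOXA3_PBA_r1": 1.0, "HOXA3_PBA_r2": 1.0, "MEIS_PBA_r1": 0.75}
    bhlh = {"HOXA2_BA2_r1": 0.5, "HOXA2_BA2_r2": 0.5}
    return [
        PlantedMotif("TGATTCAT", "TGATTCAT", "hoxpbx", {"PBA": 0.20, "BA2": 0.0},
                     hox3, 90),
        PlantedMotif("TGATGGAT", "TGATGGAT", "hoxpbx", {"BA2": 0.25}, hox2, 90),
        PlantedMotif("TGATTGAT", "TGATTGAT", "hoxpbx", {"BA2": 0.25}, hox2, 90),
        PlantedMotif("TGATTAAT", "TGATTAAT", "hoxpbx",
                     {"BA1": 0.30, "BA2": 0.30, "PBA": 0.30}, all_tasks, 90),
        PlantedMotif("TGACA", "TGACA", "meis",
                     {"BA1": 0.40, "BA2": 0.40, "PBA": 0.40}, meis_b, 150),
        PlantedMotif("Forkhead", (
            "AAAATAAACA", "AAAAATAAAC", "AATAAATCAA", "ATNAATCAACA",
            "AAATAAACAC", "ATAAATCAAC", "GAAAATAAAC", "CAAAATAAAC",
            "AAAATAAACT", "AAATAAACAA"), "forkhead", {"PBA": 0.30}, fork, 150),
        PlantedMotif("GATA", "AGATAA", "gata", {"PBA": 0.30}, {}, 150),
        PlantedMotif("bHLH", "CATCTG", "bhlh", {"BA2": 0.20}, bhlh, 150),
    ]


@dataclass
class SynthConfig:
    """Generator configuration; the defaults are the study conditions.

    ``baseline_log2rpkm`` (b0), ``region_sd`` (region-level Gaussian noise
    shared across tasks) and ``replicate_sd`` (per task column) are in log2
    RPKM units. ``acetyl_rho`` couples acetylation fold change to true
    differential MEIS binding (PBA vs BA2).
    """

    seed: int
    n_regions: int = 6795
    region_width: int = 600
    n_chromosomes: int = 4
    spacer: int = 200
    gc_content: float = 0.41
    tissue_probs: tuple = (1 / 3, 1 / 3, 1 / 3)     # BA1, BA2, PBA
    motifs: list = field(default_factory=default_motif_catalogue)
    baseline_log2rpkm: float = 2.0
    region_sd: float = 0.15
    replicate_sd: float = 0.10
    library_size: float = 5e7
    acetyl_rho: float = 0.73
    acetyl_base_count: float = 200.0
    acetyl_library: float = 1e7
    fe_background_rpkm: float = 0.5
    min_gap: int = 5
    guard: int = 25

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not np.isclose(sum(self.tissue_probs), 1.0):
            raise ValueError("tissue_probs must sum to 1")
        for m in self.motifs:
            for p in m.tissue_probs.values():
                if not 0 <= p <= 1:
                    raise ValueError(f"bad planting probability for {m.name}")


@dataclass
class Bundle:
    """In-memory fixture bundle with full ground truth."""

    config: SynthConfig
    regions: list[GenomicInterval]
    region_ids: list[str]
    sequences: list[str]
    tissues: np.ndarray                 # per-region tissue context
    chromosomes: dict                   # chrom -> full sequence
    tasks: tuple                        # Sample tuple, order fixed
    mu: np.ndarray                      # (n_regions, n_tasks) expected log2 RPKM
    counts: CountMatrix
    peaksets: dict                      # task name -> PeakSet
    binding_lfc: np.ndarray             # true MEIS PBA-vs-BA2 log2 fold change
    acetyl_lfc: np.ndarray
    acetyl_counts: pd.DataFrame         # columns PBA, BA2
    truth: list                         # per-region dicts (plantings, counts, class)

    def observed_log2_rpkm(self, pseudocount: float = 0.5) -> np.ndarray:
        from .diffbind import rpkm
        return rpkm(self.counts, pseudocount).log2_rpkm

    def summit_sequences(self, width: int = 200) -> list[str]:
        half = width // 2
        c = self.config.region_width // 2
        return [s[c - half:c + half] for s in self.sequences]

    def write(self, outdir) -> dict:
        """Write the bundle as text files; returns {name: path}."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        fa = out / "genome.fa"
        with open(fa, "w") as fh:
            for chrom, seq in self.chromosomes.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths["genome"] = fa
        bed = out / "regions.bed"
        with open(bed, "w") as fh:
            for rid, r in zip(self.region_ids, self.regions):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{rid}\n")
        paths["regions"] = bed
        for name, ps in self.peaksets.items():
            p = out / f"peaks_{name}.narrowPeak"
            write_peaks(p, ps)
            paths[f"peaks_{name}"] = p
        counts = pd.DataFrame(self.counts.counts, index=self.region_ids,
                              columns=[s.name for s in self.counts.samples])
        cpath = out / "counts.tsv"
        counts.to_csv(cpath, sep="\t", index_label="region_id")
        paths["counts"] = cpath
        ac = self.acetyl_counts.copy()
        ac["binding_lfc_true"] = self.binding_lfc
        ac["acetyl_lfc_true"] = self.acetyl_lfc
        apath = out / "acetylation.tsv"
        ac.to_csv(apath, sep="\t", index_label="region_id")
        paths["acetylation"] = apath
        tpath = out / "ground_truth.json"
        with open(tpath, "w") as fh:
            json.dump({"config": _config_dict(self.config), "regions": self.truth},
                      fh)
        paths["truth"] = tpath
        return paths


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["motifs"] = [asdict(m) for m in cfg.motifs]
    return d


def _count_matches(seq: str, motif_seqs) -> int:
    """Total exact both-strand matches to any member sequence.

    Multi-member hits at the same (offset, strand) are counted once.
    """
    if isinstance(motif_seqs, str):
        motif_seqs = (motif_seqs,)
    found = set()
    for ms in motif_seqs:
        for h in scan(seq, MotifPattern("m", ms, 0), "both"):
            found.add((h.offset, h.strand))
    return len(found)


def _plant_region(rng: np.random.Generator, cfg: SynthConfig, tissue: str):
    """Choose plantings (motif, offset, strand) for one region."""
    width = cfg.region_width
    center = width // 2
    spans: list[tuple[int, int]] = []
    plantings = []
    for m in cfg.motifs:
        p = m.tissue_probs.get(tissue, 0.0)
        if rng.random() >= p:
            continue
        member = m.sequences[int(rng.integers(len(m.sequences)))]
        if "N" in member:
            member = "".join(c if c != "N" else "ACGT"[int(rng.integers(4))]
                             for c in member)
        L = len(member)
        h = min(m.placement_halfwindow, width // 2 - L)
        placed = False
        for _ in range(200):
            off = int(rng.integers(center - h, center + h - L + 1))
            if all(off >= e + cfg.min_gap or off + L + cfg.min_gap <= s
                   for s, e in spans):
                placed = True
                break
        if not placed:
            raise RuntimeError(f"infeasible planting density for {m.name}")
        strand = "+" if rng.random() < 0.5 else "-"
        spans.append((off, off + L))
        plantings.append({"name": m.name, "class": m.feature_class,
                          "offset": off, "strand": strand,
                          "sequence": member})
    return plantings


def _guard_cleanup(seq_arr: np.ndarray, plantings, cfg: SynthConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Destroy chance HOX-PBX matches inside the guard around plantings."""
    if not plantings:
        return seq_arr
    planted_spans = [(p["offset"], p["offset"] + len(p["sequence"]))
                     for p in plantings]
    guards = [(max(0, s - cfg.guard), e + cfg.guard) for s, e in planted_spans]
    bases = np.array(list("ACGT"))
    for _ in range(20):
        seq = "".join(seq_arr)
        dirty = []
        for h in scan(seq, HOX_PBX, "both"):
            span = (h.offset, h.end)
            # matches lying fully inside a planted motif are intrinsic to
            # that motif's sequence, not chance background; leave them
            if any(span[0] >= s and span[1] <= e for s, e in planted_spans):
                continue
            if any(span[0] < ge and span[1] > gs for gs, ge in guards):
                dirty.append(span)
        if not dirty:
            return seq_arr
        for s, e in dirty:
            # mutate one base of the chance match that is outside every
            # planted span
            free = [i for i in range(s, e)
                    if not any(ps <= i < pe for ps, pe in planted_spans)]
            if not free:
                continue
            i = free[int(rng.integers(len(free)))]
            choices = bases[bases != seq_arr[i]]
            seq_arr[i] = choices[int(rng.integers(len(choices)))]
    return seq_arr


def generate(config: SynthConfig) -> Bundle:
    """Generate a complete fixture bundle from one seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    width = cfg.region_width
    tasks = DEFAULT_TASKS
    task_names = [s.name for s in tasks]
    n = cfg.n_regions

    # deterministic tissue composition (exact proportions), shuffled
    counts_per = np.floor(np.asarray(cfg.tissue_probs) * n).astype(int)
    while counts_per.sum() < n:
        counts_per[int(np.argmax(np.asarray(cfg.tissue_probs) * n - counts_per))] += 1
    tissues = np.repeat(TISSUES, counts_per)
    rng.shuffle(tissues)

    gc = cfg.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    sequences, truth, region_ids = [], [], []
    beta = np.zeros((len(cfg.motifs), len(tasks)))
    for mi, m in enumerate(cfg.motifs):
        for ti, tname in enumerate(task_names):
            beta[mi, ti] = m.betas.get(tname, 0.0)

    motif_counts = np.zeros((n, len(cfg.motifs)), dtype=int)
    for i in range(n):
        rid = f"r{i:05d}"
        region_ids.append(rid)
        plantings = _plant_region(rng, cfg, tissues[i])
        seq_arr = rng.choice(bases, size=width, p=base_probs)
        for p in plantings:
            ins = p["sequence"] if p["strand"] == "+" else revcomp(p["sequence"])
            seq_arr[p["offset"]:p["offset"] + len(ins)] = list(ins)
        seq_arr = _guard_cleanup(seq_arr, plantings, cfg, rng)
        seq = "".join(seq_arr)
        sequences.append(seq)
        for mi, m in enumerate(cfg.motifs):
            motif_counts[i, mi] = _count_matches(seq, m.sequence)
        truth.append({"region_id": rid, "tissue": str(tissues[i]),
                      "plantings": plantings,
                      "motif_counts": {m.name: int(motif_counts[i, mi])
                                       for mi, m in enumerate(cfg.motifs)}})

    # expected log2 RPKM: additive effects + shared region noise + replicate noise
    det = cfg.baseline_log2rpkm + motif_counts @ beta           # (n, T)
    eps = rng.normal(0.0, cfg.region_sd, size=n)
    rep = rng.normal(0.0, cfg.replicate_sd, size=(n, len(tasks)))
    mu = det + eps[:, None] + rep

    lam = 2.0 ** mu * (width / 1e3) * (cfg.library_size / 1e6)
    counts = rng.poisson(lam).astype(np.int64)

    # genome assembly: regions laid out with random spacers
    per_chrom = [[] for _ in range(cfg.n_chromosomes)]
    for i in range(n):
        per_chrom[i % cfg.n_chromosomes].append(i)
    chromosomes, regions = {}, [None] * n
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chrS{ci + 1}"
        parts, pos = [], 0
        for i in idxs:
            sp = "".join(rng.choice(bases, size=cfg.spacer, p=base_probs))
            parts.append(sp)
            pos += cfg.spacer
            regions[i] = GenomicInterval(chrom, pos, pos + width)
            parts.append(sequences[i])
            pos += width
        parts.append("".join(rng.choice(bases, size=cfg.spacer, p=base_probs)))
        chromosomes[chrom] = "".join(parts)

    cm = CountMatrix(regions, list(tasks), counts,
                     np.full(len(tasks), cfg.library_size))

    # per-sample peak sets: HOXA2 peaks in BA2 regions, HOXA3 in PBA, MEIS in
    # all; FE = expected RPKM over background RPKM
    fe = 2.0 ** (det + eps[:, None]) / cfg.fe_background_rpkm   # (n, T)
    peaksets = {}
    for ti, s in enumerate(tasks):
        if s.factor == "HOXA2":
            members = np.nonzero(tissues == "BA2")[0]
        elif s.factor == "HOXA3":
            members = np.nonzero(tissues == "PBA")[0]
        else:
            members = np.arange(n)
        peaks = [Peak(regions[i], regions[i].center, float(fe[i, ti]),
                      region_ids[i]) for i in members]
        peaksets[s.name] = PeakSet(peaks, label=s.name, genome_id="synth")

    # acetylation coupled to true differential MEIS binding (PBA vs BA2)
    i_pba = task_names.index("MEIS_PBA_r1")
    i_ba2 = task_names.index("MEIS_BA2_r1")
    binding_lfc = det[:, i_pba] - det[:, i_ba2]
    sd = binding_lfc.std()
    z = (binding_lfc - binding_lfc.mean()) / (sd if sd > 0 else 1.0)
    rho = cfg.acetyl_rho
    acetyl_lfc = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    lam_p = cfg.acetyl_base_count * 2.0 ** (acetyl_lfc / 2)
    lam_b = cfg.acetyl_base_count * 2.0 ** (-acetyl_lfc / 2)
    acetyl_counts = pd.DataFrame({"PBA": rng.poisson(lam_p),
                                  "BA2": rng.poisson(lam_b)}, index=region_ids)

    # true differential class from deterministic MEIS log2 RPKM per tissue
    meis_idx = {t: task_names.index(f"MEIS_{t}_r1") for t in TISSUES}
    for i, rec in enumerate(truth):
        label = "ns"
        for t in TISSUES:
            others = [o for o in TISSUES if o != t]
            d = [det[i, meis_idx[t]] - det[i, meis_idx[o]] for o in others]
            if all(x >= 1 for x in d):
                label = f"{t}_up"
            elif all(x <= -1 for x in d):
                label = f"{t}_down"
        rec["true_class"] = label
        rec["expected_log2rpkm"] = {tn: float(mu[i, ti])
                                    for ti, tn in enumerate(task_names)}
        rec["binding_lfc"] = float(binding_lfc[i])
        rec["acetyl_lfc"] = float(acetyl_lfc[i])

    return Bundle(cfg, regions, region_ids, sequences, tissues, chromosomes,
                  tasks, mu, cm, peaksets, binding_lfc, acetyl_lfc,
                  acetyl_counts, truth)


@dataclass
class TruthReport:
    ok: bool
    failures: list


def truth_check(bundle: Bundle) -> TruthReport:
    """Validate a bundle against its own ground truth.

    Checks that every recorded planting is literally present in the emitted
    sequence (on the recorded strand), that recorded motif counts match a
    fresh scan, and that per-task mean observed counts are within 3 standard
    errors of the Poisson expectation.
    """
    failures = []
    name_to_seq = {m.name: m.sequence for m in bundle.config.motifs}
    for rec, seq in zip(bundle.truth, bundle.sequences):
        for p in rec["plantings"]:
            ins = p["sequence"] if p["strand"] == "+" else revcomp(p["sequence"])
            found = seq[p["offset"]:p["offset"] + len(ins)]
            if found != ins:
                failures.append(
                    f"{rec['region_id']}: planting {p['name']} at {p['offset']} "
                    f"expected {ins}, found {found}")
        for mname, cnt in rec["motif_counts"].items():
            if _count_matches(seq, name_to_seq[mname]) != cnt:
                failures.append(f"{rec['region_id']}: stale count for {mname}")
    width = bundle.config.region_width
    lam = (2.0 ** bundle.mu * (width / 1e3)
           * (bundle.config.library_size / 1e6))
    nreg = len(bundle.regions)
    for ti, s in enumerate(bundle.tasks):
        expect = lam[:, ti].sum() / nreg
        se = np.sqrt(lam[:, ti].sum()) / nreg
        obs = bundle.counts.counts[:, ti].mean()
        if abs(obs - expect) > 3 * se:
            failures.append(f"task {s.name}: mean count {obs:.2f} vs "
                            f"expected {expect:.2f} (3SE={3 * se:.3f})")
    return TruthReport(not failures, failures)
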