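"""Degenerate-consensus and k-mer motif scanning.

The motifs of interest are short consensus sequences written in IUPAC codes:
the bipartite HOX-PBX site TGATNNAT (whose 16 NN concretizations are the
"variants" whose differential usage distinguishes HOX paralogs), the MEIS
pentamer TGACA, the GATA consensus WGATAA, and Forkhead sites represented
either as the TACAAA consensus or as an exact k-mer set (KSM-style).

Scanning semantics: a window matches when the number of mismatches at
*fixed* (non-N) pattern positions is within the pattern's mismatch budget;
N positions in the pattern are free and match any base, while an N in the
genome never satisfies a fixed position. Both strands are scanned by
default; reverse-strand hits report their matched sequence in motif
orientation (reverse complement of the genomic window), so variant counts
pool the two strands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

__all__ = [
    "IUPAC",
    "MotifPattern",
    "KmerSet",
    "MotifHit",
    "VariantCountTable",
    "HOX_PBX",
    "MEIS",
    "GATA",
    "FORKHEAD_CONSENSUS",
    "BHLH",
    "FORKHEAD_KMERS",
    "revcomp",
    "enumerate_variants",
    "scan",
    "count_variants",
    "presence_fraction",
    "pair_distances",
    "select_candidate_sites",
    "select_knockout_pairs",
    "class_motif_enrichment",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# base -> bitmask; genomic N carries no bits so it never satisfies a fixed
# pattern position
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}
_PAT_BITS = {c: sum(_BASE_BITS[b] for b in bases) for c, bases in IUPAC.items()}

_SEQ_LUT = np.full(256, -1, dtype=np.int16)
for _b, _v in _BASE_BITS.items():
    _SEQ_LUT[ord(_b)] = _v
_BIT_COMP = {0: 0, 1: 8, 2: 4, 4: 2, 8: 1}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def _encode_seq(seq: str) -> np.ndarray:
    arr = _SEQ_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


@dataclass(frozen=True, slots=True)
class MotifPattern:
    """Degenerate consensus with a mismatch budget.

    Mismatches are counted only at fixed (non-N) positions; ``max_mismatch=1``
    on TGATNNAT therefore means at most one of the six fixed bases differs.
    """

    name: str
    iupac: str
    max_mismatch: int = 0

    def __post_init__(self):
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class KmerSet:
    """Exact-match k-mer set representation of a motif.

    An N inside a k-mer is a single-position wildcard. Duplicates are
    removed, order preserved.
    """

    name: str
    kmers: tuple[str, ...]

    def __init__(self, name: str, kmers):
        object.__setattr__(self, "name", name)
        seen, uniq = set(), []
        for k in kmers:
            k = k.upper()
            if set(k) - set("ACGTN"):
                raise ValueError(f"k-mer {k!r} has characters outside ACGTN")
            if k not in seen:
                seen.add(k)
                uniq.append(k)
        object.__setattr__(self, "kmers", tuple(uniq))

    def patterns(self) -> list[MotifPattern]:
        return [MotifPattern(self.name, k, 0) for k in self.kmers]


@dataclass(frozen=True, slots=True)
class MotifHit:
    """A located, stranded motif match within a region."""

    region_id: str
    offset: int           # 0-based window start within the region
    strand: str           # "+" or "-"
    matched_variant: str  # concrete sequence in motif orientation
    mismatches: int
    pattern: str = ""     # name of the pattern or k-mer set
    length: int = 0

    @property
    def end(self) -> int:
        return self.offset + (self.length or len(self.matched_variant))


# Shared motif definitions
HOX_PBX = MotifPattern("HOX-PBX", "TGATNNAT", 0)
MEIS = MotifPattern("MEIS", "TGACA", 0)
GATA = MotifPattern("GATA", "WGATAA", 0)
FORKHEAD_CONSENSUS = MotifPattern("Forkhead", "TACAAA", 0)
BHLH = MotifPattern("bHLH", "CATCTG", 0)
FORKHEAD_KMERS = KmerSet("Forkhead", [
    "AAAATAAACA", "AAAAATAAAC", "AATAAATCAA", "ATNAATCAACA", "AAATAAACAC",
    "ATAAATCAAC", "GAAAATAAAC", "CAAAATAAAC", "AAAATAAACT", "AAATAAACAA",
])

#: the recognized site classes, for cross-class exclusion windows
SITE_CLASSES = {"hoxpbx": HOX_PBX, "meis": MEIS, "forkhead": FORKHEAD_KMERS,
                "gata": GATA, "bhlh": BHLH}


def cross_class_exclusion(own_class: str) -> list:
    """Patterns of every known site class except the candidate's own."""
    return [p for c, p in SITE_CLASSES.items() if c != own_class]


def enumerate_variants(pattern: MotifPattern) -> list[str]:
    """All concrete sequences of a degenerate pattern (Cartesian expansion)."""
    choices = [IUPAC[c] for c in pattern.iupac]
    return ["".join(t) for t in itertools.product(*choices)]


def _scan_one_orientation(bits: np.ndarray, pattern_iupac: str,
                          max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
    """Window offsets and mismatch counts for one pattern orientation."""
    L = len(pattern_iupac)
    n = bits.size - L + 1
    if n <= 0:
        return np.empty(0, int), np.empty(0, int)
    pmask = np.array([_PAT_BITS[c] for c in pattern_iupac], dtype=np.int16)
    fixed = np.array([c != "N" for c in pattern_iupac])
    win = np.lib.stride_tricks.sliding_window_view(bits, L)
    if fixed.any():
        mism = ((win[:, fixed] & pmask[fixed]) == 0).sum(axis=1)
    else:
        mism = np.zeros(n, dtype=int)
    idx = np.nonzero(mism <= max_mismatch)[0]
    return idx, mism[idx]


def scan(seq: str, pattern, strands: str = "both",
         region_id: str = "") -> list[MotifHit]:
    """All motif hits in ``seq``, sorted by offset then strand.

    ``pattern`` is a :class:`MotifPattern` or a :class:`KmerSet` (scanned as
    a union of exact patterns; duplicate (offset, strand) hits from different
    k-mers are all reported). ``strands`` is ``"both"`` or ``"forward"``.
    """
    if isinstance(pattern, KmerSet):
        hits = []
        for p in pattern.patterns():
            hits.extend(scan(seq, p, strands, region_id))
        hits.sort(key=lambda h: (h.offset, h.strand, h.matched_variant))
        return hits
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    seq = seq.upper()
    bits = _encode_seq(seq)
    if len(pattern) > len(seq):
        return []
    hits = []
    idx, mm = _scan_one_orientation(bits, pattern.iupac, pattern.max_mismatch)
    for o, m in zip(idx, mm):
        hits.append(MotifHit(region_id, int(o), "+",
                             seq[o:o + len(pattern)], int(m),
                             pattern.name, len(pattern)))
    if strands == "both":
        rc_pat = revcomp(pattern.iupac)
        idx, mm = _scan_one_orientation(bits, rc_pat, pattern.max_mismatch)
        for o, m in zip(idx, mm):
            hits.append(MotifHit(region_id, int(o), "-",
                                 revcomp(seq[o:o + len(pattern)]), int(m),
                                 pattern.name, len(pattern)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _check_ranked(peaks: PeakSet):
    fes = peaks.fold_enrichments()
    if np.any(np.diff(fes) > 0):
        raise ValueError("peaks must be FE-ranked (decreasing); call .ranked() "
                         "and align sequences accordingly")


@dataclass(slots=True)
class VariantCountTable:
    """Per-variant hit counts across FE-ordered peak bins.

    ``counts`` holds all exact hits (both strands), ``presence`` the number
    of peaks containing each variant at least once.
    """

    counts: pd.DataFrame          # variants x bins, hit counts
    presence: pd.Series           # variant -> n peaks with >=1 hit
    pattern: MotifPattern
    bin_size: int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def count_variants(peaks: PeakSet, seqs: list[str], bin_size: int = 50,
                   pattern: MotifPattern = HOX_PBX,
                   strands: str = "both") -> VariantCountTable:
    """Count concrete variants of a degenerate motif across FE bins.

    ``peaks`` must be FE-ranked with one summit-window sequence per peak in
    the same order; peaks are grouped into consecutive bins of ``bin_size``
    by decreasing FE. Only exact (0-mismatch) hits are attributed; hits
    whose free positions contain genomic N match no concrete variant and
    are ignored.
    """
    if len(seqs) != len(peaks):
        raise ValueError(f"{len(peaks)} peaks but {len(seqs)} sequences")
    _check_ranked(peaks)
    variants = enumerate_variants(pattern)
    exact = MotifPattern(pattern.name, pattern.iupac, 0)
    n_bins = (len(seqs) + bin_size - 1) // bin_size
    labels = [f"{i * bin_size + 1}-{min((i + 1) * bin_size, len(seqs))}"
              for i in range(n_bins)]
    counts = pd.DataFrame(0, index=variants, columns=labels, dtype=int)
    presence = pd.Series(0, index=variants, dtype=int)
    vset = set(variants)
    for i, s in enumerate(seqs):
        col = labels[i // bin_size]
        seen = set()
        for h in scan(s, exact, strands):
            if h.matched_variant in vset:
                counts.loc[h.matched_variant, col] += 1
                seen.add(h.matched_variant)
        for v in seen:
            presence[v] += 1
    return VariantCountTable(counts, presence, pattern, bin_size)


def presence_fraction(peaks: PeakSet, seqs: list[str], pattern: MotifPattern,
                      topNs: list[int], strands: str = "both",
                      exact_mismatch: bool = False) -> pd.DataFrame:
    """Fraction of the top-N peaks containing at least one hit.

    The mismatch budget comes from ``pattern.max_mismatch``; with
    ``exact_mismatch`` only hits at exactly that mismatch count qualify
    (the "low-affinity sites only" reading, excluding perfect matches).
    Peaks must be FE-ranked and aligned with ``seqs``.
    """
    if len(seqs) != len(peaks):
        raise ValueError(f"{len(peaks)} peaks but {len(seqs)} sequences")
    _check_ranked(peaks)
    if max(topNs) > len(peaks):
        raise ValueError(f"max N {max(topNs)} exceeds {len(peaks)} peaks")
    mm = pattern.max_mismatch
    has_hit = np.array([
        any(h.mismatches == mm for h in scan(s, pattern, strands))
        if exact_mismatch else bool(scan(s, pattern, strands))
        for s in seqs])
    rows = [(n, float(has_hit[:n].mean())) for n in sorted(topNs)]
    return pd.DataFrame(rows, columns=["N", "fraction"])


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open spans (0 when they overlap)."""
    return max(0, b_start - a_end, a_start - b_end)


def pair_distances(hitsA: list[MotifHit], hitsB: list[MotifHit]
                   ) -> tuple[pd.DataFrame, int]:
    """Minimal edge-to-edge gap from each A-hit to any B-hit in its region.

    Regions containing A-hits but no B-hits are excluded; their count is
    returned alongside the table.
    """
    by_region_b: dict[str, list[MotifHit]] = {}
    for h in hitsB:
        by_region_b.setdefault(h.region_id, []).append(h)
    rows, excluded = [], set()
    for h in hitsA:
        bs = by_region_b.get(h.region_id)
        if not bs:
            excluded.add(h.region_id)
            continue
        gaps = [(_gap(h.offset, h.end, b.offset, b.end), b) for b in bs]
        g, bbest = min(gaps, key=lambda t: t[0])
        rows.append((h.region_id, h.offset, h.strand, bbest.offset,
                     bbest.strand, g))
    df = pd.DataFrame(rows, columns=["region_id", "a_offset", "a_strand",
                                     "b_offset", "b_strand", "gap"])
    return df, len(excluded)


def select_candidate_sites(region_ids: list[str], seqs: list[str], motif,
                           summit_offsets: list[int] | None = None,
                           summit_halfwindow: int = 250,
                           exclude_internal=HOX_PBX,
                           exclude_window: int | None = 25,
                           deduplicate_overlapping: bool = True,
                           strands: str = "both") -> list[MotifHit]:
    """Motif instances within ±``summit_halfwindow`` of each region's summit.

    ``summit_offsets`` gives the summit position within each sequence
    (defaults to the sequence midpoint). Candidates containing a match to
    ``exclude_internal`` — a pattern, k-mer set, or list of either (HOX-PBX
    by default) — are removed, so Forkhead/GATA candidates never double as
    HOX-PBX sites. ``exclude_window`` widens the checked span to the
    erasure-site width centred on the candidate (25 nt by default), so that
    knocking out the candidate cannot clip another known site and the
    predicted change stays attributable to the candidate itself. Pass
    ``exclude_window=None`` to check only the matched span, or
    ``exclude_internal=None`` to disable entirely (e.g. when selecting the
    HOX-PBX sites themselves). Overlapping hits in one region (common with
    heavily overlapping k-mer sets, where one genomic site matches several
    members at shifted offsets) are one physical site; by default each such
    cluster is reduced to its most central hit so downstream cohorts do not
    pseudo-replicate sites.
    """
    if len(region_ids) != len(seqs):
        raise ValueError("region_ids and seqs must align")
    if exclude_internal is None:
        excl = []
    elif isinstance(exclude_internal, (MotifPattern, KmerSet)):
        excl = [exclude_internal]
    else:
        excl = list(exclude_internal)
    min_excl_len = min((len(p.iupac) if isinstance(p, MotifPattern)
                        else min(len(k) for k in p.kmers))
                       for p in excl) if excl else 0
    out = []
    for i, (rid, s) in enumerate(zip(region_ids, seqs)):
        summit = summit_offsets[i] if summit_offsets is not None else len(s) // 2
        lo, hi = summit - summit_halfwindow, summit + summit_halfwindow
        for h in scan(s, motif, strands, region_id=rid):
            if h.offset < lo or h.end > hi:
                continue
            if excl:
                if exclude_window is None:
                    ws, we = h.offset, h.end
                else:
                    mid = (h.offset + h.end + 1) // 2
                    ws = max(0, mid - (exclude_window + 1) // 2)
                    we = min(len(s), ws + exclude_window)
                window = s[ws:we]
                if len(window) >= min_excl_len and any(
                        scan(window, p, "both") for p in excl):
                    continue
            out.append(h)
    if deduplicate_overlapping:
        out = _dedup_overlapping(out)
    return out


def _dedup_overlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Reduce each cluster of overlapping same-region hits to one hit."""
    by_region: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_region.setdefault(h.region_id, []).append(h)
    kept = []
    for rid in by_region:
        hs = sorted(by_region[rid], key=lambda h: (h.offset, h.end))
        cluster: list[MotifHit] = []
        cl_end = -1

        def _flush():
            if not cluster:
                return
            lo = min(h.offset for h in cluster)
            hi = max(h.end for h in cluster)
            mid = (lo + hi) / 2
            kept.append(min(cluster,
                            key=lambda h: (abs((h.offset + h.end) / 2 - mid),
                                           h.offset)))

        for h in hs:
            if not cluster or h.offset < cl_end:
                cluster.append(h)
                cl_end = max(cl_end, h.end)
            else:
                _flush()
                cluster = [h]
                cl_end = h.end
        _flush()
    kept.sort(key=lambda h: (h.region_id, h.offset))
    return kept


def select_knockout_pairs(hox_sites: list[MotifHit], other_sites: list[MotifHit],
                          dmin: int = 1, dmax: int = 100) -> pd.DataFrame:
    """Pair each non-HOX site with its nearest HOX site at gap in [dmin, dmax].

    Gap is edge-to-edge; abutting or overlapping sites (gap 0) are excluded
    under the default ``dmin=1``. Each non-HOX site is paired at most once.
    """
    by_region: dict[str, list[MotifHit]] = {}
    for h in hox_sites:
        by_region.setdefault(h.region_id, []).append(h)
    rows = []
    for o in other_sites:
        hs = by_region.get(o.region_id)
        if not hs:
            continue
        gaps = [(_gap(o.offset, o.end, h.offset, h.end), h) for h in hs]
        g, hbest = min(gaps, key=lambda t: t[0])
        if dmin <= g <= dmax:
            rows.append((o.region_id, o.offset, o.end, o.strand, o.pattern,
                         o.matched_variant, hbest.offset, hbest.end, g))
    return pd.DataFrame(rows, columns=[
        "region_id", "offset", "end", "strand", "pattern", "matched_variant",
        "hox_offset", "hox_end", "gap",
    ])


def class_motif_enrichment(classes: dict[str, list[str]], patterns: list,
                           strands: str = "both") -> pd.DataFrame:
    """Motif-presence enrichment of each pattern in each region class.

    The background is the union of all classes. For a class of size n with k
    regions containing the motif, against K of N background regions, the
    enrichment p-value is the hypergeometric upper tail P(X >= k); q-values
    are Benjamini-Hochberg across all (class, pattern) cells.
    """
    from .diffbind import bh_fdr

    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for label, seqs in classes.items():
        if len(seqs) == 0:
            raise ValueError(f"empty class {label!r}")
    motif_names = []
    presence: dict[str, np.ndarray] = {}
    labels_per_region, all_seqs = [], []
    for label, seqs in classes.items():
        labels_per_region.extend([label] * len(seqs))
        all_seqs.extend(seqs)
    for pat in patterns:
        name = pat.name
        motif_names.append(name)
        presence[name] = np.array(
            [bool(scan(s, pat, strands)) for s in all_seqs]
        )
    labels_arr = np.array(labels_per_region)
    N = len(all_seqs)
    rows = []
    for label in classes:
        in_class = labels_arr == label
        n = int(in_class.sum())
        for name in motif_names:
            K = int(presence[name].sum())
            k = int(presence[name][in_class].sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append((label, name, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["class", "pattern", "k", "n", "K", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
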