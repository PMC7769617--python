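"""Genomic intervals, peak sets, and summit-window analytics.

Coordinates are 0-based half-open (BED convention) throughout. Peaks carry a
summit (the base with maximal pile-up, as reported by MACS2) and a fold
enrichment (FE, signal over background), the quantity every ranking in this
package uses. The central operations are fixed-width summit windows, overlap
partitioning of two peak sets ("shared" means the 200 nt summit windows
intersect by at least ``min_overlap`` bases), ranked-overlap curves over
FE-ordered prefixes, and nearest-peak distance tables with log10 binning.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "SummitWindow",
    "OverlapPartition",
    "PeakParseError",
    "read_peaks",
    "write_peaks",
    "summit_window",
    "overlap_partition",
    "ranked_overlap_curve",
    "nearest_distance",
    "extract_sequences",
    "fe_distribution_compare",
]


class PeakParseError(ValueError):
    """A peak file row could not be parsed; the message names the line."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates; ``end > start >= 0``.
    strand : str
        One of ``+``, ``-``, ``.`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class Peak:
    """A ChIP-seq peak: an interval plus summit and fold enrichment."""

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    name: str = ""

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval {self.interval}"
            )
        if not self.fold_enrichment > 0:
            raise ValueError(f"fold_enrichment must be > 0, got {self.fold_enrichment}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def _rank_key(p: Peak):
    # FE ties broken by (chrom, start, name) so "top N" is deterministic.
    return (-p.fold_enrichment, p.chrom, p.interval.start, p.name)


@dataclass(slots=True)
class PeakSet:
    """An ordered collection of peaks from one factor/tissue experiment."""

    peaks: list[Peak]
    label: str = ""
    genome_id: str = ""

    def __post_init__(self):
        seen = set()
        for p in self.peaks:
            key = (p.chrom, p.summit)
            if key in seen:
                raise ValueError(
                    f"duplicate (chrom, summit) {key} in peak set {self.label!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def ranked(self) -> "PeakSet":
        """Peaks sorted by decreasing FE (deterministic tie-break)."""
        return replace(self, peaks=sorted(self.peaks, key=_rank_key))

    def top(self, n: int) -> "PeakSet":
        if n > len(self.peaks):
            raise ValueError(f"top {n} requested but set has {len(self.peaks)} peaks")
        return replace(self, peaks=self.ranked().peaks[:n])

    def fold_enrichments(self) -> np.ndarray:
        return np.array([p.fold_enrichment for p in self.peaks], dtype=float)


# ---------------------------------------------------------------------------
# I/O


def _parse_row(fields: list[str], lineno: int, dialect: str,
               summit_col: int, fe_col: int, one_based: bool) -> Peak:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
        if one_based:
            start -= 1
        if dialect == "narrowPeak":
            fe = float(fields[6])
            offset = int(fields[9])
            summit = start + offset if offset >= 0 else (start + end) // 2
        else:  # bed_summit_fe
            summit = int(fields[summit_col])
            if one_based:
                summit -= 1
            fe = float(fields[fe_col])
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    except (IndexError, ValueError) as exc:
        raise PeakParseError(f"line {lineno}: cannot parse row under dialect "
                             f"{dialect!r}: {exc}") from exc
    if not (start <= summit < end):
        raise PeakParseError(f"line {lineno}: summit {summit} outside [{start},{end})")
    if fe <= 0:
        return None  # rejected row
    return Peak(GenomicInterval(chrom, start, end, strand), summit, fe, name)


def read_peaks(path, dialect: str = "narrowPeak", *, summit_col: int = 4,
               fe_col: int = 5, one_based: bool = False, label: str = "",
               genome_id: str = "") -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    Parameters
    ----------
    path : path-like
        Input file. Lines starting with ``#`` or ``track`` are skipped.
    dialect : {"narrowPeak", "bed_summit_fe"}
        ``narrowPeak``: MACS2 BED6+4; summit = start + column-10 offset, FE =
        signalValue (column 7). ``bed_summit_fe``: generic BED whose summit
        (absolute coordinate) and FE columns are configurable, since deposited
        supplementary tables do not follow one schema.
    summit_col, fe_col : int
        0-based column indices for the ``bed_summit_fe`` dialect.
    one_based : bool
        Convert 1-based inclusive inputs to the internal 0-based convention.

    Rows whose FE is not strictly positive are rejected (dropped).
    """
    if dialect not in ("narrowPeak", "bed_summit_fe"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            peak = _parse_row(fields, lineno, dialect, summit_col, fe_col,
                              one_based)
            if peak is not None:
                peaks.append(peak)
    return PeakSet(peaks, label=label or str(path), genome_id=genome_id)


def write_peaks(path, peakset: PeakSet) -> None:
    """Write a peak set as narrowPeak (summit as column-10 offset)."""
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.fold_enrichment:.6g}\t-1\t-1\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# Summit windows and overlap


@dataclass(frozen=True, slots=True)
class SummitWindow:
    """Fixed-width window centred on a peak summit (may be clipped at 0)."""

    interval: GenomicInterval
    clipped: bool
    peak: Peak


def summit_window(peak: Peak, width: int = 200) -> SummitWindow:
    """The ``width`` nt window centred on the peak summit.

    Windows extending past the chromosome start are clipped at 0 and flagged
    rather than discarded, so peak counts are preserved.
    """
    if width <= 0 or width % 2:
        raise ValueError(f"width must be an even positive integer, got {width}")
    half = width // 2
    start = peak.summit - half
    clipped = start < 0
    start = max(start, 0)
    return SummitWindow(
        GenomicInterval(peak.chrom, start, peak.summit + half), clipped, peak
    )


@dataclass(slots=True)
class OverlapPartition:
    """Exhaustive, disjoint partition of two peak sets by window overlap."""

    a_only: list[Peak]
    a_shared: list[Peak]
    b_only: list[Peak]
    b_shared: list[Peak]


def _windows_by_chrom(ps: PeakSet, width: int):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in ps:
        w = summit_window(p, width).interval
        by_chrom.setdefault(p.chrom, []).append((w.start, w.end))
    for lst in by_chrom.values():
        lst.sort()
    return by_chrom


def _shared_mask(ps: PeakSet, other_windows, width: int, min_overlap: int):
    mask = []
    for p in ps:
        w = summit_window(p, width).interval
        cands = other_windows.get(p.chrom, [])
        # windows have length <= width, so any overlapping window starts
        # within (w.start - width, w.end)
        lo = bisect_left(cands, (w.start - width, -1))
        hi = bisect_right(cands, (w.end, 1 << 60))
        hit = any(
            min(w.end, e) - max(w.start, s) >= min_overlap
            for s, e in cands[lo:hi]
        )
        mask.append(hit)
    return mask


def overlap_partition(A: PeakSet, B: PeakSet, min_overlap: int = 1,
                      width: int = 200) -> OverlapPartition:
    """Partition peaks of ``A`` and ``B`` by summit-window overlap.

    A peak of ``A`` is *shared* iff its ``width`` nt summit window intersects
    at least ``min_overlap`` bases of some summit window of ``B`` (and
    symmetrically for ``B``). Each peak is counted once, however many windows
    of the other set it touches.
    """
    if A.genome_id != B.genome_id:
        raise ValueError(
            f"genome mismatch: {A.genome_id!r} vs {B.genome_id!r}"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    wb = _windows_by_chrom(B, width)
    wa = _windows_by_chrom(A, width)
    mask_a = _shared_mask(A, wb, width, min_overlap)
    mask_b = _shared_mask(B, wa, width, min_overlap)
    return OverlapPartition(
        a_only=[p for p, m in zip(A, mask_a) if not m],
        a_shared=[p for p, m in zip(A, mask_a) if m],
        b_only=[p for p, m in zip(B, mask_b) if not m],
        b_shared=[p for p, m in zip(B, mask_b) if m],
    )


def ranked_overlap_curve(A: PeakSet, B: PeakSet, Ns: list[int],
                         min_overlap: int = 1, width: int = 200) -> pd.DataFrame:
    """Percent of the top-N FE-ranked peaks of ``A`` overlapping top-N of ``B``.

    Returns a frame with columns ``N``, ``n_shared`` and ``percent``.
    """
    rows = []
    for n in Ns:
        if n > min(len(A), len(B)):
            raise ValueError(f"N={n} exceeds a set size ({len(A)}, {len(B)})")
        part = overlap_partition(A.top(n), B.top(n), min_overlap, width)
        rows.append((n, len(part.a_shared), 100.0 * len(part.a_shared) / n))
    return pd.DataFrame(rows, columns=["N", "n_shared", "percent"])


def nearest_distance(A: PeakSet, B: PeakSet,
                     mode: str = "summit") -> pd.DataFrame:
    """Distance from each peak of ``A`` to the nearest peak of ``B``.

    ``mode="summit"`` measures absolute summit-to-summit separation (the
    default); ``mode="edge"`` measures the edge-to-edge gap between peak
    intervals (0 when they overlap). Chromosomes of ``A`` absent from ``B``
    yield infinite distance and are flagged. Distances are binned into unit
    log10 intervals with a separate ``"0"`` bin.
    """
    if mode not in ("summit", "edge"):
        raise ValueError(f"unknown mode {mode!r}")
    b_summits: dict[str, list[int]] = {}
    b_ivs: dict[str, list[tuple[int, int]]] = {}
    for p in B:
        b_summits.setdefault(p.chrom, []).append(p.summit)
        b_ivs.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    for v in b_summits.values():
        v.sort()
    rows = []
    for p in A:
        if p.chrom not in b_summits:
            rows.append((p.name, p.chrom, p.summit, math.inf, "inf", True))
            continue
        if mode == "summit":
            cands = b_summits[p.chrom]
            i = bisect_left(cands, p.summit)
            d = min(
                abs(p.summit - cands[j])
                for j in (i - 1, i)
                if 0 <= j < len(cands)
            )
        else:
            d = min(
                max(s - p.interval.end, p.interval.start - e, 0)
                for s, e in b_ivs[p.chrom]
            )
        if d == 0:
            label = "0"
        else:
            k = int(math.floor(math.log10(d)))
            label = f"[10^{k},10^{k + 1})"
        rows.append((p.name, p.chrom, p.summit, float(d), label, False))
    return pd.DataFrame(
        rows, columns=["name", "chrom", "summit", "distance", "bin", "no_b_chrom"]
    )


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_sequences(intervals, genome) -> list[str]:
    """Extract uppercase sequences for half-open intervals from a FASTA.

    ``genome`` is a FASTA path or an open :class:`pyfaidx.Fasta`. Intervals
    beyond chromosome bounds raise, naming the offending interval.
    """
    import pyfaidx

    fa = genome if isinstance(genome, pyfaidx.Fasta) else pyfaidx.Fasta(str(genome))
    out = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome")
        clen = len(fa[iv.chrom])
        if iv.end > clen:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
                f"end {clen}"
            )
        seq = fa[iv.chrom][iv.start:iv.end].seq.upper()
        if len(seq) != iv.length:
            raise ValueError(f"short sequence for {iv}")
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# FE distribution comparison


def fe_distribution_compare(A: PeakSet, B: PeakSet) -> dict:
    """Compare log2 FE distributions of two peak sets.

    Returns quartile summaries per set (box = central 50%, whiskers = outer
    quartiles) plus a one-sided Welch two-sample t statistic and p-value for
    the alternative mean(log2 FE of A) > mean(log2 FE of B). Two identical
    constant samples are a degenerate case and return t=0, p=0.5, flagged.
    """
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 peaks per set")
    a = np.log2(A.fold_enrichments())
    b = np.log2(B.fold_enrichments())
    qs = [0, 25, 50, 75, 100]
    summary = {
        "A_quartiles": dict(zip(qs, np.percentile(a, qs))),
        "B_quartiles": dict(zip(qs, np.percentile(b, qs))),
        "n_A": len(a),
        "n_B": len(b),
        "degenerate": False,
    }
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            summary.update(t=0.0, p=0.5, degenerate=True)
        else:
            summary.update(
                t=math.inf if a.mean() > b.mean() else -math.inf,
                p=0.0 if a.mean() > b.mean() else 1.0,
                degenerate=True,
            )
        return summary
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    summary.update(t=float(t), p=float(p))
    return summary
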