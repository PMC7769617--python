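"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (all-pairs loops, per-character
window comparison) so they stay independent of the vectorized production
code paths they check.
"""

import numpy as np
import pytest

from hoxtale.intervals import GenomicInterval, Peak, PeakSet
from hoxtale.motifs import IUPAC, revcomp
from hoxtale.synth import SynthConfig, generate

# ---------------------------------------------------------------------------
# Oracles


def brute_scan(seq: str, iupac: str, max_mismatch: int, strands: str = "both"):
    """Character-by-character window scan; returns (offset, strand, variant,
    mismatches) tuples sorted like the production scanner."""
    seq = seq.upper()
    out = []

    def _mismatches(window, pat):
        mm = 0
        for wc, pc in zip(window, pat):
            if pc == "N":
                continue
            if wc == "N" or wc not in IUPAC[pc]:
                mm += 1
        return mm

    L = len(iupac)
    for o in range(len(seq) - L + 1):
        win = seq[o:o + L]
        mm = _mismatches(win, iupac)
        if mm <= max_mismatch:
            out.append((o, "+", win, mm))
        if strands == "both":
            mm = _mismatches(revcomp(win), iupac)
            if mm <= max_mismatch:
                out.append((o, "-", revcomp(win), mm))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def brute_overlap_shared(A, B, width, min_overlap):
    """All-pairs summit-window intersection; returns the shared mask for A."""
    mask = []
    for p in A:
        s1, e1 = max(0, p.summit - width // 2), p.summit + width // 2
        hit = False
        for q in B:
            if q.chrom != p.chrom:
                continue
            s2, e2 = max(0, q.summit - width // 2), q.summit + width // 2
            if min(e1, e2) - max(s1, s2) >= min_overlap:
                hit = True
                break
        mask.append(hit)
    return mask


def random_peakset(rng, n, label, chroms=("chr1", "chr2"), span=1_000_000,
                   genome_id="test"):
    peaks, used = [], set()
    while len(peaks) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        summit = int(rng.integers(200, span))
        if (chrom, summit) in used:
            continue
        used.add((chrom, summit))
        start = summit - int(rng.integers(50, 150))
        end = summit + int(rng.integers(50, 150))
        fe = float(rng.uniform(1, 50))
        peaks.append(Peak(GenomicInterval(chrom, max(0, start), end), summit,
                          fe, f"{label}_{len(peaks)}"))
    return PeakSet(peaks, label=label, genome_id=genome_id)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_bundle():
    """A 400-region bundle (BA2/PBA only), shared across tests."""
    return generate(SynthConfig(seed=11, n_regions=400,
                                tissue_probs=(0.0, 0.5, 0.5)))


@pytest.fixture(scope="session")
def default_bundle():
    """A three-tissue bundle at moderate size."""
    return generate(SynthConfig(seed=12, n_regions=600))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
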