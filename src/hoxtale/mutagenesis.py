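"""In-silico binding-site knockout.

A 25 nt site containing a candidate feature is replaced by random
dinucleotides sampled from the remainder of the region (composition-
preserving erasure), the trained regressor predicts binding of the mutated
sequence, and the predicted change is averaged over 100 independent
replacements. Cohorts of sites are summarized per feature class and task
with a one-sample Wilcoxon signed-rank test against zero and BH correction
across groups.

Replacement itself is not effect-neutral: random patches occasionally
create chance motif instances (and erase near-miss instances), giving every
knockout a small sign-consistent background shift that a signed-rank test
over tightly averaged sites will flag even for effect-free features. The
knockout therefore supports background normalization: pair each candidate
site with a control site — a motif-free window in the same region — and
report the candidate's predicted change minus the control's. The planted
negative control (GATA) is only expected to be null on this adjusted scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnn import CNNRegressor, encode_batch, predict
from .diffbind import bh_fdr
from .motifs import MotifHit, SITE_CLASSES, scan

__all__ = [
    "KnockoutSite",
    "KnockoutResult",
    "make_site",
    "make_control_site",
    "knockout",
    "cohort_summary",
]


@dataclass(frozen=True, slots=True)
class KnockoutSite:
    """A fixed-width erasure window around a motif hit within a region."""

    region_id: str
    start: int
    end: int
    feature_class: str
    source_offset: int
    source_end: int
    strand: str = "+"

    @property
    def width(self) -> int:
        return self.end - self.start


def make_site(hit: MotifHit, region_length: int, width: int = 25,
              feature_class: str | None = None) -> KnockoutSite:
    """The ``width`` nt site centred on the motif midpoint.

    With the default odd width the extra base falls to the left of the
    midpoint (site = [mid - 13, mid + 12) for width 25). Sites running past
    the region edge are shifted inward, preserving width; the motif span is
    always contained when it fits.
    """
    if region_length < width:
        raise ValueError(f"region length {region_length} < site width {width}")
    mid = (hit.offset + hit.end) // 2 + (hit.offset + hit.end) % 2  # round up
    start = mid - (width + 1) // 2
    start = min(max(start, 0), region_length - width)
    return KnockoutSite(hit.region_id, start, start + width,
                        feature_class or hit.pattern,
                        hit.offset, hit.end, hit.strand)


def make_control_site(seq: str, avoid: KnockoutSite, width: int = 25,
                      patterns=None, seed: int = 0,
                      max_tries: int = 200) -> KnockoutSite | None:
    """A motif-free control window in the same region.

    Samples window positions until one neither overlaps ``avoid`` nor
    contains a match to any of ``patterns`` (all known site classes by
    default). Returns None when no clean window is found.
    """
    if patterns is None:
        patterns = list(SITE_CLASSES.values())
    rng = np.random.default_rng(seed)
    n = len(seq)
    if n < width:
        raise ValueError("region shorter than control width")
    for _ in range(max_tries):
        start = int(rng.integers(0, n - width + 1))
        end = start + width
        if start < avoid.end and end > avoid.start:
            continue
        window = seq[start:end]
        if any(scan(window, p, "both") for p in patterns):
            continue
        return KnockoutSite(avoid.region_id, start, end, "control",
                            start, end)
    return None


@dataclass(slots=True)
class KnockoutResult:
    """Averaged predicted binding change from erasing one site."""

    site: KnockoutSite
    mean_delta: np.ndarray   # per task
    sd_delta: np.ndarray
    n_repeats: int
    seed: int
    tasks: tuple


def _dinucleotide_pool(seq: str, site: KnockoutSite) -> list[str]:
    """Non-overlapping dinucleotide tiling of the sequence outside the site.

    The two outside segments are tiled independently so no artificial
    junction dinucleotide is created; a trailing odd base is dropped.
    """
    pool = []
    for seg in (seq[:site.start], seq[site.end:]):
        pool.extend(seg[i:i + 2] for i in range(0, len(seg) - 1, 2))
    if not pool:
        raise ValueError("region outside the site is shorter than 2 nt")
    return pool


def _mutants(seq: str, site: KnockoutSite, repeats: int,
             rng: np.random.Generator) -> list[str]:
    pool = _dinucleotide_pool(seq, site)
    width = site.width
    n_di = (width + 1) // 2
    out = []
    for _ in range(repeats):
        picks = rng.integers(0, len(pool), size=n_di)
        patch = "".join(pool[i] for i in picks)[:width]
        out.append(seq[:site.start] + patch + seq[site.end:])
    return out


def knockout(model: CNNRegressor, seq: str, site: KnockoutSite,
             repeats: int = 100, seed: int = 0,
             control_site: KnockoutSite | None = None) -> KnockoutResult:
    """Erase a site by repeated random dinucleotide replacement.

    Each repeat rewrites the site with ceil(width/2) dinucleotides drawn
    uniformly with replacement from the outside-site tiling, concatenated
    and truncated to the site width. Delta = predict(mutated) −
    predict(original), averaged over repeats. With ``control_site`` the
    same procedure runs on the control window and the reported delta is the
    per-repeat difference (background-normalized knockout). Seeded, hence
    reproducible; nothing outside the site(s) is ever altered.
    """
    if not (0 <= site.start < site.end <= len(seq)):
        raise ValueError(f"site [{site.start},{site.end}) outside region "
                         f"of length {len(seq)}")
    rng = np.random.default_rng(seed)
    mutants = _mutants(seq, site, repeats, rng)
    if control_site is not None:
        mutants += _mutants(seq, control_site, repeats, rng)
    X = encode_batch([seq] + mutants, model.input_length)
    preds = predict(model, X)
    delta = preds[1:repeats + 1] - preds[0]
    if control_site is not None:
        delta = delta - (preds[repeats + 1:] - preds[0])
    return KnockoutResult(site, delta.mean(axis=0), delta.std(axis=0, ddof=1),
                          repeats, seed, model.tasks)


def cohort_summary(results: list[KnockoutResult], min_group: int = 5,
                   fdr: float = 0.05) -> pd.DataFrame:
    """Per (feature class, task) effect summary across knockout sites.

    For each group: the mean and median of per-site mean deltas, a two-sided
    one-sample Wilcoxon signed-rank p-value against zero, and BH q across
    all tested groups. Groups smaller than ``min_group`` (or with all-zero
    deltas, where the signed-rank statistic is undefined) are flagged and
    left untested (p = NaN; all-zero groups report p = 1).
    """
    if not results:
        raise ValueError("no knockout results")
    tasks = results[0].tasks
    rows = []
    for fclass in sorted({r.site.feature_class for r in results}):
        sub = [r for r in results if r.site.feature_class == fclass]
        deltas = np.stack([r.mean_delta for r in sub])  # (sites, tasks)
        for j, task in enumerate(tasks):
            d = deltas[:, j]
            flagged, p = False, np.nan
            if len(d) < min_group:
                flagged = True
            elif np.all(d == 0):
                flagged, p = True, 1.0
            else:
                nz = d[d != 0]
                if nz.size == 0:
                    flagged, p = True, 1.0
                else:
                    p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
            rows.append((fclass, getattr(task, "name", str(task)), len(d),
                         float(d.mean()), float(np.median(d)),
                         float(d.std(ddof=1)) if len(d) > 1 else np.nan,
                         p, flagged))
    df = pd.DataFrame(rows, columns=["feature_class", "task", "n_sites",
                                     "mean_delta", "median_delta", "sd_delta",
                                     "p", "flagged"])
    tested = df["p"].notna() & ~df["flagged"]
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(df.loc[tested, "p"].to_numpy())
    df["q"] = q
    df["significant"] = df["q"] < fdr
    return df
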