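"""Sliding-window runs-of-homozygosity detection, ROH islands and annotation.

Mirrors the PLINK ``--homozyg`` approach: a 50-SNP window slides along each
chromosome, a window counts as homozygous when it carries at most one
heterozygous and at most five missing calls, and a SNP is flagged as
potentially inside a run when the fraction of homozygous windows covering it
reaches the window threshold.  Maximal flagged stretches then become ROH
segments subject to minimum length (1 Mb), maximum inter-SNP gap (1 Mb),
minimum density (1 SNP / 100 kb) and a minimum SNP count L chosen so the
expected number of chance runs over the whole dataset is below alpha:

    L = ceil( ln(alpha / (ns * ni)) / ln(1 - het) )

with ns genotyped SNPs per animal, ni animals and het the mean SNP
heterozygosity.

Island calling follows the top-1% convention: per-SNP ROH incidence across
individuals is thresholded at its (1 - top_pct) empirical quantile and runs
of at least two consecutive panel SNPs strictly above it form islands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .intervals import FeatureSet

logger = logging.getLogger(__name__)


@dataclass
class ROHParams:
    """Detection parameters (defaults are the standard cattle-chip settings)."""

    min_len_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    window_threshold: float = 0.01
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_len_bp", "max_gap_bp", "min_density_bp_per_snp",
                     "window_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: sample, chromosome, bp span and SNP count."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class ROHIsland:
    """A region where per-SNP ROH incidence exceeds the population threshold."""

    chrom: str
    start: int
    end: int
    n_snps: int
    peak_incidence: float
    genes: list[str] = field(default_factory=list)


def min_snp_count(ns: int, ni: int, het: float, alpha: float = 0.05) -> int:
    """Minimum SNPs per ROH limiting chance runs to an expected count alpha.

    L = ceil( ln(alpha/(ns*ni)) / ln(1-het) ).  Raises for het of 0 or 1,
    where the expression is undefined.
    """
    if ns < 1 or ni < 1:
        raise ValueError("ns and ni must be >= 1")
    if not 0 < het < 1:
        raise ValueError("het must lie strictly between 0 and 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    ratio = math.log(alpha / (ns * ni)) / math.log(1.0 - het)
    # tolerance guards the ceiling against float noise when the ratio is an
    # exact integer (e.g. ns=ni=1, het=0.95, alpha=0.05 gives exactly 1)
    return max(1, math.ceil(ratio - 1e-9))


def window_homozygosity_flags(
    codes: np.ndarray, positions: np.ndarray, params: ROHParams | None = None
) -> np.ndarray:
    """Per-SNP homozygosity flags for one sample on one chromosome.

    A sliding window of ``window_snps`` consecutive SNPs is homozygous when it
    holds at most ``max_het_per_window`` heterozygous and at most
    ``max_missing_per_window`` missing calls.  Each SNP's score is the
    fraction of windows covering it that are homozygous; it is flagged when
    the score reaches ``window_threshold``.  Chromosomes shorter than one
    window are scored against the single truncated window.
    """
    params = params or ROHParams()
    codes = np.asarray(codes)
    positions = np.asarray(positions, dtype=np.int64)
    if codes.shape != positions.shape:
        raise ValueError("codes and positions must have equal length")
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted strictly ascending")

    w = min(params.window_snps, n)
    het = (codes == 1).astype(np.int32)
    mis = (codes == MISSING).astype(np.int32)
    # window i covers SNPs [i, i+w); count via cumulative sums
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    idx = np.arange(n_win)
    win_ok = (
        (chet[idx + w] - chet[idx] <= params.max_het_per_window)
        & (cmis[idx + w] - cmis[idx] <= params.max_missing_per_window)
    )
    cok = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_cover = hi - lo + 1
    n_ok = cok[hi + 1] - cok[lo]
    score = n_ok / n_cover
    return score >= params.window_threshold


def call_roh(
    flags: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
    L: int,
    sample_id: str = "",
    chrom: str = "",
) -> list[ROHSegment]:
    """Segment flagged SNPs into ROH calls.

    Maximal stretches of flagged SNPs are split where the gap between
    consecutive SNPs exceeds ``max_gap_bp``; surviving stretches must span at
    least ``min_len_bp``, contain at least ``L`` SNPs and keep a density of
    at most ``min_density_bp_per_snp`` bp per SNP.
    """
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions, dtype=np.int64)
    segments: list[ROHSegment] = []
    run_start = None
    prev_pos = None

    def close(run_start: int, run_end: int) -> None:
        n_snps = run_end - run_start + 1
        start, end = int(positions[run_start]), int(positions[run_end])
        length = end - start + 1
        if length < params.min_len_bp or n_snps < L:
            return
        if length / n_snps > params.min_density_bp_per_snp:
            return
        segments.append(ROHSegment(sample_id, chrom, start, end, n_snps))

    for i in range(flags.size):
        if flags[i]:
            if run_start is None:
                run_start = i
            elif positions[i] - prev_pos > params.max_gap_bp:
                close(run_start, i - 1)
                run_start = i
            prev_pos = positions[i]
        else:
            if run_start is not None:
                close(run_start, i - 1)
                run_start = None
    if run_start is not None:
        close(run_start, flags.size - 1)
    return segments


def detect_roh(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
    include_sex_chroms: bool = False,
) -> tuple[list[ROHSegment], int]:
    """Run ROH detection for every sample over (by default) autosomes only.

    L is computed from the data: ns = mean genotyped SNPs per animal,
    ni = number of animals, het = mean per-site observed heterozygosity.
    Returns the segments and the L used.
    """
    from .genotype import site_stats

    params = params or ROHParams()
    chroms = list(gm.chrom_order) if include_sex_chroms else gm.autosomal_chroms()

    stats = site_stats(gm)
    hets = np.array([s.het_rate for s in stats if s.defined])
    het = float(hets.mean()) if hets.size else 0.0
    if not 0 < het < 1:
        raise ValueError(f"mean heterozygosity {het} outside (0, 1); cannot compute L")
    ns = int(round((gm.calls != MISSING).sum(axis=1).mean()))
    L = min_snp_count(max(ns, 1), gm.n_samples, het, params.alpha)

    chrom_arr = gm.chroms
    segments: list[ROHSegment] = []
    for chrom in chroms:
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        positions = gm.positions[mask]
        for i, sample in enumerate(gm.samples):
            codes = gm.calls[i, mask]
            flags = window_homozygosity_flags(codes, positions, params)
            segments.extend(
                call_roh(flags, positions, params, L, sample.sample_id, chrom)
            )
    logger.info("detect_roh: %d segments in %d samples (L=%d, het=%.3f)",
                len(segments), gm.n_samples, L, het)
    return segments, L


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segments as a PLINK ``.hom``-style table (length in kb)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_kb": [s.length_bp / 1e3 for s in segments],
        }
    )


def roh_summary(
    segments: list[ROHSegment],
    samples: list,
    autosome_len: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-breed ROH burden summaries.

    Samples without segments appear with zero counts.  Coverage is total ROH
    length over ``autosome_len``.
    """
    if autosome_len <= 0:
        raise ValueError("autosome_len must be positive")
    per: dict[str, list[int]] = {s.sample_id: [] for s in samples}
    for seg in segments:
        per.setdefault(seg.sample_id, []).append(seg.length_bp)
    rows = []
    breed_of = {s.sample_id: s.breed for s in samples}
    for sid, lengths in per.items():
        total = int(sum(lengths))
        rows.append({
            "sample_id": sid,
            "breed": breed_of.get(sid, ""),
            "n_roh": len(lengths),
            "total_bp": total,
            "mean_bp": total / len(lengths) if lengths else 0.0,
            "coverage": total / autosome_len,
        })
    per_sample = pd.DataFrame(rows)
    per_breed = (
        per_sample.groupby("breed", sort=True)
        .agg(
            n_samples=("sample_id", "count"),
            mean_n_roh=("n_roh", "mean"),
            mean_total_bp=("total_bp", "mean"),
            mean_coverage=("coverage", "mean"),
            max_total_bp=("total_bp", "max"),
        )
        .reset_index()
    )
    return per_sample, per_breed


def snp_incidence(
    segments: list[ROHSegment],
    sites: list[tuple[str, int]],
    n_individuals: int,
) -> np.ndarray:
    """Fraction of individuals whose ROH cover each panel SNP.

    ``sites`` is a genome-ordered list of (chrom, pos); a segment covers a
    SNP when start <= pos <= end on the same chromosome.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    covered: dict[int, set[str]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, (chrom, pos) in enumerate(sites):
        by_chrom.setdefault(chrom, []).append((pos, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for seg in segments:
        entries = by_chrom.get(seg.chrom)
        if not entries:
            continue
        poss = [p for p, _ in entries]
        lo = np.searchsorted(poss, seg.start, side="left")
        hi = np.searchsorted(poss, seg.end, side="right")
        for _, j in entries[lo:hi]:
            covered.setdefault(j, set()).add(seg.sample_id)
    out = np.zeros(len(sites))
    for j, who in covered.items():
        out[j] = len(who) / n_individuals
    return out


def island_call(
    incidence: np.ndarray,
    sites: list[tuple[str, int]],
    top_pct: float = 0.01,
    min_snps: int = 2,
    gap_split_bp: int | None = None,
) -> tuple[float, list[ROHIsland]]:
    """Call ROH islands from per-SNP incidence.

    The threshold is the (1 - ``top_pct``) empirical quantile of the
    incidence values; islands are maximal runs of consecutive panel SNPs (in
    genome order, never spanning chromosomes) with incidence strictly above
    it, and must contain at least ``min_snps`` SNPs.  ``gap_split_bp``
    additionally breaks runs where consecutive SNPs are farther apart than
    the given distance (off by default).  When every SNP has the same
    incidence nothing exceeds the threshold and no island is returned.
    """
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size != len(sites):
        raise ValueError("incidence and sites must align")
    if incidence.size < 100:
        logger.warning("island_call: only %d SNPs; the top-%g%% threshold is coarse",
                       incidence.size, 100 * top_pct)
    threshold = float(np.quantile(incidence, 1.0 - top_pct))
    above = incidence > threshold
    if not above.any():
        logger.info("island_call: no SNP strictly above threshold %.4f", threshold)
        return threshold, []

    islands: list[ROHIsland] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= min_snps:
            chrom = sites[run[0]][0]
            islands.append(
                ROHIsland(
                    chrom=chrom,
                    start=sites[run[0]][1],
                    end=sites[run[-1]][1],
                    n_snps=len(run),
                    peak_incidence=float(incidence[run].max()),
                )
            )
        run.clear()

    for j in range(len(sites)):
        if not above[j]:
            close()
            continue
        if run:
            prev = run[-1]
            same_chrom = sites[prev][0] == sites[j][0]
            gap_ok = (
                gap_split_bp is None
                or sites[j][1] - sites[prev][1] <= gap_split_bp
            )
            if not (same_chrom and gap_ok):
                close()
        run.append(j)
    close()
    return threshold, islands


def annotate_intervals(
    intervals: list,
    features: FeatureSet,
) -> list[list[str]]:
    """Overlapping feature IDs for each interval (islands or any regions).

    ``intervals`` holds objects with ``chrom``/``start``/``end`` attributes or
    (chrom, start, end) tuples; overlap means the 1-based inclusive bp ranges
    intersect.  Feature lists are sorted and deduplicated; ``ROHIsland``
    inputs also get their ``genes`` field populated.
    """
    out: list[list[str]] = []
    for iv in intervals:
        if isinstance(iv, tuple):
            chrom, start, end = iv
            hits = features.overlapping(chrom, start, end)
        else:
            hits = features.overlapping(iv.chrom, iv.start, iv.end)
            if isinstance(iv, ROHIsland):
                iv.genes = hits
        out.append(hits)
    return out


def islands_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": [i.start for i in islands],
            "end": [i.end for i in islands],
            "n_snps": [i.n_snps for i in islands],
            "peak_incidence": [i.peak_incidence for i in islands],
            "genes": [",".join(i.genes) for i in islands],
        }
    )


def islands_bed(islands: list[ROHIsland]) -> pd.DataFrame:
    """Islands in BED form (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": [i.start - 1 for i in islands],
            "end": [i.end for i in islands],
            "name": [f"island_{k + 1}" for k in range(len(islands))],
        }
    )
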