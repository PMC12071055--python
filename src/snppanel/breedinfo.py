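"""Per-site breed-differentiation statistics and candidate-site ranking.

Stage-1 candidate discovery: each site is scored for every breed comparison
with three ancestry-informativeness statistics — Wright's Fst (two-population
heterozygosity form), delta (absolute frequency difference) and Rosenberg's
informativeness for assignment (In) — and the per-comparison top-N lists are
unioned into a candidate pool.  A PCA-based silhouette score then picks the
subset size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class BreedFreqTable:
    """Alt-allele frequencies per breed per site.

    ``p`` has shape (n_breeds, n_sites); entries are NaN where a breed has no
    non-missing call at the site.  ``n_alleles`` holds the non-missing allele
    counts (2 x genotyped samples).
    """

    breeds: list[str]
    p: np.ndarray
    n_alleles: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.p.shape[1]


def breed_freqs(gm: GenotypeMatrix) -> BreedFreqTable:
    """Per-breed alt allele frequencies, missing-excluded.

    Raises if the matrix holds a single breed (no comparison is possible).
    """
    labels = gm.breeds
    breeds = sorted(set(labels))
    if len(breeds) < 2:
        raise ValueError("at least two breeds are required for breed comparisons")
    p = np.full((len(breeds), gm.n_sites), np.nan)
    n_alleles = np.zeros((len(breeds), gm.n_sites), dtype=np.int64)
    for i, b in enumerate(breeds):
        calls = gm.calls[labels == b, :]
        miss = calls == MISSING
        n_obs = calls.shape[0] - miss.sum(axis=0)
        dosage = np.where(miss, 0, calls).sum(axis=0)
        n_alleles[i] = 2 * n_obs
        with np.errstate(invalid="ignore"):
            p[i] = np.where(n_obs > 0, dosage / (2.0 * n_obs), np.nan)
    return BreedFreqTable(breeds, p, n_alleles, gm.chroms, gm.positions)


def _check_freq(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return p


def wright_fst(p1, p2):
    """Wright's Fst between two populations from allele frequencies.

    HT = 2 p̄ (1 − p̄) with p̄ = (p1 + p2)/2; HS the mean within-population
    heterozygosity; returns (HT − HS)/HT, defined as 0 where HT = 0 (both
    populations fixed for the same allele).  Accepts scalars or arrays.
    """
    p1, p2 = _check_freq(p1), _check_freq(p2)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    return float(fst) if np.isscalar(p1) or p1.ndim == 0 else fst


def global_fst(p1, p2) -> float:
    """Multi-locus Wright's Fst: ratio of summed (HT − HS) to summed HT.

    The standard way to average Fst across loci — weighting each locus by its
    total heterozygosity — which avoids the downward Jensen bias of averaging
    per-locus ratios.  ``p1``/``p2`` are per-site frequency vectors.
    """
    p1, p2 = _check_freq(p1), _check_freq(p2)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    denom = ht.sum()
    if denom == 0:
        return 0.0
    return float((ht - hs).sum() / denom)


def delta_stat(p1, p2):
    """Absolute allele-frequency difference |p1 − p2|."""
    p1, p2 = _check_freq(p1), _check_freq(p2)
    d = np.abs(p1 - p2)
    return float(d) if d.ndim == 0 else d


def _xlogx(p: np.ndarray) -> np.ndarray:
    # 0 * ln 0 == 0 by convention
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def informativeness_in(p_vec):
    """Rosenberg's informativeness for assignment, In, over K populations.

    For alt-allele frequencies ``p_vec`` (length K, or shape (K, n_sites) for
    many sites at once), summing over both alleles j with mean frequency p̄_j:

        In = Σ_j ( −p̄_j ln p̄_j + (1/K) Σ_i p_ij ln p_ij )

    Natural log; 0·ln 0 = 0.  In = 0 iff all populations share the same
    frequency; the two-population maximum is ln 2 at fixed difference.
    """
    p = _check_freq(p_vec)
    if p.ndim == 1:
        p = p[:, None]
        squeeze = True
    else:
        squeeze = False
    k = p.shape[0]
    if k < 2:
        raise ValueError("In requires at least two populations")
    total = np.zeros(p.shape[1])
    for allele in (p, 1.0 - p):
        pbar = allele.mean(axis=0)
        total += -_xlogx(pbar) + _xlogx(allele).mean(axis=0)
    total = np.maximum(total, 0.0)  # clip -0.0 / rounding at the In=0 boundary
    return float(total[0]) if squeeze else total


STATISTICS = ("fst", "delta", "in")


def score_breed_pairs(
    freqs: BreedFreqTable,
    pairs: list[tuple[str, str]] | None = None,
    statistics: tuple[str, ...] = STATISTICS,
) -> pd.DataFrame:
    """Score every site for every breed pair with the requested statistics.

    Returns a long-form frame (site_idx, chrom, pos, statistic, comparison,
    value).  Sites where either breed has no data are dropped for that
    comparison.  By default all unordered breed pairs are scored.
    """
    if pairs is None:
        pairs = list(itertools.combinations(freqs.breeds, 2))
    idx = {b: i for i, b in enumerate(freqs.breeds)}
    frames = []
    site_idx = np.arange(freqs.n_sites)
    for b1, b2 in pairs:
        p1, p2 = freqs.p[idx[b1]], freqs.p[idx[b2]]
        ok = ~(np.isnan(p1) | np.isnan(p2))
        comparison = f"{b1}~{b2}"
        values = {}
        if "fst" in statistics:
            values["fst"] = wright_fst(p1[ok], p2[ok])
        if "delta" in statistics:
            values["delta"] = delta_stat(p1[ok], p2[ok])
        if "in" in statistics:
            values["in"] = informativeness_in(np.stack([p1[ok], p2[ok]]))
        for stat, val in values.items():
            frames.append(
                pd.DataFrame(
                    {
                        "site_idx": site_idx[ok],
                        "chrom": freqs.chroms[ok],
                        "pos": freqs.positions[ok],
                        "statistic": stat,
                        "comparison": comparison,
                        "value": val,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def rank_top_sites(scores: pd.DataFrame, n: int) -> np.ndarray:
    """Union of per-(statistic, comparison) top-``n`` site lists.

    Within each list sites are ranked by descending value; ties break on the
    genome-order site index (smaller chromosome rank, then position), so the
    output is a deterministic function of the scores.  Returns sorted unique
    site indices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chosen: set[int] = set()
    for (_, _), grp in scores.groupby(["statistic", "comparison"], sort=True):
        if n > len(grp):
            logger.warning(
                "rank_top_sites: n=%d exceeds %d available sites; taking all", n, len(grp)
            )
        ordered = grp.sort_values(
            ["value", "site_idx"], ascending=[False, True], kind="mergesort"
        )
        chosen.update(int(i) for i in ordered["site_idx"].head(n))
    return np.asarray(sorted(chosen), dtype=np.intp)


@dataclass
class SubsetReport:
    """PCA-based separation report for a candidate subset."""

    n_sites: int
    pct_var_pc1: float
    pct_var_pc2: float
    silhouette: float


def evaluate_subset(gm: GenotypeMatrix, subset: np.ndarray) -> SubsetReport:
    """Silhouette of breed labels in PC1–PC2 space restricted to ``subset`` sites."""
    from sklearn.metrics import silhouette_score

    from .popgen import pca_genotypes

    subset = np.asarray(subset, dtype=np.intp)
    if subset.size < 2:
        raise ValueError("subset must contain at least two sites")
    res = pca_genotypes(gm.subset_sites(subset), n_components=2)
    labels = gm.breeds
    if len(set(labels)) < 2:
        raise ValueError("silhouette requires at least two breeds")
    sil = float(silhouette_score(res.scores[:, :2], labels))
    return SubsetReport(
        n_sites=int(subset.size),
        pct_var_pc1=float(res.pct_variance[0]),
        pct_var_pc2=float(res.pct_variance[1]),
        silhouette=sil,
    )


def choose_subset_size(
    gm: GenotypeMatrix,
    scores: pd.DataFrame,
    sizes: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000),
    plateau: float = 0.02,
) -> tuple[int, dict[int, SubsetReport]]:
    """Pick the top-N size whose breed separation has plateaued.

    Evaluates each candidate size and returns the smallest N whose silhouette
    is within ``plateau`` of the maximum across the tested sizes, together
    with the per-size reports.
    """
    reports = {n: evaluate_subset(gm, rank_top_sites(scores, n)) for n in sizes}
    best = max(r.silhouette for r in reports.values())
    for n in sorted(reports):
        if reports[n].silhouette >= best - plateau:
            return n, reports
    raise AssertionError("unreachable: at least one size attains the maximum")


def candidate_table(gm: GenotypeMatrix, subset: np.ndarray, category: str = "breed_specific") -> pd.DataFrame:
    """Candidate list TSV content for the chosen subset."""
    subset = np.asarray(subset, dtype=np.intp)
    return pd.DataFrame(
        {
            "chrom": gm.chroms[subset],
            "pos": gm.positions[subset],
            "category": category,
        }
    )
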