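"""Panel validation: PCA, p-distance, neighbor-joining trees, LD decay.

These are method-level reimplementations of the standard validation
toolchain: genotype PCA with per-site 2p centring and sqrt(2p(1-p)) scaling,
the allele-sharing p-distance, classic Saitou–Nei neighbor joining, and
genotype-correlation r² binned by physical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# -- PCA -----------------------------------------------------------------------


@dataclass
class PCAResult:
    """Sample scores and percent variance explained, components ordered."""

    scores: np.ndarray
    pct_variance: np.ndarray
    sample_ids: list[str]


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Principal component analysis of the dosage matrix.

    Missing calls are mean-imputed per site; each site is centred by 2p and
    scaled by sqrt(2p(1-p)) (p the alt allele frequency), monomorphic sites
    are dropped, and the components come from an SVD of the scaled matrix.
    Component signs are fixed by making the largest-magnitude loading
    positive, so results are reproducible across runs and sample orderings.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    calls = gm.calls.astype(float)
    miss = gm.calls == MISSING
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(miss, 0, calls).sum(axis=0) / (2.0 * n_obs), np.nan)
    poly = (n_obs > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic or empty; PCA undefined")
    calls = calls[:, poly]
    p = p[poly]
    miss = miss[:, poly]
    calls[miss] = np.broadcast_to(2.0 * p, calls.shape)[miss]
    x = (calls - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    k = min(n_components, gm.n_samples, x.shape[1])
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    # deterministic sign: largest-|.| loading of each component positive
    for c in range(len(s)):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    var = s**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u[:, :k] * s[:k]
    return PCAResult(scores=scores, pct_variance=pct[:k], sample_ids=gm.sample_ids)


# -- p-distance ----------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{d:.6f}" for d in self.matrix[i])
                fh.write(f"{name} {row}\n")


def p_distance(gm: GenotypeMatrix, allow_missing_pairs: bool = False) -> DistanceMatrix:
    """Allele-sharing p-distance between all sample pairs.

    d(i, j) = mean over sites where both calls are non-missing of
    |g_i - g_j| / 2.  A pair with zero jointly non-missing sites raises
    unless ``allow_missing_pairs`` (then NaN).
    """
    if gm.n_samples < 2:
        raise ValueError("p-distance requires at least two samples")
    calls = gm.calls.astype(float)
    obs = gm.calls != MISSING
    # n_samples is small at validation scale, so loop the pairs
    n = gm.n_samples
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = both.sum()
            if m == 0:
                undefined.append((gm.sample_ids[i], gm.sample_ids[j]))
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = np.abs(calls[i, both] - calls[j, both]).mean() / 2.0
    if undefined and not allow_missing_pairs:
        raise ValueError(f"sample pairs with no jointly called sites: {undefined}")
    return DistanceMatrix(ids=list(gm.sample_ids), matrix=d)


# -- neighbor joining ----------------------------------------------------------


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.17g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Classic Saitou–Nei neighbor joining; returns an unrooted newick tree.

    Ties in the Q criterion break on the smallest pair of active-node
    indices, so the tree is a deterministic function of the matrix.  A
    negative branch length is clamped to zero and the deficit moved to the
    sister branch, preserving the pair's summed length.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix contains undefined entries")

    d = {i: {j: float(dm.matrix[i, j]) for j in range(n) if j != i} for i in range(n)}
    nodes: dict[int, _Node] = {i: _Node(name=dm.ids[i]) for i in range(n)}
    next_id = n
    active = sorted(d)

    def clamp(pair: list[tuple[int, float]]) -> list[tuple[int, float]]:
        (a, la), (b, lb) = pair
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return [(a, max(la, 0.0)), (b, max(lb, 0.0))]

    while len(active) > 3:
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (m - 2) * d[i][j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i][j] - li
        (i2, li), (j2, lj) = clamp([(i, li), (j, lj)])
        new = _Node(children=[(nodes[i2], li), (nodes[j2], lj)])
        d[next_id] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
            d[next_id][k] = dk
            d[k][next_id] = dk
        nodes[next_id] = new
        active = sorted(k for k in active if k not in (i, j)) + [next_id]
        active.sort()
        next_id += 1

    i, j, k = active
    # three-point formulas for the final unrooted join
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    lengths = {i: li, j: lj, k: lk}
    # clamp negatives pairwise against the largest sibling
    order = sorted(lengths, key=lambda x: lengths[x])
    for a in order:
        if lengths[a] < 0:
            donor = order[-1]
            lengths[donor] += lengths[a]
            lengths[a] = 0.0
    root = _Node(children=[(nodes[x], max(lengths[x], 0.0)) for x in (i, j, k)])
    return root.newick() + ";"


# -- LD decay ------------------------------------------------------------------


@dataclass
class LDCurve:
    """Mean r² per physical-distance bin."""

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    both = (x != MISSING) & (y != MISSING)
    if both.sum() < 2:
        return None
    xv, yv = x[both].astype(float), y[both].astype(float)
    if xv.var() == 0 or yv.var() == 0:
        return None  # monomorphic in the observed samples
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_decay(
    gm: GenotypeMatrix,
    breed: str | None = None,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
) -> tuple[LDCurve, float]:
    """Genotype-correlation LD decay within a breed.

    r² between same-chromosome site pairs within ``max_dist`` is the squared
    Pearson correlation of dosage vectors over pairwise-complete samples;
    pairs involving a monomorphic site are skipped.  Returns the binned curve
    and the distance at which mean r² first decays to 0.2 (linear
    interpolation between bin midpoints; NaN when the curve never crosses).
    """
    if breed is not None:
        keep = [s.sample_id for s in gm.samples if s.breed == breed]
        if len(keep) < 2:
            raise ValueError(f"breed {breed!r} has fewer than two samples")
        gm = gm.subset_samples(keep)

    edges = np.arange(0, max_dist + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    chrom_arr = gm.chroms
    for chrom in gm.chrom_order:
        mask = chrom_arr == chrom
        if mask.sum() < 2:
            continue
        pos = gm.positions[mask]
        sub = gm.calls[:, mask]
        nloc = pos.size
        for a in range(nloc - 1):
            for b in range(a + 1, nloc):
                dist = pos[b] - pos[a]
                if dist > max_dist:
                    break
                r2 = _pair_r2(sub[:, a], sub[:, b])
                if r2 is None:
                    continue
                k = min(int(dist // bin_width), len(sums) - 1)
                sums[k] += r2
                counts[k] += 1
    if counts.sum() == 0:
        logger.warning("ld_decay: no usable site pairs within %d bp", max_dist)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    curve = LDCurve(bin_edges=edges, mean_r2=mean_r2, pair_counts=counts)
    return curve, _decay_distance(curve, 0.2)


def _decay_distance(curve: LDCurve, level: float) -> float:
    """Distance where the binned mean r² first crosses below ``level``."""
    mids = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2.0
    ok = ~np.isnan(curve.mean_r2)
    mids, r2 = mids[ok], curve.mean_r2[ok]
    if r2.size == 0 or r2[0] < level:
        return float("nan") if r2.size == 0 else float(mids[0])
    for k in range(1, r2.size):
        if r2[k] < level:
            x0, x1, y0, y1 = mids[k - 1], mids[k], r2[k - 1], r2[k]
            if y0 == y1:
                return float(x1)
            return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
    return float("nan")
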