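"""Deterministic multi-breed genotype simulation (Balding–Nichols model).

Breed allele frequencies are Beta-distributed around an ancestral frequency
p ~ Uniform(0.05, 0.95):

    p_ij ~ Beta( p (1 - F_i) / F_i,  (1 - p)(1 - F_i) / F_i )

so that E[p_ij] = p and Var[p_ij] = F_i p (1 - p), with F_i the
differentiation parameter of breed i.  Genotypes are Binomial(2, p_ij)
draws, missingness is an independent Bernoulli mask, and homozygous tracts
can be planted as ground truth for ROH detection.  Everything is
reproducible from the config seed.

Default conditions emulate a multi-breed cattle resequencing panel at desk
scale: 9 breeds of 20 animals, F = 0.1 per breed (local-breed-scale
differentiation), ~0.5% missingness (a >99% call rate), and sites placed
uniformly over two 50-Mb chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, SampleInfo, VariantSite

logger = logging.getLogger(__name__)


def _default_chroms() -> dict[str, int]:
    return {"1": 50_000_000, "2": 50_000_000}


@dataclass
class SimConfig:
    """Simulation settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_breeds: int = 9
    samples_per_breed: int = 20
    n_sites: int = 5000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    F: float | list[float] = 0.1
    missing_rate: float = 0.005
    planted_tracts: list[tuple[str, str, int, int]] = field(default_factory=list)
    ld_copy_fraction: float = 0.0
    ld_copy_max_dist: int = 5_000

    def __post_init__(self) -> None:
        if self.n_breeds < 1 or self.samples_per_breed < 1 or self.n_sites < 1:
            raise ValueError("counts must be >= 1")
        fs = self.f_per_breed()
        if any(not 0 < f < 1 for f in fs):
            raise ValueError("F must lie strictly in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def f_per_breed(self) -> list[float]:
        if isinstance(self.F, (int, float)):
            return [float(self.F)] * self.n_breeds
        if len(self.F) != self.n_breeds:
            raise ValueError("per-breed F list must have n_breeds entries")
        return [float(f) for f in self.F]

    @property
    def breed_names(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_breeds)]


@dataclass
class SimFrequencies:
    """Ancestral and per-breed alt-allele frequencies."""

    p_ancestral: np.ndarray
    p_breed: np.ndarray  # (n_breeds, n_sites)


def simulate_frequencies(config: SimConfig, rng: np.random.Generator | None = None) -> SimFrequencies:
    """Draw ancestral and Balding–Nichols per-breed allele frequencies."""
    rng = rng or np.random.default_rng(config.seed)
    p = rng.uniform(0.05, 0.95, config.n_sites)
    p_breed = np.empty((config.n_breeds, config.n_sites))
    for i, f in enumerate(config.f_per_breed()):
        scale = (1.0 - f) / f
        p_breed[i] = rng.beta(p * scale, (1.0 - p) * scale)
    return SimFrequencies(p_ancestral=p, p_breed=p_breed)


def _place_sites(config: SimConfig, rng: np.random.Generator) -> list[VariantSite]:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = np.floor(config.n_sites * lengths / lengths.sum()).astype(int)
    while n_per.sum() < config.n_sites:
        n_per[np.argmax(lengths)] += 1
    sites: list[VariantSite] = []
    for c, n in zip(chroms, n_per):
        length = config.chrom_lengths[c]
        n = min(n, length)
        # rejection-sample unique positions; cheap even for Mb-scale chromosomes
        chosen: np.ndarray = np.unique(rng.integers(1, length + 1, size=2 * n))
        while chosen.size < n:
            more = rng.integers(1, length + 1, size=2 * n)
            chosen = np.unique(np.concatenate([chosen, more]))
        pos = np.sort(rng.permutation(chosen)[:n])
        for k, p in enumerate(pos):
            ref, alt = ("A", "G") if k % 2 == 0 else ("C", "T")
            sites.append(VariantSite(c, int(p), f"{c}_{int(p)}", ref, alt))
    return sites


def simulate_genotypes(
    freqs: SimFrequencies, config: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw Binomial(2, p_ij) genotypes with a Bernoulli missingness mask.

    When ``ld_copy_fraction`` > 0 a fraction of sites is duplicated at a
    nearby position with a 2% genotype-flip rate, creating high-r² pairs for
    LD testing (the model itself has no linkage).  Planted tracts from the
    config are applied last.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    sites = _place_sites(config, rng)
    n_sites = len(sites)
    samples = [
        SampleInfo(f"{b}_{k + 1}", b, "F" if (k % 2 == 0) else "M")
        for b in config.breed_names
        for k in range(config.samples_per_breed)
    ]
    calls = np.empty((len(samples), n_sites), dtype=np.int8)
    for i in range(config.n_breeds):
        rows = slice(i * config.samples_per_breed, (i + 1) * config.samples_per_breed)
        pb = freqs.p_breed[i, :n_sites]
        calls[rows] = rng.binomial(2, pb, size=(config.samples_per_breed, n_sites))

    if config.ld_copy_fraction > 0:
        sites, calls = _copy_sites_for_ld(sites, calls, config, rng)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    gm = GenotypeMatrix(sites=sites, samples=samples, calls=calls,
                        chrom_order=list(config.chrom_lengths))
    truth = []
    for sample_id, chrom, start, end in config.planted_tracts:
        truth.append(plant_roh(gm, sample_id, chrom, start, end,
                               rng=np.random.default_rng(rng.integers(2**31))))
    gm.meta["planted_tracts"] = truth
    return gm


def _copy_sites_for_ld(sites, calls, config, rng):
    n_sites = len(sites)
    n_copy = int(config.ld_copy_fraction * n_sites)
    idx = rng.choice(n_sites, size=n_copy, replace=False)
    taken = {(s.chrom, s.pos) for s in sites}
    new_sites, new_cols = [], []
    for j in idx:
        s = sites[j]
        offset = int(rng.integers(1, config.ld_copy_max_dist + 1))
        pos = s.pos + offset
        if (s.chrom, pos) in taken:
            continue
        taken.add((s.chrom, pos))
        col = calls[:, j].copy()
        flip = rng.random(col.shape) < 0.02
        col[flip] = rng.integers(0, 3, size=int(flip.sum()))
        new_sites.append(VariantSite(s.chrom, pos, f"{s.chrom}_{pos}", s.ref, s.alt))
        new_cols.append(col)
    if not new_sites:
        return sites, calls
    all_sites = sites + new_sites
    all_calls = np.concatenate([calls, np.stack(new_cols, axis=1)], axis=1)
    rank = {c: i for i, c in enumerate(config.chrom_lengths)}
    order = sorted(range(len(all_sites)),
                   key=lambda i: (rank[all_sites[i].chrom], all_sites[i].pos))
    return [all_sites[i] for i in order], all_calls[:, order]


def plant_roh(
    gm: GenotypeMatrix,
    sample_id: str,
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict:
    """Force one sample homozygous across [start, end] (1-based inclusive).

    At each site in the region the sample's call becomes 0 or 2, the allele
    drawn by the site's realized frequency; missing calls are preserved.
    Returns a truth record with the realized SNP count.  Modifies ``gm`` in
    place.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    i = gm.sample_index([sample_id])[0]
    region = (gm.chroms == chrom) & (gm.positions >= start) & (gm.positions <= end)
    if region.sum() < 2:
        raise ValueError(f"region {chrom}:{start}-{end} contains fewer than two sites")
    calls = gm.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * n_obs), 0.5)
    for j in np.flatnonzero(region):
        if calls[i, j] == MISSING:
            continue
        calls[i, j] = 2 if rng.random() < p[j] else 0
    positions = gm.positions[region]
    return {
        "sample_id": sample_id,
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "first_snp": int(positions[0]),
        "last_snp": int(positions[-1]),
        "n_snps": int(region.sum()),
    }


def label_candidates(
    gm: GenotypeMatrix,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign candidate categories to random disjoint site subsets.

    ``fractions`` maps 'trait_related' and 'common' to site fractions (their
    sum must be <= 1).  The remaining sites with realized MAF > 0.2 become
    'wgs_polymorphic'.  Returns a candidate frame (chrom, pos, category,
    maf) with mutually disjoint categories.
    """
    from .genotype import site_stats

    fractions = fractions or {"trait_related": 0.1, "common": 0.2}
    extra = set(fractions) - {"trait_related", "common"}
    if extra:
        raise ValueError(f"unsupported categories: {sorted(extra)}")
    if sum(fractions.values()) > 1:
        raise ValueError("fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    n = gm.n_sites
    perm = rng.permutation(n)
    stats = site_stats(gm)
    mafs = np.array([s.maf for s in stats])

    counts = {cat: int(round(f * n)) for cat, f in fractions.items()}
    labels = np.full(n, "", dtype=object)
    cursor = 0
    for cat in ("trait_related", "common"):
        if cat in counts:
            take = perm[cursor:cursor + counts[cat]]
            labels[take] = cat
            cursor += counts[cat]
    rest = perm[cursor:]
    wgs = rest[mafs[rest] > 0.2]
    labels[wgs] = "wgs_polymorphic"

    rows = [
        {"chrom": gm.sites[j].chrom, "pos": gm.sites[j].pos,
         "category": labels[j], "maf": float(mafs[j])}
        for j in range(n) if labels[j]
    ]
    return pd.DataFrame(rows)


def expected_pairwise_fst(f1: float, f2: float | None = None) -> float:
    """Model expectation of the two-population Fst between simulated breeds.

    For breeds with Balding–Nichols parameters F1 and F2 around a shared
    ancestral frequency, HT − HS = (p1 − p2)²/2 has expectation
    (F1 + F2)/2 · p(1 − p) while E[HT] = 2 p (1 − p)(1 − (F1 + F2)/4), so the
    heterozygosity-weighted multi-locus Fst converges to

        (F1 + F2) / (4 − (F1 + F2)),

    which is F/(2 − F) when both breeds share parameter F.  Note this is
    below F itself: F parameterises each breed's divergence from the
    ancestral pool, not the pairwise contrast.
    """
    if f2 is None:
        f2 = f1
    s = f1 + f2
    return s / (4.0 - s)


def simulate(config: SimConfig) -> GenotypeMatrix:
    """Frequencies + genotypes + planted tracts in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    return simulate_genotypes(freqs, config, rng)
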