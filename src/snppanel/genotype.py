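"""Genotype data model, VCF/TSV ingestion, per-site statistics and QC filters.

The central container is :class:`GenotypeMatrix`: samples x biallelic sites
with genotype codes counting copies of the alternate allele (0, 1, 2) and
``MISSING`` (-1) for uncalled genotypes.  Coordinates are 1-based inclusive
(VCF convention) throughout the package; BED output converts to 0-based
half-open at the writing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype code for a missing (uncalled or half-called) diploid genotype.
MISSING: int = -1

_SEX_CHROM_NAMES = frozenset(
    {"X", "Y", "chrX", "chrY", "ChrX", "ChrY", "MT", "chrM", "chrMT", "W", "Z"}
)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP locus.

    ``pos`` is the 1-based base-pair position.  ``ref`` and ``alt`` are
    single-base alleles and must differ.
    """

    chrom: str
    pos: int
    site_id: str = "."
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt allele identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata: breed label and (optionally) sex."""

    sample_id: str
    breed: str
    sex: str | None = None


@dataclass
class SiteStats:
    """Per-site summary statistics, computed on non-missing calls only.

    ``defined`` is False when every call at the site is missing, in which
    case the frequency fields are NaN rather than silently zero.
    """

    p_alt: float
    maf: float
    missing_rate: float
    het_rate: float
    defined: bool = True


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of alt-allele dosage codes.

    ``calls`` has shape ``(n_samples, n_sites)`` with entries in
    ``{0, 1, 2, MISSING}``.  Sites are sorted by chromosome (order of first
    appearance, kept in ``chrom_order``) and then by position.
    """

    sites: list[VariantSite]
    samples: list[SampleInfo]
    calls: np.ndarray
    chrom_order: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"(n_samples={len(self.samples)}, n_sites={len(self.sites)})"
            )
        if not self.chrom_order:
            seen: list[str] = []
            for s in self.sites:
                if s.chrom not in seen:
                    seen.append(s.chrom)
            self.chrom_order = seen
        self._check_sorted()

    def _check_sorted(self) -> None:
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        prev = (-1, -1)
        for s in self.sites:
            key = (rank[s.chrom], s.pos)
            if key <= prev:
                raise ValueError(
                    "sites must be strictly increasing in position within "
                    f"each chromosome (violated at {s.chrom}:{s.pos})"
                )
            prev = key

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def breeds(self) -> np.ndarray:
        return np.asarray([s.breed for s in self.samples])

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.asarray([s.chrom for s in self.sites])

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=np.intp)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            calls=self.calls[idx, :].copy(),
            chrom_order=list(self.chrom_order),
        )

    def subset_sites(self, site_idx: np.ndarray) -> "GenotypeMatrix":
        site_idx = np.asarray(site_idx, dtype=np.intp)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in site_idx],
            samples=list(self.samples),
            calls=self.calls[:, site_idx].copy(),
            chrom_order=list(self.chrom_order),
        )

    def autosomal_chroms(self) -> list[str]:
        return [c for c in self.chrom_order if c not in _SEX_CHROM_NAMES]


# -- ingestion -----------------------------------------------------------------


def read_sample_table(path) -> dict[str, SampleInfo]:
    """Read a sample table TSV with columns sample_id, breed[, sex]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    out: dict[str, SampleInfo] = {}
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", None)
        if sex is not None and (pd.isna(sex) or sex == ""):
            sex = None
        if row.sample_id in out:
            raise ValueError(f"duplicate sample_id in table: {row.sample_id}")
        out[row.sample_id] = SampleInfo(row.sample_id, row.breed, sex)
    return out


_SNP_BASES = frozenset("ACGT")


def read_vcf(path, sample_table) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF (plain or bgzipped) into a matrix.

    ``sample_table`` is a path to a TSV (sample_id, breed[, sex]) or an
    already-parsed ``{sample_id: SampleInfo}`` mapping; every VCF sample must
    appear in it.  Multiallelic and non-SNP records are skipped and counted in
    ``meta['skipped_records']``.  Phased and unphased genotypes are treated
    identically; half-missing diploid calls count as missing.
    """
    from cyvcf2 import VCF

    if not isinstance(sample_table, dict):
        sample_table = read_sample_table(sample_table)

    vcf = VCF(str(path), gts012=True)
    absent = [s for s in vcf.samples if s not in sample_table]
    if absent:
        raise ValueError(f"VCF samples absent from sample table: {absent}")
    samples = [sample_table[s] for s in vcf.samples]

    chrom_order: list[str] = list(vcf.seqnames)
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        if rec.REF not in _SNP_BASES or rec.ALT[0] not in _SNP_BASES:
            skipped += 1
            continue
        if rec.CHROM not in chrom_order:
            chrom_order.append(rec.CHROM)
        sites.append(
            VariantSite(rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0])
        )
        # derive alt dosage from raw allele pairs so half-missing calls
        # (e.g. "0/.") count as MISSING rather than silently as hom-ref
        g = np.asarray(rec.genotype.array(), dtype=np.int16)[:, :2]
        gt = g.sum(axis=1).astype(np.int8)
        gt[(g < 0).any(axis=1)] = MISSING
        cols.append(gt)
    vcf.close()

    if not sites:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)

    calls = np.stack(cols, axis=1)
    rank = {c: i for i, c in enumerate(chrom_order)}
    order = sorted(range(len(sites)), key=lambda i: (rank[sites[i].chrom], sites[i].pos))
    gm = GenotypeMatrix(
        sites=[sites[i] for i in order],
        samples=samples,
        calls=calls[:, order],
        chrom_order=chrom_order,
        meta={"skipped_records": skipped, "source": str(path)},
    )
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCFv4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snppanel\n")
        for chrom in gm.chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_sample_table(gm: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "breed": [s.breed for s in gm.samples],
            "sex": [s.sex or "" for s in gm.samples],
        }
    ).to_csv(path, sep="\t", index=False)


# -- per-site statistics -------------------------------------------------------


def site_stats(gm: GenotypeMatrix, sample_subset: list[str] | None = None) -> list[SiteStats]:
    """Per-site alt frequency, MAF, missingness and observed heterozygosity.

    Frequencies exclude missing calls.  A site where every call is missing
    gets ``defined=False`` with NaN frequencies (its missing_rate is 1).
    """
    calls = gm.calls
    if sample_subset is not None:
        if not sample_subset:
            raise ValueError("sample_subset must be non-empty when given")
        calls = calls[gm.sample_index(sample_subset), :]
    n = calls.shape[0]
    miss = calls == MISSING
    n_obs = n - miss.sum(axis=0)
    dosage = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_obs > 0, dosage / (2.0 * n_obs), np.nan)
        het = np.where(n_obs > 0, (calls == 1).sum(axis=0) / n_obs, np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    missing_rate = miss.sum(axis=0) / n
    return [
        SiteStats(
            p_alt=float(p_alt[j]),
            maf=float(maf[j]),
            missing_rate=float(missing_rate[j]),
            het_rate=float(het[j]),
            defined=bool(n_obs[j] > 0),
        )
        for j in range(calls.shape[1])
    ]


def site_stats_frame(gm: GenotypeMatrix, sample_subset: list[str] | None = None) -> pd.DataFrame:
    """Site statistics as a DataFrame (chrom, pos, p_alt, maf, missing_rate, het_rate)."""
    stats = site_stats(gm, sample_subset)
    return pd.DataFrame(
        {
            "chrom": gm.chroms,
            "pos": gm.positions,
            "p_alt": [s.p_alt for s in stats],
            "maf": [s.maf for s in stats],
            "missing_rate": [s.missing_rate for s in stats],
            "het_rate": [s.het_rate for s in stats],
        }
    )


@dataclass
class FilterResult:
    """Outcome of :func:`filter_sites`: the retained matrix and removal counts."""

    matrix: GenotypeMatrix
    n_removed_missing: int
    n_removed_maf: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_missing + self.n_removed_maf


def filter_sites(
    gm: GenotypeMatrix, max_missing: float = 0.1, min_maf: float = 0.05
) -> FilterResult:
    """QC filter: retain sites with missing_rate < ``max_missing`` and maf >= ``min_maf``.

    The MAF boundary is inclusive (a site at exactly ``min_maf`` is kept);
    removal is the condition maf < ``min_maf``.  Undefined (all-missing)
    sites fail the missingness filter.  Site order is preserved.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    stats = site_stats(gm)
    keep, rm_miss, rm_maf = [], 0, 0
    for j, s in enumerate(stats):
        if not s.defined or s.missing_rate >= max_missing:
            rm_miss += 1
        elif s.maf < min_maf:
            rm_maf += 1
        else:
            keep.append(j)
    if not keep:
        logger.warning("filter_sites: all %d sites removed", gm.n_sites)
    out = gm.subset_sites(np.asarray(keep, dtype=np.intp))
    return FilterResult(out, rm_miss, rm_maf)
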