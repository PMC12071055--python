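"""Reduced-panel construction: priority tiers, 50-kb windows, SD² spacing.

The panel algorithm merges candidate sites from several sources into priority
tiers (1 = breed-specific / trait-related, 2 = common commercial-chip sites,
3 = WGS polymorphic sites with MAF > 0.2), tiles each chromosome with fixed
windows (50 kb by default) and applies a per-window rule:

* exactly one candidate          -> keep it;
* two or more candidates         -> keep the pair (Ni, Nj) minimising
  SD² = variance of {S, Ni, Nj, E} where S, E are the window bounds;
* no candidates                  -> fill with the best supplement site
  (highest priority, then MAF, then leftmost), if any.

Every window decision is written to an audit table so a panel can be traced
back to the rule that produced each site.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype import GenotypeMatrix, site_stats
from .intervals import FeatureSet

logger = logging.getLogger(__name__)

#: Category -> priority tier.  Lower number = higher priority.
CATEGORY_PRIORITY: dict[str, int] = {
    "breed_specific": 1,
    "trait_related": 1,
    "common": 2,
    "wgs_polymorphic": 3,
}

#: Priority assigned to QC-passing supplement sites that fall in no category.
FILLER_PRIORITY: int = 4

#: MAF floor for the wgs_polymorphic category.
WGS_POLYMORPHIC_MIN_MAF: float = 0.2

DEFAULT_WINDOW_BP: int = 50_000

#: Flanking distance (bp) defining upstream/downstream of a gene.
FLANK_BP: int = 5_000

MAF_BINS: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class CandidateSite:
    """A candidate locus with its source category and priority tier."""

    chrom: str
    pos: int
    category: str
    priority: int
    maf: float = float("nan")
    ref: str = "N"
    alt: str = "N"


@dataclass(frozen=True)
class GenomicWindow:
    """A tiling window, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, pos: int) -> bool:
        return self.start < pos <= self.end  # 1-based position in (start, end]


@dataclass
class WindowAudit:
    """The rule applied in one window (kept_single | sd2_pair | filled | empty)."""

    window: GenomicWindow
    rule: str
    sd2: float = float("nan")
    n_candidates: int = 0
    selected_pos: tuple[int, ...] = ()


@dataclass
class PanelDesign:
    """A designed panel: the selected candidate sites plus the window audit trail."""

    selected: list[CandidateSite]
    audit: list[WindowAudit]
    config: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.selected)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.selected:
            counts[c.category] = counts.get(c.category, 0) + 1
        return counts

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_id": [a.window.window_id for a in self.audit],
                "chrom": [a.window.chrom for a in self.audit],
                "start": [a.window.start for a in self.audit],
                "end": [a.window.end for a in self.audit],
                "rule": [a.rule for a in self.audit],
                "sd2": [a.sd2 for a in self.audit],
                "n_candidates": [a.n_candidates for a in self.audit],
                "selected_pos": [",".join(map(str, a.selected_pos)) for a in self.audit],
            }
        )

    def panel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.selected],
                "pos": [c.pos for c in self.selected],
                "ref": [c.ref for c in self.selected],
                "alt": [c.alt for c in self.selected],
                "category": [c.category for c in self.selected],
                "priority": [c.priority for c in self.selected],
                "maf": [c.maf for c in self.selected],
            }
        )

    def bed_frame(self) -> pd.DataFrame:
        """Panel sites in BED form (0-based half-open)."""
        return pd.DataFrame(
            {
                "chrom": [c.chrom for c in self.selected],
                "start": [c.pos - 1 for c in self.selected],
                "end": [c.pos for c in self.selected],
                "name": [c.category for c in self.selected],
            }
        )


# -- priority assignment -------------------------------------------------------


def assign_priorities(candidates) -> tuple[list[CandidateSite], int]:
    """Map categorised sites to priority tiers and deduplicate physical loci.

    ``candidates`` is a DataFrame (chrom, pos, category[, maf, ref, alt]) or an
    iterable of such records.  A physical (chrom, pos) appearing under several
    categories keeps the entry with the lowest priority number (highest
    priority).  ``wgs_polymorphic`` entries require maf > 0.2 and are rejected
    (counted) otherwise.  Returns (sites, n_rejected).
    """
    if isinstance(candidates, pd.DataFrame):
        records = candidates.to_dict("records")
    else:
        records = list(candidates)
    best: dict[tuple[str, int], CandidateSite] = {}
    n_rejected = 0
    for rec in records:
        if isinstance(rec, CandidateSite):
            rec = {
                "chrom": rec.chrom, "pos": rec.pos, "category": rec.category,
                "maf": rec.maf, "ref": rec.ref, "alt": rec.alt,
            }
        category = rec["category"]
        if category not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown candidate category: {category!r}")
        maf = float(rec.get("maf", float("nan")))
        if category == "wgs_polymorphic" and not maf > WGS_POLYMORPHIC_MIN_MAF:
            n_rejected += 1
            continue
        site = CandidateSite(
            chrom=str(rec["chrom"]),
            pos=int(rec["pos"]),
            category=category,
            priority=CATEGORY_PRIORITY[category],
            maf=maf,
            ref=str(rec.get("ref", "N")),
            alt=str(rec.get("alt", "N")),
        )
        key = (site.chrom, site.pos)
        if key not in best or site.priority < best[key].priority:
            best[key] = site
    if n_rejected:
        logger.info("assign_priorities: rejected %d wgs_polymorphic sites with MAF <= %.2f",
                    n_rejected, WGS_POLYMORPHIC_MIN_MAF)
    return list(best.values()), n_rejected


# -- windows and spacing -------------------------------------------------------


def make_windows(chrom_lengths, width: int = DEFAULT_WINDOW_BP) -> list[GenomicWindow]:
    """Tile each chromosome with disjoint windows covering [0, length).

    ``chrom_lengths`` is a {chrom: length} mapping or a two-column frame
    (chrom, length).  The last window of a chromosome may be short.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if isinstance(chrom_lengths, pd.DataFrame):
        chrom_lengths = dict(zip(chrom_lengths.iloc[:, 0].astype(str),
                                 chrom_lengths.iloc[:, 1].astype(int)))
    windows: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, width):
            windows.append(GenomicWindow(str(chrom), start, min(start + width, length)))
    return windows


def sd2_spacing(S: float, E: float, Ni: float, Nj: float) -> float:
    """Spacing criterion for a window: variance of the four positions.

    With X̄ = (S + Ni + Nj + E)/4,

        SD² = ((S − X̄)² + (Ni − X̄)² + (Nj − X̄)² + (E − X̄)²) / 4.

    S and E are the window bounds; Ni < Nj are the two candidate positions.
    """
    if Ni == Nj:
        raise ValueError("Ni and Nj must be distinct positions")
    if not (S <= Ni < Nj <= E):
        raise ValueError(f"require S <= Ni < Nj <= E, got S={S}, Ni={Ni}, Nj={Nj}, E={E}")
    xs = np.array([S, Ni, Nj, E], dtype=float)
    xbar = xs.mean()
    return float(np.mean((xs - xbar) ** 2))


def select_window_sites(
    window: GenomicWindow,
    candidates: list[CandidateSite],
    supplement_pool: list[CandidateSite] | None = None,
) -> tuple[list[CandidateSite], WindowAudit]:
    """Apply the per-window selection rule.

    * 1 candidate  -> kept (rule ``kept_single``).
    * >=2          -> the pair minimising :func:`sd2_spacing`; ties broken by
      higher combined priority (smaller priority-number sum), then the
      leftmost pair (rule ``sd2_pair``).
    * 0 candidates -> the single best supplement site, ranked by priority
      tier, then higher MAF, then leftmost position (rule ``filled``); with
      an empty pool the window stays empty (rule ``empty``).
    """
    supplement_pool = supplement_pool or []
    for c in candidates + supplement_pool:
        if not window.contains(c.pos):
            raise ValueError(f"site {c.chrom}:{c.pos} outside window {window.window_id}")

    if len(candidates) == 1:
        return list(candidates), WindowAudit(window, "kept_single", n_candidates=1,
                                             selected_pos=(candidates[0].pos,))
    if len(candidates) >= 2:
        ordered = sorted(candidates, key=lambda c: c.pos)
        best_key, best_pair, best_sd2 = None, None, None
        for a, b in itertools.combinations(ordered, 2):
            sd2 = sd2_spacing(window.start, window.end, a.pos, b.pos)
            key = (sd2, a.priority + b.priority, a.pos, b.pos)
            if best_key is None or key < best_key:
                best_key, best_pair, best_sd2 = key, (a, b), sd2
        assert best_pair is not None
        return list(best_pair), WindowAudit(
            window, "sd2_pair", sd2=best_sd2, n_candidates=len(candidates),
            selected_pos=(best_pair[0].pos, best_pair[1].pos),
        )
    if supplement_pool:
        fill = min(
            supplement_pool,
            key=lambda c: (c.priority, -(c.maf if np.isfinite(c.maf) else -1.0), c.pos),
        )
        return [fill], WindowAudit(window, "filled", selected_pos=(fill.pos,))
    return [], WindowAudit(window, "empty")


# -- panel assembly ------------------------------------------------------------


def build_panel(
    gm: GenotypeMatrix | None,
    candidates: list[CandidateSite],
    chrom_lengths,
    width: int = DEFAULT_WINDOW_BP,
    cap_exempt_priority1: bool = False,
    pool_max_missing: float = 0.1,
    pool_min_maf: float = 0.05,
) -> PanelDesign:
    """Assemble a panel by running the window rule over every chromosome.

    ``gm`` supplies the supplement pool for empty windows: its QC-passing
    sites (missingness < ``pool_max_missing``, MAF >= ``pool_min_maf``) that
    are not themselves candidates, tiered as priority 3 when MAF > 0.2 and
    priority 4 otherwise.  Pass ``gm=None`` to design from candidates alone.

    With ``cap_exempt_priority1`` every priority-1 candidate is kept and the
    two-per-window rule applies only to priority-2/3 candidates; the default
    (off) applies the rule to all candidates.
    """
    if isinstance(chrom_lengths, pd.DataFrame):
        chrom_lengths = dict(zip(chrom_lengths.iloc[:, 0].astype(str),
                                 chrom_lengths.iloc[:, 1].astype(int)))
    lengths = {str(k): int(v) for k, v in chrom_lengths.items()}
    bad = sorted({c.chrom for c in candidates} - set(lengths))
    if bad:
        raise ValueError(f"candidate chromosomes absent from chrom_lengths: {bad}")

    windows = make_windows(lengths, width)
    by_window: dict[tuple[str, int], list[CandidateSite]] = {}
    for c in candidates:
        by_window.setdefault((c.chrom, (c.pos - 1) // width), []).append(c)

    pool_by_window: dict[tuple[str, int], list[CandidateSite]] = {}
    if gm is not None:
        cand_keys = {(c.chrom, c.pos) for c in candidates}
        stats = site_stats(gm)
        for site, st in zip(gm.sites, stats):
            if (site.chrom, site.pos) in cand_keys or site.chrom not in lengths:
                continue
            if not st.defined or st.missing_rate >= pool_max_missing or st.maf < pool_min_maf:
                continue
            tier = 3 if st.maf > WGS_POLYMORPHIC_MIN_MAF else FILLER_PRIORITY
            pool_by_window.setdefault((site.chrom, (site.pos - 1) // width), []).append(
                CandidateSite(site.chrom, site.pos,
                              "wgs_polymorphic" if tier == 3 else "supplement",
                              tier, st.maf, site.ref, site.alt)
            )

    selected: list[CandidateSite] = []
    audits: list[WindowAudit] = []
    for win in windows:
        key = (win.chrom, win.start // width)
        cands = sorted(by_window.get(key, []), key=lambda c: c.pos)
        pool = sorted(pool_by_window.get(key, []), key=lambda c: c.pos)
        if cap_exempt_priority1:
            p1 = [c for c in cands if c.priority == 1]
            rest = [c for c in cands if c.priority > 1]
            if p1:
                chosen = list(p1)
                if rest:
                    extra, _ = select_window_sites(win, rest, None)
                    chosen += extra
                rule = "kept_single" if len(chosen) == 1 else "priority1_exempt"
                audit = WindowAudit(win, rule, n_candidates=len(cands),
                                    selected_pos=tuple(c.pos for c in chosen))
            else:
                chosen, audit = select_window_sites(win, rest, pool)
        else:
            chosen, audit = select_window_sites(win, cands, pool)
        # restore priority-4 fills to a plain tier label in the output
        selected.extend(replace(c, priority=min(c.priority, 3)) for c in chosen)
        audits.append(audit)

    panel = PanelDesign(
        selected=selected,
        audit=audits,
        config={
            "width": width,
            "cap_exempt_priority1": cap_exempt_priority1,
            "pool_max_missing": pool_max_missing,
            "pool_min_maf": pool_min_maf,
        },
    )
    logger.info("build_panel: %d sites selected (%s)", panel.total, panel.category_counts())
    return panel


def detection_rate(n_detected: int, n_panel: int) -> float:
    """Percentage of panel loci detected in a genotyped population."""
    if n_panel <= 0:
        raise ValueError("panel size must be positive")
    return 100.0 * n_detected / n_panel


# -- reporting -----------------------------------------------------------------


def classify_site_region(chrom: str, pos: int, annotation: FeatureSet) -> str:
    """Genomic region class of a position relative to gene annotation.

    Precedence: exonic > intronic > upstream > downstream > intergenic.
    Upstream/downstream means within 5 kb of the gene start/end respecting
    strand (for a minus-strand gene 'upstream' lies past its right end).
    """
    if chrom not in annotation.trees:
        logger.warning("classify_site_region: chromosome %s absent from annotation", chrom)
        return "intergenic"
    labels: set[str] = set()
    for gid in annotation.overlapping(chrom, pos - FLANK_BP, pos + FLANK_BP):
        g = annotation.genes[gid]
        if g.start <= pos <= g.end:
            in_exon = any(s <= pos <= e for s, e in g.exons)
            labels.add("exonic" if in_exon else "intronic")
        elif pos < g.start:
            labels.add("upstream" if g.strand == "+" else "downstream")
        else:
            labels.add("downstream" if g.strand == "+" else "upstream")
    for label in ("exonic", "intronic", "upstream", "downstream"):
        if label in labels:
            return label
    return "intergenic"


def panel_report(
    panel: PanelDesign,
    gm: GenotypeMatrix | None = None,
    annotation: FeatureSet | None = None,
) -> dict:
    """Summary report: per-chromosome counts, MAF spectrum, density, regions.

    MAF values come from the candidate records; when a genotype matrix is
    supplied, sites lacking a MAF are looked up in it.
    """
    per_chrom: dict[str, int] = {}
    for c in panel.selected:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1

    mafs = np.array([c.maf for c in panel.selected], dtype=float)
    if gm is not None and np.isnan(mafs).any():
        lookup = {(s.chrom, s.pos): st.maf
                  for s, st in zip(gm.sites, site_stats(gm))}
        for i, c in enumerate(panel.selected):
            if np.isnan(mafs[i]):
                mafs[i] = lookup.get((c.chrom, c.pos), np.nan)
    known = mafs[~np.isnan(mafs)]
    hist, _ = np.histogram(known, bins=MAF_BINS)
    maf_hist = {
        f"[{MAF_BINS[i]:g},{MAF_BINS[i + 1]:g})" if i < len(hist) - 1
        else f"[{MAF_BINS[i]:g},{MAF_BINS[i + 1]:g}]": int(hist[i])
        for i in range(len(hist))
    }

    n_windows = len(panel.audit)
    rules = pd.Series([a.rule for a in panel.audit]).value_counts().to_dict()
    report = {
        "total": panel.total,
        "per_chrom": per_chrom,
        "category_counts": panel.category_counts(),
        "maf_hist": maf_hist,
        "n_windows": n_windows,
        "sites_per_window": panel.total / n_windows if n_windows else float("nan"),
        "window_rules": rules,
    }
    if annotation is not None:
        regions: dict[str, int] = {}
        for c in panel.selected:
            label = classify_site_region(c.chrom, c.pos, annotation)
            regions[label] = regions.get(label, 0) + 1
        report["region_counts"] = regions
    return report


# -- genotyping QC comparisons -------------------------------------------------


def sample_call_rates(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample call and missingness rates over all sites."""
    from .genotype import MISSING

    miss = (gm.calls == MISSING).mean(axis=1)
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "breed": [s.breed for s in gm.samples],
            "sex": [s.sex for s in gm.samples],
            "call_rate": 1.0 - miss,
            "missing_rate": miss,
        }
    )


def qc_compare_groups(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Welch two-sample t-tests of a per-sample statistic between groups.

    ``values`` is a per-sample numeric vector (e.g. call rate); ``groups`` the
    matching labels (sex or breed).  Groups with fewer than two samples are
    excluded with a warning.  Returns one row per group pair with means and
    the two-sided p-value; ``significant`` marks p < ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    usable = []
    for g in pd.unique(groups):
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        if (groups == g).sum() >= 2:
            usable.append(g)
        else:
            logger.warning("qc_compare_groups: group %r has < 2 samples; excluded", g)
    rows = []
    for g1, g2 in itertools.combinations(usable, 2):
        x, y = values[groups == g1], values[groups == g2]
        if np.allclose(x.var(), 0) and np.allclose(y.var(), 0) and np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0  # identical constant groups: no evidence of difference
        else:
            t, p = sps.ttest_ind(x, y, equal_var=False)
        rows.append({
            "group1": g1, "group2": g2,
            "mean1": float(x.mean()), "mean2": float(y.mean()),
            "n1": len(x), "n2": len(y),
            "t": float(t), "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
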