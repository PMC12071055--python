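"""Gene / feature interval handling: GFF3 and BED ingestion, overlap indexes.

Internally all intervals are 1-based inclusive (GFF convention); BED input is
converted on read and BED output on write.  Overlap queries go through
:mod:`intervaltree`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class Gene:
    """A gene interval with optional exon structure (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class FeatureSet:
    """Per-chromosome interval index over genes or generic features."""

    genes: dict[str, Gene]
    trees: dict[str, IntervalTree]
    n_skipped: int = 0

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """IDs of features whose 1-based inclusive span intersects [start, end]."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        # interval tree is half-open: store [start, end+1)
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path) -> FeatureSet:
    """Extract gene intervals (with exon structure) from a GFF3 file.

    Features of type ``gene`` define intervals; ``exon`` features are attached
    to their gene via Parent chains when the Parent refers directly to a gene
    ID, or via an mRNA whose Parent is a gene.  Malformed lines are skipped
    and counted.
    """
    genes: dict[str, Gene] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, int, int]] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                skipped += 1
                continue
            chrom, _, ftype, start, end, _, strand, _, attr = fields[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                skipped += 1
                continue
            attrs = _parse_gff_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if gid is None:
                    skipped += 1
                    continue
                genes[gid] = Gene(gid, chrom, start_i, end_i, strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    skipped += 1
                    continue
                pending_exons.append((parent, start_i, end_i))
    for parent, s, e in pending_exons:
        gid = parent if parent in genes else mrna_parent.get(parent)
        if gid in genes:
            genes[gid].exons.append((s, e))
    if skipped:
        logger.info("read_gff3_genes: skipped %d malformed lines", skipped)
    return _build_featureset(genes, skipped)


def read_bed_intervals(path) -> FeatureSet:
    """Read generic features from BED (0-based half-open -> 1-based inclusive)."""
    genes: dict[str, Gene] = {}
    skipped = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                skipped += 1
                continue
            try:
                start = int(fields[1]) + 1
                end = int(fields[2])
            except ValueError:
                skipped += 1
                continue
            name = fields[3] if len(fields) > 3 else f"feature_{i + 1}"
            strand = fields[5] if len(fields) > 5 else "+"
            genes[name] = Gene(name, fields[0], start, end, strand)
    if skipped:
        logger.info("read_bed_intervals: skipped %d malformed lines", skipped)
    return _build_featureset(genes, skipped)


def _build_featureset(genes: dict[str, Gene], n_skipped: int) -> FeatureSet:
    trees: dict[str, IntervalTree] = {}
    for g in genes.values():
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    return FeatureSet(genes=genes, trees=trees, n_skipped=n_skipped)
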