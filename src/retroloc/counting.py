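"""Hierarchical repeat-aware read counting.

Individual repeat copies cannot be quantified when copies are near
identical, so counting collapses multimapping fragments once per taxonomy
level: a fragment whose placements all fall entirely within copies of one
element adds 1 to that element; a fragment spanning several elements of one
family still adds 1 to the family (and likewise for the class), but nothing
at the element level.  Only alignments mapping entirely within a copy are
eligible.  Single-copy genes are counted from uniquely placed fragments by
exonic overlap, with an optional 3'-window mode for degraded libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, RepeatCopy, RepeatTaxonomy
from .samio import ReadAlignmentGroup

LEVELS = ("gene", "element", "family", "class")
STRAND_MODES = ("unstranded", "same", "opposite")


@dataclass
class CountTable:
    """Features x samples counts at one summarization level."""

    level: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature names")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def combine_tables(tables: Sequence[CountTable]) -> CountTable:
    """Column-concatenate single-sample tables sharing one level."""
    level = tables[0].level
    if any(t.level != level for t in tables):
        raise ValueError("tables are at different levels")
    df = pd.concat([t.counts for t in tables], axis=1).fillna(0)
    return CountTable(level, df)


class CopyIndex:
    """Interval lookup of repeat copies for containment tests."""

    def __init__(self, copies: Sequence[RepeatCopy]):
        self.copies = list(copies)
        self._trees: dict[str, IntervalTree] = {}
        for i, c in enumerate(self.copies):
            self._trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, i)
        self.by_id = {c.copy_id: c for c in self.copies}

    def containing(self, chrom: str, start: int, end: int) -> list[RepeatCopy]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [
            self.copies[iv.data]
            for iv in tree.overlap(start, end)
            if iv.begin <= start and iv.end >= end
        ]


def _strand_ok(rec_strand: str, copy_strand: str, strand_mode: str) -> bool:
    if strand_mode == "unstranded":
        return True
    if strand_mode == "same":
        return rec_strand == copy_strand
    if strand_mode == "opposite":
        return rec_strand != copy_strand
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def assign_fragment_to_copies(
    group: ReadAlignmentGroup,
    index: CopyIndex,
    strand_mode: str = "unstranded",
) -> set[str]:
    """Copy ids hit by a fragment.

    A record hits a copy iff every aligned block lies entirely within the
    copy's span and the strand condition holds; the fragment's hit set is
    the union over its records.  Records outside every copy contribute
    nothing.
    """
    hits: set[str] = set()
    for rec in group.records:
        for copy in index.containing(rec.chrom, rec.start, rec.end):
            if _strand_ok(rec.strand, copy.strand, strand_mode):
                hits.add(copy.copy_id)
    return hits


def _feature_universe(
    copies: Sequence[RepeatCopy], taxonomy: RepeatTaxonomy, level: str
) -> list[str]:
    if level == "element":
        names = {c.element for c in copies}
    elif level == "family":
        names = {taxonomy.family_of(c.element) for c in copies}
    elif level == "class":
        names = {taxonomy.class_of(c.element) for c in copies}
    else:
        raise ValueError(f"unknown repeat level {level!r}")
    return sorted(names)


def _collapse_hits(
    hit_ids: set[str],
    index: CopyIndex,
    taxonomy: RepeatTaxonomy,
    level: str,
) -> str | None:
    """Feature credited at ``level`` by the once-per-level rule, or None."""
    if not hit_ids:
        return None
    if level == "element":
        names = {index.by_id[cid].element for cid in hit_ids}
    elif level == "family":
        names = {taxonomy.family_of(index.by_id[cid].element) for cid in hit_ids}
    else:
        names = {taxonomy.class_of(index.by_id[cid].element) for cid in hit_ids}
    if len(names) == 1:
        return next(iter(names))
    return None


def count_repeats(
    groups: Iterable[ReadAlignmentGroup],
    copies: Sequence[RepeatCopy] | CopyIndex,
    taxonomy: RepeatTaxonomy,
    level: str,
    strand_mode: str = "unstranded",
    sample: str = "sample",
) -> CountTable:
    """Count fragments against repeats at one taxonomy level.

    Each fragment contributes at most 1: to the single element (family,
    class) containing every copy it hits, or nothing when its hits span
    several features at that level.
    """
    index = copies if isinstance(copies, CopyIndex) else CopyIndex(copies)
    features = _feature_universe(index.copies, taxonomy, level)
    counts = dict.fromkeys(features, 0)
    for grp in groups:
        hit = assign_fragment_to_copies(grp, index, strand_mode)
        name = _collapse_hits(hit, index, taxonomy, level)
        if name is not None:
            counts[name] += 1
    return CountTable(
        level, pd.DataFrame({sample: pd.Series(counts, dtype=int)}).loc[features]
    )


class GeneWindows:
    """Genomic windows per gene under a counting mode."""

    def __init__(self, genes: Sequence[GeneModel], mode: str = "exonic",
                 last_bp: int = 500):
        if mode not in ("exonic", "last500bp"):
            raise ValueError(f"unknown gene counting mode {mode!r}")
        self.genes = list(genes)
        self.windows: list[list[tuple[int, int]]] = []
        self._tree: dict[str, IntervalTree] = {}
        for gi, g in enumerate(self.genes):
            if mode == "exonic":
                win = list(g.exons)
            else:
                win = _three_prime_window(g, last_bp)
            self.windows.append(win)
            for s, e in win:
                self._tree.setdefault(g.chrom, IntervalTree()).addi(s, e, gi)

    def overlaps(self, chrom: str, start: int, end: int) -> set[int]:
        tree = self._tree.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def _three_prime_window(gene: GeneModel, last_bp: int) -> list[tuple[int, int]]:
    """Exonic intervals covering the 3'-most ``last_bp`` transcript bases."""
    tlen = gene.transcript_length
    keep = min(last_bp, tlen)
    # transcript window in genomic-offset coordinates
    if gene.strand == "+":
        lo, hi = tlen - keep, tlen
    else:
        lo, hi = 0, keep
    out: list[tuple[int, int]] = []
    off = 0
    for s, e in gene.exons:
        elen = e - s
        a, b = max(lo, off), min(hi, off + elen)
        if a < b:
            out.append((s + a - off, s + b - off))
        off += elen
    return out


def count_genes(
    groups: Iterable[ReadAlignmentGroup],
    genes: Sequence[GeneModel] | GeneWindows,
    mode: str = "exonic",
    unique_only: bool = True,
    min_overlap_fraction: float = 0.5,
    last_bp: int = 500,
    sample: str = "sample",
) -> CountTable:
    """Count fragments against single-copy genes.

    Only uniquely placed fragments are counted (when ``unique_only``); a
    fragment is assigned to a gene when at least ``min_overlap_fraction`` of
    its aligned bases fall in the gene's counting window (exons, or their
    intersection with the 3'-most ``last_bp`` transcript bases).  Fragments
    qualifying for two or more genes are discarded.
    """
    win = genes if isinstance(genes, GeneWindows) else GeneWindows(genes, mode, last_bp)
    counts = {g.gene_id: 0 for g in win.genes}
    for grp in groups:
        if unique_only and not grp.is_unique:
            continue
        total = 0
        per_gene: dict[int, int] = {}
        for rec in grp.records:
            if rec.is_secondary:
                continue
            total += rec.aligned_bases
            for s, e in rec.blocks:
                for gi in win.overlaps(rec.chrom, s, e):
                    ov = 0
                    for ws, we in win.windows[gi]:
                        a, b = max(s, ws), min(e, we)
                        if a < b:
                            ov += b - a
                    if ov:
                        per_gene[gi] = per_gene.get(gi, 0) + ov
        if not total:
            continue
        qualified = [gi for gi, ov in per_gene.items()
                     if ov >= min_overlap_fraction * total]
        if len(qualified) == 1:
            counts[win.genes[qualified[0]].gene_id] += 1
    features = sorted(counts)
    return CountTable(
        "gene", pd.DataFrame({sample: pd.Series(counts, dtype=int)}).loc[features]
    )


def count_all_levels(
    groups: Sequence[ReadAlignmentGroup],
    copies: Sequence[RepeatCopy] | CopyIndex,
    taxonomy: RepeatTaxonomy,
    genes: Sequence[GeneModel],
    strand_mode: str = "unstranded",
    gene_mode: str = "exonic",
    unique_only_genes: bool = True,
    sample: str = "sample",
) -> dict[str, CountTable]:
    """One streaming pass producing gene/element/family/class tables.

    Equivalent to running the level-specific counters independently.
    """
    index = copies if isinstance(copies, CopyIndex) else CopyIndex(copies)
    win = GeneWindows(genes, gene_mode)
    feat = {lvl: _feature_universe(index.copies, taxonomy, lvl)
            for lvl in ("element", "family", "class")}
    counts = {lvl: dict.fromkeys(feat[lvl], 0) for lvl in feat}
    gene_counts = {g.gene_id: 0 for g in win.genes}

    for grp in groups:
        hit = assign_fragment_to_copies(grp, index, strand_mode)
        for lvl in ("element", "family", "class"):
            name = _collapse_hits(hit, index, taxonomy, lvl)
            if name is not None:
                counts[lvl][name] += 1
        if unique_only_genes and not grp.is_unique:
            continue
        total = 0
        per_gene: dict[int, int] = {}
        for rec in grp.records:
            if rec.is_secondary:
                continue
            total += rec.aligned_bases
            for s, e in rec.blocks:
                for gi in win.overlaps(rec.chrom, s, e):
                    ov = 0
                    for ws, we in win.windows[gi]:
                        a, b = max(s, ws), min(e, we)
                        if a < b:
                            ov += b - a
                    if ov:
                        per_gene[gi] = per_gene.get(gi, 0) + ov
        if not total:
            continue
        qualified = [gi for gi, ov in per_gene.items() if ov >= 0.5 * total]
        if len(qualified) == 1:
            gene_counts[win.genes[qualified[0]].gene_id] += 1

    out: dict[str, CountTable] = {
        "gene": CountTable(
            "gene",
            pd.DataFrame({sample: pd.Series(gene_counts, dtype=int)})
            .loc[sorted(gene_counts)],
        )
    }
    for lvl in ("element", "family", "class"):
        out[lvl] = CountTable(
            lvl,
            pd.DataFrame({sample: pd.Series(counts[lvl], dtype=int)}).loc[feat[lvl]],
        )
    return out


__all__ = [
    "LEVELS",
    "STRAND_MODES",
    "CountTable",
    "combine_tables",
    "CopyIndex",
    "GeneWindows",
    "assign_fragment_to_copies",
    "count_repeats",
    "count_genes",
    "count_all_levels",
]
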