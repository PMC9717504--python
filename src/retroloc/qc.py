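"""Fractionation and RNA-integrity quality control.

Two statistics drive sample inclusion:

* the splicing index (SI) of each protein-coding gene — the fraction of
  informative reads that indicate splicing; cytoplasmic fractions of well
  separated samples sit near SI = 1 while nuclear fractions contain
  partially spliced pre-mRNA (SI < 1);
* the 5'/3' gene-body coverage ratio over the most highly expressed genes —
  normalized coverage at transcript position 15 versus 85; a greater than
  2.5-fold disparity in either direction marks a degraded library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .samio import AlignmentRecord, ReadAlignmentGroup


@dataclass(frozen=True)
class SpliceIndexResult:
    gene_id: str
    spliced_reads: int
    informative_reads: int

    @property
    def splicing_index(self) -> float | None:
        if self.informative_reads == 0:
            return None
        return self.spliced_reads / self.informative_reads


@dataclass(frozen=True)
class GeneBodyCoverage:
    """Mean normalized coverage at 101 normalized transcript positions."""

    profile: np.ndarray  # length 101
    n_genes_used: int

    @property
    def ratio_5p_3p(self) -> float | None:
        if self.profile[85] <= 0:
            return None
        return float(self.profile[15] / self.profile[85])


@dataclass(frozen=True)
class IntegrityVerdict:
    passed: bool
    ratio_5p_3p: float | None
    reason: str


def _fragment_splice_status(
    group: ReadAlignmentGroup,
    gene: GeneModel,
    introns: Sequence[tuple[int, int]],
    boundaries: Sequence[int],
    min_overhang: int,
) -> tuple[bool, bool]:
    """(indicates_splicing, crosses_boundary) for one fragment vs one gene."""
    spliced = False
    boundary = False
    for rec in group.records:
        if rec.chrom != gene.chrom:
            continue
        blocks = rec.blocks
        for i in range(len(blocks) - 1):
            gap = (blocks[i][1], blocks[i + 1][0])
            if gap in introns:
                left = blocks[i][1] - blocks[i][0]
                right = blocks[i + 1][1] - blocks[i + 1][0]
                if left >= min_overhang and right >= min_overhang:
                    spliced = True
        if not spliced:
            for s, e in blocks:
                for b in boundaries:
                    if s <= b - min_overhang and e >= b + min_overhang:
                        boundary = True
                        break
                if boundary:
                    break
    return spliced, boundary


def splicing_index(
    groups: Iterable[ReadAlignmentGroup],
    gene: GeneModel,
    min_overhang: int = 6,
) -> SpliceIndexResult:
    """SI = reads indicating splicing / total informative reads, per gene.

    A fragment indicates splicing when an alignment gap exactly matches an
    annotated intron with at least ``min_overhang`` aligned bases on both
    flanking exons; it is informative when it does so or crosses an
    exon-intron boundary with the same overhang on each side.  Reads fully
    inside an intron are not informative.
    """
    introns = set(gene.introns())
    if not introns:
        raise ValueError(f"{gene.gene_id}: splicing index needs >= 1 intron")
    boundaries = sorted({p for iv in introns for p in iv})
    intron_tuples = frozenset(introns)
    spliced_n = 0
    informative_n = 0
    for grp in groups:
        spliced, boundary = _fragment_splice_status(
            grp, gene, intron_tuples, boundaries, min_overhang
        )
        if spliced or boundary:
            informative_n += 1
        if spliced:
            spliced_n += 1
    return SpliceIndexResult(gene.gene_id, spliced_n, informative_n)


def splicing_index_distribution(
    groups: Sequence[ReadAlignmentGroup],
    genes: Sequence[GeneModel],
    min_overhang: int = 6,
    min_informative: int = 10,
) -> tuple[pd.DataFrame, dict[str, float | int | None]]:
    """Per-gene SI table plus boxplot summary statistics for one sample.

    Genes with fewer than ``min_informative`` informative reads are reported
    with an undefined SI and excluded from the summary.
    """
    trees: dict[str, IntervalTree] = {}
    multi_exon = [g for g in genes if len(g.exons) > 1]
    for gi, g in enumerate(multi_exon):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, gi)
    per_gene: dict[int, list[ReadAlignmentGroup]] = {gi: [] for gi in range(len(multi_exon))}
    for grp in groups:
        hit: set[int] = set()
        for rec in grp.records:
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(rec.start, rec.end):
                hit.add(iv.data)
        for gi in hit:
            per_gene[gi].append(grp)
    rows = []
    values = []
    for gi, g in enumerate(multi_exon):
        res = splicing_index(per_gene[gi], g, min_overhang=min_overhang)
        si = res.splicing_index if res.informative_reads >= min_informative else None
        rows.append((g.gene_id, res.spliced_reads, res.informative_reads, si))
        if si is not None:
            values.append(si)
    table = pd.DataFrame(
        rows, columns=["gene_id", "spliced_reads", "informative_reads", "splicing_index"]
    )
    arr = np.array(values, dtype=float)
    summary = {
        "n_genes": int(arr.size),
        "median": float(np.median(arr)) if arr.size else None,
        "q25": float(np.percentile(arr, 25)) if arr.size else None,
        "q75": float(np.percentile(arr, 75)) if arr.size else None,
    }
    return table, summary


def gene_body_coverage(
    records: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    top_n: int = 500,
) -> GeneBodyCoverage:
    """Mean normalized exonic coverage profile over the top-N expressed genes.

    Genes are ranked by exonic read count within this sample (ties broken by
    gene_id); each selected gene's per-base exonic coverage is taken in
    5'->3' transcript orientation, binned to 101 normalized positions,
    scaled to mean 1, and averaged across genes.
    """
    records = list(records)
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        for s, e in g.exons:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, gi)

    gene_hits: dict[int, list[AlignmentRecord]] = {gi: [] for gi in range(len(genes))}
    for rec in records:
        if rec.is_secondary:
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hit: set[int] = set()
        for s, e in rec.blocks:
            for iv in tree.overlap(s, e):
                hit.add(iv.data)
        for gi in hit:
            gene_hits[gi].append(rec)

    ranked = sorted(
        range(len(genes)),
        key=lambda gi: (-len(gene_hits[gi]), genes[gi].gene_id),
    )
    ranked = [gi for gi in ranked if gene_hits[gi]][:top_n]
    if not ranked:
        raise ValueError("no expressed gene found for coverage profiling")

    profiles = np.zeros((len(ranked), 101))
    for row, gi in enumerate(ranked):
        g = genes[gi]
        tlen = g.transcript_length
        cov = np.zeros(tlen)
        # map exonic block overlap into transcript coordinates
        offsets = []
        off = 0
        for s, e in g.exons:
            offsets.append((s, e, off))
            off += e - s
        for rec in gene_hits[gi]:
            for bs, be in rec.blocks:
                for s, e, off in offsets:
                    a, b = max(bs, s), min(be, e)
                    if a < b:
                        cov[off + a - s : off + b - s] += 1
        if g.strand == "-":
            cov = cov[::-1]
        # 101 normalized positions
        pos = (np.arange(tlen) * 101) // tlen
        sums = np.bincount(pos, weights=cov, minlength=101)
        counts = np.bincount(pos, minlength=101)
        prof = np.divide(sums, counts, out=np.zeros(101), where=counts > 0)
        mean = prof.mean()
        if mean > 0:
            prof = prof / mean
        profiles[row] = prof
    return GeneBodyCoverage(profile=profiles.mean(axis=0), n_genes_used=len(ranked))


def integrity_filter(cov: GeneBodyCoverage, max_fold: float = 2.5) -> IntegrityVerdict:
    """Fail a sample whose 5'/3' coverage disparity exceeds ``max_fold``.

    Applied two-sided: a ratio r fails iff max(r, 1/r) > max_fold; exactly
    ``max_fold`` passes (the exclusion rule is a strict inequality).
    """
    ratio = cov.ratio_5p_3p
    if ratio is None or ratio <= 0:
        return IntegrityVerdict(False, ratio, "coverage ratio undefined")
    disparity = max(ratio, 1.0 / ratio)
    if disparity > max_fold:
        return IntegrityVerdict(
            False, ratio, f"5p/3p disparity {disparity:.2f}-fold > {max_fold}"
        )
    return IntegrityVerdict(True, ratio, "ok")


def filter_duplicates(
    groups: Iterable[ReadAlignmentGroup],
) -> tuple[list[ReadAlignmentGroup], int]:
    """Remove duplicate-flagged records; empty fragments vanish.

    Returns the surviving groups and the number of records removed.
    """
    out: list[ReadAlignmentGroup] = []
    removed = 0
    for grp in groups:
        kept = [r for r in grp.records if not r.is_duplicate]
        removed += len(grp.records) - len(kept)
        if kept:
            out.append(ReadAlignmentGroup(grp.read_id, kept))
    return out, removed


def subsample_to_smallest(
    samples: Mapping[str, Sequence[ReadAlignmentGroup]],
    seed: int = 0,
) -> dict[str, list[ReadAlignmentGroup]]:
    """Downsample every sample to the smallest sample's fragment count.

    Whole read-name groups are kept or dropped together, so a multimapping
    fragment's records stay atomic.  Deterministic given ``seed``; sample
    identity (not dict order) selects each subsampling stream.
    """
    if len(samples) < 2:
        raise ValueError("subsampling needs at least two samples")
    import zlib

    target = min(len(g) for g in samples.values())
    out: dict[str, list[ReadAlignmentGroup]] = {}
    for name, groups in samples.items():
        groups = list(groups)
        if len(groups) == target:
            out[name] = groups
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
        )
        idx = rng.choice(len(groups), size=target, replace=False)
        idx.sort()
        out[name] = [groups[i] for i in idx]
    return out


__all__ = [
    "SpliceIndexResult",
    "GeneBodyCoverage",
    "IntegrityVerdict",
    "splicing_index",
    "splicing_index_distribution",
    "gene_body_coverage",
    "integrity_filter",
    "filter_duplicates",
    "subsample_to_smallest",
]
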