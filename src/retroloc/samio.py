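"""Alignment containers and SAM input/output.

Alignments are represented internally as lightweight records with 0-based
half-open aligned blocks; a :class:`ReadAlignmentGroup` collects every
alignment record sharing one read/fragment name and is the unit of counting
throughout the package. pysam handles the SAM format itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

Blocks = tuple[tuple[int, int], ...]


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One alignment placement of one read (or mate).

    ``blocks`` are the aligned reference segments (0-based half-open), in
    coordinate order; gaps between consecutive blocks are spliced-out
    reference sequence (CIGAR ``N``).
    """

    read_id: str
    chrom: str
    blocks: Blocks
    strand: str  # '+' or '-'
    mate: int = 0  # 0 = single-end, 1/2 = mate of a pair
    is_duplicate: bool = False
    is_secondary: bool = False

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(slots=True)
class ReadAlignmentGroup:
    """All alignment records sharing one read/fragment identity."""

    read_id: str
    records: list[AlignmentRecord] = field(default_factory=list)

    @property
    def n_alignments(self) -> int:
        """Number of distinct placements of the fragment.

        For paired-end fragments this is the maximum placement count over
        mates, so a uniquely placed pair reports 1.
        """
        by_mate: dict[int, int] = {}
        for rec in self.records:
            by_mate[rec.mate] = by_mate.get(rec.mate, 0) + 1
        return max(by_mate.values())

    @property
    def is_unique(self) -> bool:
        return self.n_alignments == 1


def group_records(records: Iterable[AlignmentRecord]) -> list[ReadAlignmentGroup]:
    """Group alignment records by read name, preserving first-seen order."""
    groups: dict[str, ReadAlignmentGroup] = {}
    for rec in records:
        grp = groups.get(rec.read_id)
        if grp is None:
            grp = groups[rec.read_id] = ReadAlignmentGroup(rec.read_id)
        grp.records.append(rec)
    return list(groups.values())


def ungroup(groups: Iterable[ReadAlignmentGroup]) -> Iterator[AlignmentRecord]:
    for grp in groups:
        yield from grp.records


def _blocks_from_cigar(aln: pysam.AlignedSegment) -> Blocks:
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start
    cur_start = pos
    open_block = False
    for op, length in aln.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            if not open_block:
                cur_start = pos
                open_block = True
            pos += length
        elif op == 2:  # D consumes reference but stays within a block
            pos += length
        elif op == 3:  # N closes the current block
            if open_block:
                blocks.append((cur_start, pos))
                open_block = False
            pos += length
        # I, S, H, P consume no reference
    if open_block:
        blocks.append((cur_start, pos))
    return tuple(blocks)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into alignment records (unmapped reads skipped)."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=_blocks_from_cigar(aln),
                    strand="-" if aln.is_reverse else "+",
                    mate=(2 if aln.is_read2 else 1) if aln.is_paired else 0,
                    is_duplicate=aln.is_duplicate,
                    is_secondary=aln.is_secondary,
                )
            )
    return records


def _cigar_from_blocks(blocks: Blocks) -> list[tuple[int, int]]:
    cig: list[tuple[int, int]] = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None:
            cig.append((3, s - prev_end))  # N
        cig.append((0, e - s))  # M
        prev_end = e
    return cig


def write_sam(
    path: str,
    records: Sequence[AlignmentRecord],
    references: dict[str, int],
    nh: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write coordinate-sorted SAM.

    ``nh`` optionally maps read_id to the placement count (emitted as the NH
    tag); ``sequences`` optionally maps read_id to the read sequence (written
    on the primary record only, '*' elsewhere).
    """
    names = list(references)
    tid = {name: i for i, name in enumerate(names)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": references[n]} for n in names],
        }
    )
    ordered = sorted(records, key=lambda r: (tid[r.chrom], r.start, r.read_id))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.start
            a.cigartuples = _cigar_from_blocks(rec.blocks)
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.is_secondary:
                flag |= 256
            if rec.is_duplicate:
                flag |= 1024
            if rec.mate == 1:
                flag |= 1 | 64
            elif rec.mate == 2:
                flag |= 1 | 128
            a.flag = flag
            a.mapping_quality = 0 if (nh or {}).get(rec.read_id, 1) > 1 else 60
            if sequences is not None and not rec.is_secondary:
                seq = sequences.get(rec.read_id)
                if seq is not None:
                    a.query_sequence = seq if rec.strand == "+" else _revcomp(seq)
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if nh is not None and rec.read_id in nh:
                a.set_tag("NH", nh[rec.read_id])
            out.write(a)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def drop_duplicates(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    return [r for r in records if not r.is_duplicate]


__all__ = [
    "AlignmentRecord",
    "ReadAlignmentGroup",
    "group_records",
    "ungroup",
    "read_sam",
    "write_sam",
    "drop_duplicates",
]
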