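"""Repeat and gene annotation handling.

Parses RepeatMasker ``.out`` tables into :class:`RepeatCopy` records, builds
the repeat taxonomy (class > family > element > copy, e.g. SINE > Alu >
AluYb8 > one genomic insertion), selects the conserved full-length copy
subset used for copy-level analyses, and classifies each copy's genic
context (intergenic, or nested in a protein-coding gene in sense/antisense
orientation).

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive conventions of ``.out`` and GTF happens only at file
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

#: Repeat classes RepeatMasker emits (base name before any '?' qualifier).
DEFAULT_KNOWN_CLASSES = frozenset(
    {
        "LINE",
        "SINE",
        "LTR",
        "DNA",
        "Retroposon",
        "RC",
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "scRNA",
        "srpRNA",
        "RNA",
        "Unknown",
        "Other",
        "ARTEFACT",
    }
)

#: Classes treated as retroelements in this analysis.
RETRO_CLASSES = frozenset({"LINE", "SINE", "LTR", "Retroposon"})

GENIC_CONTEXTS = ("intergenic", "genic_sense", "genic_antisense", "ambiguous")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatTaxonomy:
    """The element -> family -> class hierarchy of repeat nomenclature."""

    element_to_family: dict[str, str]
    family_to_class: dict[str, str]
    known_classes: frozenset[str] = DEFAULT_KNOWN_CLASSES

    def family_of(self, element: str) -> str:
        try:
            return self.element_to_family[element]
        except KeyError:
            raise AnnotationError(f"unknown repeat element: {element!r}") from None

    def class_of_family(self, family: str) -> str:
        try:
            return self.family_to_class[family]
        except KeyError:
            raise AnnotationError(f"unknown repeat family: {family!r}") from None

    def class_of(self, element: str) -> str:
        return self.class_of_family(self.family_of(element))

    @classmethod
    def from_copies(cls, copies: Iterable["RepeatCopy"]) -> "RepeatTaxonomy":
        e2f: dict[str, str] = {}
        f2c: dict[str, str] = {}
        for c in copies:
            if e2f.setdefault(c.element, c.family) != c.family:
                raise AnnotationError(
                    f"element {c.element!r} assigned to two families"
                )
            if f2c.setdefault(c.family, c.repclass) != c.repclass:
                raise AnnotationError(
                    f"family {c.family!r} assigned to two classes"
                )
        return cls(e2f, f2c, frozenset(f2c.values()) | DEFAULT_KNOWN_CLASSES)


@dataclass(frozen=True)
class RepeatCopy:
    """One genomic instance of a repeat element."""

    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    element: str
    family: str
    repclass: str
    mismatches: int = 0
    covers_full_consensus: bool = True
    genic_context: str | None = None
    raw_divergence: float | None = None
    raw_deletion: float | None = None
    raw_insertion: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"{self.copy_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.copy_id}: bad strand {self.strand!r}")
        if self.mismatches < 0:
            raise AnnotationError(f"{self.copy_id}: negative mismatch count")
        if self.genic_context is not None and self.genic_context not in GENIC_CONTEXTS:
            raise AnnotationError(
                f"{self.copy_id}: bad genic context {self.genic_context!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A single-copy protein-coding gene as an ordered block of exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.gene_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def derive_introns_and_junctions(
    gene: GeneModel,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Introns (gaps between exons) and splice junction coordinate pairs.

    A junction is the (donor, acceptor) genomic coordinate pair of an
    intron's boundaries; single-exon genes have neither.
    """
    introns = gene.introns()
    return introns, list(introns)


# ---------------------------------------------------------------------------
# RepeatMasker .out parsing


def _parse_int_or_paren(token: str) -> int:
    """Repeat-position tokens: plain integers, parenthesized = bases left."""
    return int(token.strip("()"))


def parse_repeatmasker_out(
    path: str,
    known_classes: frozenset[str] | None = DEFAULT_KNOWN_CLASSES,
    full_length_fraction: float = 0.99,
) -> list[RepeatCopy]:
    """Parse a RepeatMasker ``.out`` annotation table.

    Coordinates are converted from 1-based inclusive to 0-based half-open
    and orientation ``C`` to ``-``.  ``covers_full_consensus`` is true when
    the alignment spans at least ``full_length_fraction`` of the consensus
    length (consensus length = highest aligned consensus position + bases
    left).  The integer mismatch count is derived from the divergence,
    deletion and insertion percentages applied to the aligned consensus
    span; the raw percentages are kept on the record.
    """
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "bit")):  # header lines
                continue
            fields = stripped.split()
            if len(fields) < 14:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed .out record "
                    f"({len(fields)} fields, expected >= 14)"
                )
            try:
                div = float(fields[1])
                dele = float(fields[2])
                ins = float(fields[3])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                orient = fields[8]
                element = fields[9]
                cls_fam = fields[10]
                rep_a = _parse_int_or_paren(fields[11])
                rep_b = _parse_int_or_paren(fields[12])
                rep_c = _parse_int_or_paren(fields[13])
            except (ValueError, IndexError) as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed .out record: {exc}"
                ) from None
            if orient not in ("+", "C"):
                raise AnnotationError(
                    f"{path}:{lineno}: bad orientation {orient!r}"
                )
            strand = "+" if orient == "+" else "-"
            if orient == "+":  # begin, end, (left)
                rep_begin, rep_end, rep_left = rep_a, rep_b, rep_c
            else:  # (left), end, begin
                rep_left, rep_end, rep_begin = rep_a, rep_b, rep_c
            if "/" in cls_fam:
                repclass, family = cls_fam.split("/", 1)
            else:
                repclass = family = cls_fam
            repclass = repclass.rstrip("?")
            if known_classes is not None and repclass not in known_classes:
                raise AnnotationError(
                    f"{path}:{lineno}: unknown repeat class {repclass!r}"
                )
            consensus_len = rep_end + rep_left
            aligned = rep_end - rep_begin + 1
            if aligned <= 0 or consensus_len <= 0:
                raise AnnotationError(
                    f"{path}:{lineno}: inconsistent repeat positions"
                )
            substitutions = round(div * aligned / 100.0)
            indels = round((dele + ins) * aligned / 100.0)
            copies.append(
                RepeatCopy(
                    copy_id=f"{element}|{chrom}:{begin - 1}-{end}({strand})",
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    element=element,
                    family=family,
                    repclass=repclass,
                    mismatches=substitutions + indels,
                    covers_full_consensus=aligned
                    >= full_length_fraction * consensus_len,
                    raw_divergence=div,
                    raw_deletion=dele,
                    raw_insertion=ins,
                )
            )
    return copies


# ---------------------------------------------------------------------------
# GTF / BED output and round-trip input


def _gtf_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_repeat_gtf(copies: Sequence[RepeatCopy], path: str) -> None:
    """Write repeat copies as GTF (1-based inclusive); lossless round-trip."""
    with open(path, "w") as out:
        for c in copies:
            attrs = [
                ("gene_id", c.copy_id),
                ("copy_id", c.copy_id),
                ("element", c.element),
                ("family", c.family),
                ("repeat_class", c.repclass),
                ("mismatches", str(c.mismatches)),
                ("full_length", "1" if c.covers_full_consensus else "0"),
            ]
            if c.genic_context is not None:
                attrs.append(("genic_context", c.genic_context))
            out.write(
                "\t".join(
                    [
                        c.chrom,
                        "retroloc",
                        "repeat_copy",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        ".",
                        _gtf_attrs(attrs),
                    ]
                )
                + "\n"
            )


def _parse_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_repeat_gtf(path: str) -> list[RepeatCopy]:
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: malformed GTF line")
            attrs = _parse_attrs(fields[8])
            copies.append(
                RepeatCopy(
                    copy_id=attrs.get("copy_id", attrs["gene_id"]),
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    element=attrs["element"],
                    family=attrs["family"],
                    repclass=attrs["repeat_class"],
                    mismatches=int(attrs.get("mismatches", 0)),
                    covers_full_consensus=attrs.get("full_length", "1") == "1",
                    genic_context=attrs.get("genic_context"),
                )
            )
    return copies


def write_gene_gtf(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as out:
        for g in genes:
            for i, (s, e) in enumerate(g.exons, start=1):
                attrs = _gtf_attrs(
                    [
                        ("gene_id", g.gene_id),
                        ("transcript_id", f"{g.gene_id}.t1"),
                        ("exon_number", str(i)),
                    ]
                )
                out.write(
                    "\t".join(
                        [
                            g.chrom,
                            "retroloc",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def parse_gene_gtf(path: str) -> list[GeneModel]:
    """Read gene models from GTF exon lines (grouped by gene_id)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: malformed GTF line")
            if fields[2] != "exon":
                continue
            attrs = _parse_attrs(fields[8])
            gid = attrs["gene_id"]
            if gid not in exons:
                exons[gid] = []
                meta[gid] = (fields[0], fields[6])
                order.append(gid)
            exons[gid].append((int(fields[3]) - 1, int(fields[4])))
    genes = []
    for gid in order:
        chrom, strand = meta[gid]
        genes.append(
            GeneModel(gid, chrom, strand, tuple(sorted(exons[gid])))
        )
    return genes


def write_context_bed(copies: Sequence[RepeatCopy], path: str) -> None:
    """BED6 of copy regions; name field carries copy_id and genic context."""
    with open(path, "w") as out:
        for c in copies:
            name = f"{c.copy_id}|{c.genic_context or 'unset'}"
            out.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.mismatches}\t{c.strand}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and classification


def filter_conserved(
    copies: Iterable[RepeatCopy], max_mismatches: int = 10
) -> list[RepeatCopy]:
    """The most highly conserved copy subset: full length relative to the
    consensus and strictly fewer than ``max_mismatches`` mismatches."""
    return [
        c
        for c in copies
        if c.covers_full_consensus and c.mismatches < max_mismatches
    ]


def classify_genic_context(
    copies: Sequence[RepeatCopy], genes: Sequence[GeneModel]
) -> list[RepeatCopy]:
    """Assign each copy's genic context from gene-span overlap.

    Any overlap with a gene span (first exon start to last exon end) makes a
    copy genic; the orientation of every overlapped gene relative to the copy
    decides sense vs antisense, and overlap with genes on both strands is
    ambiguous.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.strand)
    out: list[RepeatCopy] = []
    for c in copies:
        tree = trees.get(c.chrom)
        hits = tree.overlap(c.start, c.end) if tree is not None else ()
        strands = {iv.data for iv in hits}
        if not strands:
            ctx = "intergenic"
        elif strands == {c.strand}:
            ctx = "genic_sense"
        elif c.strand not in strands:
            ctx = "genic_antisense"
        else:
            ctx = "ambiguous"
        out.append(replace(c, genic_context=ctx))
    return out


__all__ = [
    "AnnotationError",
    "RepeatTaxonomy",
    "RepeatCopy",
    "GeneModel",
    "RETRO_CLASSES",
    "DEFAULT_KNOWN_CLASSES",
    "derive_introns_and_junctions",
    "parse_repeatmasker_out",
    "write_repeat_gtf",
    "parse_repeat_gtf",
    "write_gene_gtf",
    "parse_gene_gtf",
    "write_context_bed",
    "filter_conserved",
    "classify_genic_context",
]
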