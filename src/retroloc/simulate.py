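"""Synthetic fraction-seq generator.

Builds a toy genome carrying multi-exon single-copy protein-coding genes
(scPCGs) and repeat copies organized in a class > family > element > copy
hierarchy, then draws paired nuclear/cytoplasmic sequencing libraries from
it with the statistical structure the downstream analysis assumes:

* nuclear gene reads are partially unspliced (pre-mRNA), cytoplasmic reads
  fully spliced by default;
* a configurable subset of each element's copies is byte-identical, so
  reads from those copies are emitted with one alignment record per
  matching copy (multimapping);
* repeat transcripts are nuclear-enriched by a per-element factor ``e``
  while scPCGs keep a nuclear:cytoplasmic ratio of 1;
* copies are placed intergenic or nested in introns in sense/antisense
  orientation;
* optional PhiX-like spike-in reads on a dedicated contig and optional
  5'-degradation of gene reads.

Every read is emitted error-free with truth labels, so counting logic (not
aligner robustness) is what downstream tests exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, RepeatCopy, RepeatTaxonomy
from .samio import AlignmentRecord, ReadAlignmentGroup, write_sam

FRACTIONS = ("nuclear", "cytoplasmic")
_FRACTION_STREAM = {"nuclear": 1, "cytoplasmic": 2}
_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default family layout: (class, family) pairs cycled over when assigning
#: elements.  Mirrors the major retroelement taxa (LINE/SINE/LTR/Retroposon).
DEFAULT_FAMILY_LAYOUT = (
    ("LINE", "L1"),
    ("SINE", "Alu"),
    ("LTR", "ERVK"),
    ("Retroposon", "SVA"),
    ("LINE", "L2"),
    ("SINE", "MIR"),
    ("LTR", "ERVL"),
    ("LTR", "ERV1"),
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults emulate the study conditions.

    ``nuclear_enrichment`` may be a single factor, a sequence cycled over
    elements, or a mapping from element name to factor.  ``degrade_5p`` maps
    fraction name to the target 3'/5' coverage fold (0/absent = no
    degradation).
    """

    seed: int = 0
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (400, 1000)
    n_repeat_elements: int = 54
    copies_per_element: int = 6
    copy_identity: float = 0.5
    consensus_length: tuple[int, int] = (400, 700)
    diverged_mismatches: tuple[int, int] = (2, 30)
    truncated_fraction: float = 0.1
    placement_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    nuclear_enrichment: float | Sequence[float] | Mapping[str, float] = 4.0
    scpcg_ratio: float = 1.0
    splicing_completeness: dict[str, float] = field(
        default_factory=lambda: {"nuclear": 0.5, "cytoplasmic": 1.0}
    )
    read_length: int = 80
    paired: bool = False
    depth: int = 100_000
    spike_in_fraction: float = 0.01
    degrade_5p: dict[str, float] | None = None
    replicates: int = 2
    repeat_read_fraction: float = 0.3
    duplicate_fraction: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.placement_mix) - 1.0) > 1e-9:
            raise SimulationError("placement_mix must sum to 1")
        for name, p in (
            ("copy_identity", self.copy_identity),
            ("spike_in_fraction", self.spike_in_fraction),
            ("truncated_fraction", self.truncated_fraction),
            ("repeat_read_fraction", self.repeat_read_fraction),
            ("duplicate_fraction", self.duplicate_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        for frac, p in self.splicing_completeness.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"splicing_completeness[{frac}] not in [0,1]")
        if self.depth <= 0 or self.read_length <= 0:
            raise SimulationError("depth and read_length must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "exon_length", "intron_length",
                    "consensus_length", "diverged_mismatches", "placement_mix"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def enrichment_for(self, elements: Sequence[str]) -> dict[str, float]:
        e = self.nuclear_enrichment
        if isinstance(e, Mapping):
            return {el: float(e[el]) for el in elements}
        if isinstance(e, (int, float)):
            return {el: float(e) for el in elements}
        vals = list(e)
        return {el: float(vals[i % len(vals)]) for i, el in enumerate(elements)}


@dataclass
class Reference:
    """Toy genome plus everything needed to draw reads from it."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    copies: list[RepeatCopy]
    taxonomy: RepeatTaxonomy
    gene_abundance: dict[str, float]
    gene_unspliced_efficiency: dict[str, float]
    element_abundance: dict[str, float]
    element_enrichment: dict[str, float]
    element_sequences: dict[str, str]  # consensus per element
    copy_sequences: dict[str, str]  # sense transcript sequence per copy
    identical_groups: dict[str, list[str]]  # element -> byte-identical copy ids
    spike_contig: str = "spikein"

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def transcript_sequence(self, gene: GeneModel) -> str:
        seq = "".join(self.genome[gene.chrom][s:e] for s, e in gene.exons)
        return seq if gene.strand == "+" else _revcomp(seq)

    def premrna_sequence(self, gene: GeneModel) -> str:
        seq = self.genome[gene.chrom][gene.start : gene.end]
        return seq if gene.strand == "+" else _revcomp(seq)


@dataclass
class FractionSample:
    """One simulated library: truth alignments, reads and labels."""

    name: str
    fraction: str
    replicate: int
    records: list[AlignmentRecord]
    read_sequences: dict[str, str]
    n_alignments: dict[str, int]
    read_truth: pd.DataFrame  # one row per read
    feature_truth: pd.DataFrame  # one row per gene/element

    def groups(self) -> list[ReadAlignmentGroup]:
        by_id: dict[str, ReadAlignmentGroup] = {}
        for rec in self.records:
            grp = by_id.get(rec.read_id)
            if grp is None:
                grp = by_id[rec.read_id] = ReadAlignmentGroup(rec.read_id)
            grp.records.append(rec)
        return list(by_id.values())


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _stream_rng(seed: int, *key: int) -> np.random.Generator:
    """One RNG stream per (purpose, sample); stable under added replicates."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


# ---------------------------------------------------------------------------
# Reference construction


def _default_taxonomy(n_elements: int) -> tuple[RepeatTaxonomy, list[str]]:
    e2f: dict[str, str] = {}
    f2c: dict[str, str] = {}
    elements: list[str] = []
    counter: dict[str, int] = {}
    for i in range(n_elements):
        cls, fam = DEFAULT_FAMILY_LAYOUT[i % len(DEFAULT_FAMILY_LAYOUT)]
        counter[fam] = counter.get(fam, 0) + 1
        name = f"{fam}-{counter[fam]}"
        elements.append(name)
        e2f[name] = fam
        f2c[fam] = cls
    tax = RepeatTaxonomy(e2f, f2c, frozenset(f2c.values()))
    return tax, elements


def generate_reference(config: SimulationConfig) -> Reference:
    """Deterministically build the toy genome and annotations."""
    rng = _stream_rng(config.seed, 0)
    tax, elements = _default_taxonomy(config.n_repeat_elements)

    # Element consensus sequences and per-copy variants.
    consensus: dict[str, str] = {}
    copy_seqs: dict[str, list[tuple[str, int, bool]]] = {}  # (seq, mism, full)
    identical_counts: dict[str, int] = {}
    for el in elements:
        clen = int(rng.integers(config.consensus_length[0], config.consensus_length[1] + 1))
        cons = _random_seq(rng, clen)
        consensus[el] = cons
        n_copies = config.copies_per_element
        n_identical = math.ceil(config.copy_identity * n_copies)
        identical_counts[el] = n_identical
        variants: list[tuple[str, int, bool]] = []
        for j in range(n_copies):
            if j < n_identical:
                variants.append((cons, 0, True))
                continue
            m = int(rng.integers(config.diverged_mismatches[0],
                                 config.diverged_mismatches[1] + 1))
            arr = np.frombuffer(cons.encode(), dtype="S1").copy()
            pos = rng.choice(clen, size=min(m, clen), replace=False)
            for p in pos:
                cur = arr[p]
                choices = _BASES[_BASES != cur]
                arr[p] = rng.choice(choices)
            seq = arr.tobytes().decode()
            truncated = rng.random() < config.truncated_fraction
            if truncated:
                seq = seq[: max(config.read_length + 20, int(0.6 * clen))]
            variants.append((seq, m, not truncated))
        copy_seqs[el] = variants

    # Placement categories per copy (largest-remainder rounding, shuffled).
    total_copies = config.n_repeat_elements * config.copies_per_element
    cat_counts = _largest_remainder(config.placement_mix, total_copies)
    categories = (
        ["intergenic"] * cat_counts[0]
        + ["genic_sense"] * cat_counts[1]
        + ["genic_antisense"] * cat_counts[2]
    )
    rng.shuffle(categories)

    # Gene skeletons: exon/intron lengths, strands, intron slots for nesting.
    gene_plans = []
    slots: list[tuple[int, int]] = []  # (gene index, intron index)
    for gi in range(config.n_genes):
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=k)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                                   size=max(k - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_plans.append(
            {"exon_lens": exon_lens.tolist(), "intron_lens": intron_lens.tolist(),
             "strand": strand, "nested": {}}
        )
        slots.extend((gi, ii) for ii in range(k - 1))

    # Assign genic copies to intron slots.
    copy_index = 0
    genic_needed = cat_counts[1] + cat_counts[2]
    if genic_needed > len(slots):
        raise SimulationError(
            f"genome too small: {genic_needed} nested copies requested but only "
            f"{len(slots)} intron slots exist; increase n_genes or exons_per_gene"
        )
    slot_order = list(range(len(slots)))
    rng.shuffle(slot_order)
    slot_iter = iter(slot_order)

    copy_plan: list[dict] = []  # per copy: element, variant idx, category, slot
    ci = 0
    for el in elements:
        for j in range(config.copies_per_element):
            cat = categories[ci]
            plan = {"element": el, "variant": j, "category": cat, "slot": None}
            if cat != "intergenic":
                si = slots[next(slot_iter)]
                plan["slot"] = si
                gene_plans[si[0]]["nested"].setdefault(si[1], []).append(plan)
            copy_plan.append(plan)
            ci += 1

    # Lay out chr1: shuffled sequence of genes and intergenic copies with gaps.
    items: list[tuple[str, object]] = [("gene", gi) for gi in range(config.n_genes)]
    items += [("copy", p) for p in copy_plan if p["category"] == "intergenic"]
    order = list(range(len(items)))
    rng.shuffle(order)

    chunks: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    copies: list[RepeatCopy] = []
    copy_sequences: dict[str, str] = {}
    identical_groups: dict[str, list[str]] = {el: [] for el in elements}

    def _emit_copy(plan: dict, strand: str, start: int) -> RepeatCopy:
        el = plan["element"]
        seq, mism, full = copy_seqs[el][plan["variant"]]
        cid = f"{el}.c{plan['variant']}"
        genome_seq = seq if strand == "+" else _revcomp(seq)
        chunks.append(genome_seq)
        copy = RepeatCopy(
            copy_id=cid,
            chrom="chr1",
            start=start,
            end=start + len(seq),
            strand=strand,
            element=el,
            family=tax.family_of(el),
            repclass=tax.class_of(el),
            mismatches=mism,
            covers_full_consensus=full,
        )
        copy_sequences[cid] = seq
        if plan["variant"] < identical_counts[el] and full:
            identical_groups[el].append(cid)
        return copy

    for idx in order:
        kind, payload = items[idx]
        gap = int(rng.integers(300, 801))
        chunks.append(_random_seq(rng, gap))
        pos += gap
        if kind == "copy":
            copy = _emit_copy(payload, "+" if rng.random() < 0.5 else "-", pos)
            copies.append(copy)
            pos = copy.end
            continue
        gi = payload
        plan = gene_plans[gi]
        strand = plan["strand"]
        exon_bounds: list[tuple[int, int]] = []
        for ei, elen in enumerate(plan["exon_lens"]):
            exon_seq = _random_seq(rng, int(elen))
            chunks.append(exon_seq)
            exon_bounds.append((pos, pos + int(elen)))
            pos += int(elen)
            if ei < len(plan["exon_lens"]) - 1:
                nested = plan["nested"].get(ei, [])
                ilen = int(plan["intron_lens"][ei])
                pad = max(150, ilen // 2)
                chunks.append(_random_seq(rng, pad))
                pos += pad
                for cplan in nested:
                    cstrand = strand if cplan["category"] == "genic_sense" else (
                        "-" if strand == "+" else "+"
                    )
                    copy = _emit_copy(cplan, cstrand, pos)
                    copies.append(copy)
                    pos = copy.end
                    chunks.append(_random_seq(rng, 150))
                    pos += 150
                tail = max(150, ilen - pad)
                chunks.append(_random_seq(rng, tail))
                pos += tail
        genes.append(GeneModel(f"gene{gi:04d}", "chr1", strand, tuple(exon_bounds)))

    genome = {"chr1": "".join(chunks), "spikein": _random_seq(rng, 3000)}

    # True abundances (fixed per simulation, shared by all samples).
    gene_ab = rng.lognormal(mean=0.0, sigma=0.6, size=config.n_genes)
    elem_ab = rng.lognormal(mean=0.0, sigma=0.6, size=config.n_repeat_elements)
    f = config.repeat_read_fraction
    if 0 < f < 1:
        elem_ab *= (f / (1 - f)) * gene_ab.sum() / elem_ab.sum()
    gene_abundance = {g.gene_id: float(a) for g, a in zip(genes, gene_ab)}
    element_abundance = {el: float(a) for el, a in zip(elements, elem_ab)}
    unspliced_eff = {
        g.gene_id: _unspliced_assignment_efficiency(g, config.read_length)
        for g in genes
    }

    return Reference(
        config=config,
        genome=genome,
        genes=genes,
        copies=copies,
        taxonomy=tax,
        gene_abundance=gene_abundance,
        gene_unspliced_efficiency=unspliced_eff,
        element_abundance=element_abundance,
        element_enrichment=config.enrichment_for(elements),
        element_sequences=consensus,
        copy_sequences=copy_sequences,
        identical_groups=identical_groups,
    )


def _unspliced_assignment_efficiency(gene: GeneModel, read_length: int) -> float:
    """Fraction of uniform pre-mRNA read positions assignable to the gene.

    A read is gene-assignable when at least half its bases are exonic, the
    rule expression counting applies.  Used to calibrate per-gene read
    yield so that the configured compartment ratio is the ratio of
    exon-assignable gene signal — the quantity scPCG-based normalization
    treats as gene expression.
    """
    span = gene.end - gene.start
    if span <= read_length:
        return 1.0
    exonic = np.zeros(span, dtype=float)
    for s, e in gene.exons:
        exonic[s - gene.start : e - gene.start] = 1.0
    window = np.convolve(exonic, np.ones(read_length), mode="valid")
    return float(np.mean(window >= read_length / 2.0))


# ---------------------------------------------------------------------------
# Read sampling


def _transcript_to_blocks(
    gene: GeneModel, t5: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map a transcript interval (offset from the 5' end) to genomic blocks."""
    tlen = gene.transcript_length
    tg = t5 if gene.strand == "+" else tlen - t5 - length
    blocks: list[tuple[int, int]] = []
    offset = 0
    lo, hi = tg, tg + length
    for s, e in gene.exons:
        elen = e - s
        a, b = max(lo, offset), min(hi, offset + elen)
        if a < b:
            blocks.append((s + a - offset, s + b - offset))
        offset += elen
    return tuple(blocks)


def simulate_fraction(
    reference: Reference, fraction: str, replicate: int
) -> FractionSample:
    """Draw one library for one fraction/replicate from the reference.

    Deterministic given the master seed; each (fraction, replicate) pair has
    its own RNG stream, so adding replicates never perturbs earlier samples.
    """
    if fraction not in FRACTIONS:
        raise SimulationError(f"unknown fraction {fraction!r}")
    config = reference.config
    rng = _stream_rng(config.seed, _FRACTION_STREAM[fraction], replicate)
    name = f"{'nuc' if fraction == 'nuclear' else 'cyt'}{replicate}"
    R = config.read_length
    nuclear = fraction == "nuclear"

    genes = reference.genes
    elements = list(reference.element_abundance)
    completeness = config.splicing_completeness.get(fraction, 1.0)
    # Per-gene yield is inflated by the inverse exon-assignment efficiency of
    # this fraction's spliced/unspliced read mixture, so the configured
    # compartment ratio is carried by the exon-assignable signal.
    eff = np.array(
        [
            completeness
            + (1 - completeness) * reference.gene_unspliced_efficiency[g.gene_id]
            for g in genes
        ]
    )
    gene_w = np.array(
        [reference.gene_abundance[g.gene_id] for g in genes], dtype=float
    ) / np.maximum(eff, 1e-9)
    elem_w = np.array([reference.element_abundance[el] for el in elements], dtype=float)
    if nuclear:
        gene_w = gene_w * config.scpcg_ratio
        elem_w = elem_w * np.array(
            [reference.element_enrichment[el] for el in elements]
        )
    weights = np.concatenate([gene_w, elem_w])
    probs = weights / weights.sum()

    n_spike = int(rng.binomial(config.depth, config.spike_in_fraction))
    n_main = config.depth - n_spike
    counts = rng.multinomial(n_main, probs)

    copies_by_element: dict[str, list[RepeatCopy]] = {}
    for c in reference.copies:
        copies_by_element.setdefault(c.element, []).append(c)
    identical = {
        el: {cid for cid in ids} for el, ids in reference.identical_groups.items()
    }

    records: list[AlignmentRecord] = []
    read_seqs: dict[str, str] = {}
    n_aln: dict[str, int] = {}
    truth_rows: list[tuple] = []
    serial = 0

    transcripts = {g.gene_id: reference.transcript_sequence(g) for g in genes}
    premrnas = {g.gene_id: reference.premrna_sequence(g) for g in genes}

    # Gene reads.
    for gi, gene in enumerate(genes):
        n = int(counts[gi])
        if n == 0:
            continue
        tlen = gene.transcript_length
        plen = gene.end - gene.start
        spliced_flags = rng.random(n) < completeness
        t_spliced = rng.integers(0, max(tlen - R, 0) + 1, size=n)
        t_pre = rng.integers(0, max(plen - R, 0) + 1, size=n)
        for i in range(n):
            rid = f"{name}:{serial:07d}"
            serial += 1
            if spliced_flags[i]:
                t5 = int(t_spliced[i])
                blocks = _transcript_to_blocks(gene, t5, R)
                seq = transcripts[gene.gene_id][t5 : t5 + R]
                spliced = True
            else:
                t5 = int(t_pre[i])
                if gene.strand == "+":
                    gstart = gene.start + t5
                else:
                    gstart = gene.end - t5 - R
                blocks = ((gstart, gstart + R),)
                seq = premrnas[gene.gene_id][t5 : t5 + R]
                spliced = False
            records.append(
                AlignmentRecord(rid, gene.chrom, blocks, gene.strand)
            )
            read_seqs[rid] = seq
            n_aln[rid] = 1
            truth_rows.append((rid, "gene", gene.gene_id, "", spliced, 1))

    # Repeat reads.
    for ei, el in enumerate(elements):
        n = int(counts[config.n_genes + ei])
        if n == 0:
            continue
        el_copies = copies_by_element.get(el, [])
        if not el_copies:
            continue
        src_idx = rng.integers(0, len(el_copies), size=n)
        u = rng.random(n)
        for i in range(n):
            src = el_copies[int(src_idx[i])]
            L = src.length
            if L <= R:
                t = 0
            else:
                t = int(u[i] * (L - R + 1))
            rid = f"{name}:{serial:07d}"
            serial += 1
            seq = reference.copy_sequences[src.copy_id][t : t + R]
            placements: list[RepeatCopy] = [src]
            if src.copy_id in identical.get(el, ()):  # multimaps to siblings
                placements = [
                    c for c in el_copies if c.copy_id in identical[el]
                ]
                # keep the source first so it carries the primary flag
                placements.sort(key=lambda c: c.copy_id != src.copy_id)
            for k, copy in enumerate(placements):
                if copy.strand == "+":
                    blocks = ((copy.start + t, copy.start + t + R),)
                else:
                    blocks = ((copy.end - t - R, copy.end - t),)
                records.append(
                    AlignmentRecord(
                        rid,
                        copy.chrom,
                        blocks,
                        copy.strand,
                        is_secondary=k > 0,
                    )
                )
            read_seqs[rid] = seq
            n_aln[rid] = len(placements)
            truth_rows.append((rid, "repeat", el, src.copy_id, False, len(placements)))

    # Spike-in reads.
    spike_len = len(reference.genome[reference.spike_contig])
    if n_spike:
        starts = rng.integers(0, spike_len - R + 1, size=n_spike)
        strands = rng.random(n_spike) < 0.5
        for i in range(n_spike):
            rid = f"{name}:{serial:07d}"
            serial += 1
            s = int(starts[i])
            strand = "+" if strands[i] else "-"
            records.append(
                AlignmentRecord(rid, reference.spike_contig, ((s, s + R),), strand)
            )
            seq = reference.genome[reference.spike_contig][s : s + R]
            read_seqs[rid] = seq if strand == "+" else _revcomp(seq)
            n_aln[rid] = 1
            truth_rows.append((rid, "spike", reference.spike_contig, "", False, 1))

    # Optional PCR-duplicate flagging (whole fragments).
    if config.duplicate_fraction > 0:
        all_ids = sorted(n_aln)
        flag = set(
            rng.choice(
                all_ids,
                size=int(config.duplicate_fraction * len(all_ids)),
                replace=False,
            )
        )
        records = [
            replace(r, is_duplicate=True) if r.read_id in flag else r
            for r in records
        ]

    sample = FractionSample(
        name=name,
        fraction=fraction,
        replicate=replicate,
        records=records,
        read_sequences=read_seqs,
        n_alignments=n_aln,
        read_truth=pd.DataFrame(
            truth_rows,
            columns=["read_id", "category", "feature", "copy_id", "spliced",
                     "n_alignments"],
        ),
        feature_truth=_feature_truth(reference, fraction),
    )
    fold = (reference.config.degrade_5p or {}).get(fraction, 0.0)
    if fold:
        sample = apply_5p_degradation(sample, reference.genes, fold,
                                      seed=config.seed + 7)
    return sample


def _feature_truth(reference: Reference, fraction: str) -> pd.DataFrame:
    rows = []
    spliced = reference.config.splicing_completeness.get(fraction, 1.0)
    for g in reference.genes:
        rows.append(
            (g.gene_id, "gene", reference.gene_abundance[g.gene_id],
             reference.config.scpcg_ratio, spliced)
        )
    for el, ab in reference.element_abundance.items():
        rows.append((el, "repeat", ab, reference.element_enrichment[el], 0.0))
    return pd.DataFrame(
        rows,
        columns=["feature", "category", "abundance", "nuc_cyt_ratio",
                 "spliced_fraction"],
    )


def simulate_all(reference: Reference) -> list[FractionSample]:
    """All fractions x replicates, in a stable sample order."""
    samples = []
    for fraction in FRACTIONS:
        for rep in range(1, reference.config.replicates + 1):
            samples.append(simulate_fraction(reference, fraction, rep))
    return samples


# ---------------------------------------------------------------------------
# 5' degradation


def apply_5p_degradation(
    sample: FractionSample,
    genes: Sequence[GeneModel],
    skew: float,
    seed: int = 0,
) -> FractionSample:
    """Thin gene reads so 3' transcript positions are over-represented.

    ``skew`` is the target fold of coverage at normalized transcript
    position 85 over position 15; 0 (or 1) leaves the sample untouched.
    Acceptance probability is linear in the read's normalized transcript
    position.  Non-gene reads pass through unchanged.
    """
    if skew < 0:
        raise SimulationError("skew must be >= 0")
    if skew in (0.0, 1.0):
        return sample
    import zlib

    s = (skew - 1.0) / (0.35 * (skew + 1.0))
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [seed & 0x7FFFFFFF, 99, zlib.crc32(sample.name.encode()) & 0xFFFF]
        )
    )

    by_gene = {g.gene_id: g for g in genes}
    # per-gene cumulative exonic length for transcript-position lookup
    cum: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for g in genes:
        starts = np.array([e[0] for e in g.exons])
        lens = np.array([e[1] - e[0] for e in g.exons])
        cum[g.gene_id] = (starts, np.concatenate([[0], np.cumsum(lens)]), g.transcript_length)

    truth = sample.read_truth.set_index("read_id")
    norm = 1.0 + 0.5 * s
    # Decide per gene read using its first record's midpoint.
    first_rec: dict[str, AlignmentRecord] = {}
    for rec in sample.records:
        first_rec.setdefault(rec.read_id, rec)
    kept_ids: set[str] = set()
    for rid, row in truth.iterrows():
        if row["category"] != "gene":
            kept_ids.add(rid)
            continue
        gene = by_gene[row["feature"]]
        rec = first_rec[rid]
        mid = (rec.start + rec.end) // 2
        starts, cumlen, tlen = cum[gene.gene_id]
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        i = max(i, 0)
        exon_s, exon_e = gene.exons[i]
        within = min(max(mid - exon_s, 0), exon_e - exon_s)
        tpos = cumlen[i] + within
        x = tpos / tlen if tlen else 0.5
        if gene.strand == "-":
            x = 1.0 - x
        accept = (1.0 + s * (x - 0.5)) / norm
        if rng.random() < accept:
            kept_ids.add(rid)

    records = [r for r in sample.records if r.read_id in kept_ids]
    return FractionSample(
        name=sample.name,
        fraction=sample.fraction,
        replicate=sample.replicate,
        records=records,
        read_sequences={k: v for k, v in sample.read_sequences.items() if k in kept_ids},
        n_alignments={k: v for k, v in sample.n_alignments.items() if k in kept_ids},
        read_truth=sample.read_truth[sample.read_truth["read_id"].isin(kept_ids)]
        .reset_index(drop=True),
        feature_truth=sample.feature_truth,
    )


# ---------------------------------------------------------------------------
# File output


def write_reference(reference: Reference, out_dir: str) -> None:
    import os

    from .annotation import write_gene_gtf, write_repeat_gtf

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "genome.fa"), "w") as fa:
        for name, seq in reference.genome.items():
            fa.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")
    write_gene_gtf(reference.genes, os.path.join(out_dir, "genes.gtf"))
    write_repeat_gtf(reference.copies, os.path.join(out_dir, "repeats.gtf"))


def write_sample(sample: FractionSample, reference: Reference, out_dir: str) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_sam(
        os.path.join(out_dir, f"{sample.name}.sam"),
        sample.records,
        reference.reference_lengths,
        nh=sample.n_alignments,
        sequences=sample.read_sequences,
    )
    with open(os.path.join(out_dir, f"{sample.name}.fastq"), "w") as fq:
        for rid in sorted(sample.read_sequences):
            seq = sample.read_sequences[rid]
            fq.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    sample.read_truth.to_csv(
        os.path.join(out_dir, f"{sample.name}.truth.tsv"), sep="\t", index=False
    )


__all__ = [
    "SimulationConfig",
    "SimulationError",
    "Reference",
    "FractionSample",
    "FRACTIONS",
    "generate_reference",
    "simulate_fraction",
    "simulate_all",
    "apply_5p_degradation",
    "write_reference",
    "write_sample",
]
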