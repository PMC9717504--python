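"""Containment counting and once-per-level multimapper collapsing tests."""

from __future__ import annotations

import random

import pytest

from retroloc.annotation import GeneModel, RepeatCopy, RepeatTaxonomy
from retroloc.counting import (
    CopyIndex,
    assign_fragment_to_copies,
    count_all_levels,
    count_genes,
    count_repeats,
    _three_prime_window,
)

from conftest import make_fragment

TAX = RepeatTaxonomy(
    {"L1HS": "L1", "L1PA2": "L1", "AluYb8": "Alu", "AluSx": "Alu"},
    {"L1": "LINE", "Alu": "SINE"},
)


def _copy(cid, element, start, end, strand="+", chrom="chr1"):
    family = TAX.family_of(element)
    return RepeatCopy(cid, chrom, start, end, strand, element, family,
                      TAX.class_of(element))


COPIES = [
    _copy("l1hs.a", "L1HS", 1000, 2000),
    _copy("l1hs.b", "L1HS", 3000, 4000),
    _copy("l1hs.c", "L1HS", 5000, 6000, strand="-"),
    _copy("alu.y", "AluYb8", 7000, 7300),
    _copy("alu.s", "AluSx", 8000, 8300),
    _copy("l1pa.a", "L1PA2", 9000, 9900),
]
INDEX = CopyIndex(COPIES)


def test_containment_rule():
    inside = make_fragment("a", [("chr1", ((1100, 1180),), "+")])
    assert assign_fragment_to_copies(inside, INDEX) == {"l1hs.a"}
    overhang = make_fragment("b", [("chr1", ((1950, 2030),), "+")])
    assert assign_fragment_to_copies(overhang, INDEX) == set()
    triple = make_fragment(
        "c",
        [("chr1", ((1100, 1180),), "+"), ("chr1", ((3100, 3180),), "+"),
         ("chr1", ((5100, 5180),), "-")],
    )
    assert assign_fragment_to_copies(triple, INDEX) == {
        "l1hs.a", "l1hs.b", "l1hs.c"
    }


def test_strand_modes():
    frag = make_fragment("a", [("chr1", ((5100, 5180),), "+")])  # '-' copy
    assert assign_fragment_to_copies(frag, INDEX, "unstranded") == {"l1hs.c"}
    assert assign_fragment_to_copies(frag, INDEX, "same") == set()
    assert assign_fragment_to_copies(frag, INDEX, "opposite") == {"l1hs.c"}


def _count(frags, level):
    return count_repeats(frags, INDEX, TAX, level).counts["sample"]


def test_once_per_level_collapsing():
    # one fragment hitting three L1HS copies: once at each level
    frag = make_fragment(
        "m",
        [("chr1", ((1100, 1180),), "+"), ("chr1", ((3100, 3180),), "+"),
         ("chr1", ((5100, 5180),), "-")],
    )
    assert _count([frag], "element")["L1HS"] == 1
    assert _count([frag], "family")["L1"] == 1
    assert _count([frag], "class")["LINE"] == 1

    # AluYb8 + AluSx: no element credit, one family/class credit
    alu = make_fragment(
        "n", [("chr1", ((7100, 7180),), "+"), ("chr1", ((8100, 8180),), "+")]
    )
    assert _count([alu], "element").sum() == 0
    assert _count([alu], "family")["Alu"] == 1
    assert _count([alu], "class")["SINE"] == 1

    # Alu + L1: different classes, nothing anywhere
    cross = make_fragment(
        "x", [("chr1", ((7100, 7180),), "+"), ("chr1", ((1100, 1180),), "+")]
    )
    for level in ("element", "family", "class"):
        assert _count([cross], level).sum() == 0


def test_records_outside_copies_contribute_nothing():
    frag = make_fragment(
        "p", [("chr1", ((1100, 1180),), "+"), ("chr1", ((50_000, 50_080),), "+")]
    )
    assert assign_fragment_to_copies(frag, INDEX) == {"l1hs.a"}
    assert _count([frag], "element")["L1HS"] == 1


def test_permutation_invariance():
    rnd = random.Random(0)
    frags = []
    for i in range(200):
        s = rnd.randrange(500, 9900)
        frags.append(make_fragment(f"r{i}", [("chr1", ((s, s + 60),), "+")]))
    a = count_repeats(frags, INDEX, TAX, "family").counts
    shuffled = frags[:]
    rnd.shuffle(shuffled)
    b = count_repeats(shuffled, INDEX, TAX, "family").counts
    assert a.equals(b)


def brute_force_repeat_counts(frags, copies, taxonomy, level, strand_mode):
    """Exhaustive all-pairs implementation of the counting rules."""
    label = {
        "element": lambda c: c.element,
        "family": lambda c: taxonomy.family_of(c.element),
        "class": lambda c: taxonomy.class_of(c.element),
    }[level]
    counts: dict[str, int] = {}
    for frag in frags:
        hit = []
        for rec in frag.records:
            for c in copies:
                if rec.chrom != c.chrom:
                    continue
                if not all(c.start <= s and e <= c.end for s, e in rec.blocks):
                    continue
                if strand_mode == "same" and rec.strand != c.strand:
                    continue
                if strand_mode == "opposite" and rec.strand == c.strand:
                    continue
                hit.append(c)
        names = {label(c) for c in hit}
        if len(names) == 1:
            name = names.pop()
            counts[name] = counts.get(name, 0) + 1
    return counts


def random_instance(rnd, n_frags=120, n_copies=40):
    elements = list(TAX.element_to_family)
    copies = []
    for i in range(n_copies):
        s = rnd.randrange(0, 20_000)
        copies.append(
            _copy(f"c{i}", rnd.choice(elements), s, s + rnd.randrange(80, 600),
                  strand=rnd.choice("+-"))
        )
    frags = []
    for i in range(n_frags):
        n_rec = rnd.choice([1, 1, 1, 2, 3])
        placements = []
        for _ in range(n_rec):
            s = rnd.randrange(0, 20_500)
            if rnd.random() < 0.3:  # spliced-style two-block record
                blocks = ((s, s + 30), (s + 60, s + 90))
            else:
                blocks = ((s, s + rnd.randrange(30, 90)),)
            placements.append(("chr1", blocks, rnd.choice("+-")))
        frags.append(make_fragment(f"f{i}", placements))
    return frags, copies


@pytest.mark.parametrize("strand_mode", ["unstranded", "same", "opposite"])
def test_counting_matches_brute_force(strand_mode):
    rnd = random.Random(17)
    for _ in range(10):
        frags, copies = random_instance(rnd)
        index = CopyIndex(copies)
        for level in ("element", "family", "class"):
            table = count_repeats(frags, index, TAX, level, strand_mode)
            expected = brute_force_repeat_counts(
                frags, copies, TAX, level, strand_mode
            )
            observed = {k: int(v) for k, v in table.counts["sample"].items() if v}
            assert observed == expected


GENES = [
    GeneModel("gplus", "chr1", "+", ((0, 400), (600, 900))),
    GeneModel("gother", "chr2", "+", ((0, 300),)),
]


def test_three_prime_window_projection():
    assert _three_prime_window(GENES[0], 500) == [(200, 400), (600, 900)]
    minus = GeneModel("gm", "chr1", "-", ((0, 400), (600, 900)))
    assert _three_prime_window(minus, 500) == [(0, 400), (600, 700)]


def test_gene_counting_unique_and_windows():
    exonic = make_fragment("u", [("chr1", ((100, 180),), "+")])
    table = count_genes([exonic], GENES)
    assert table.counts["sample"]["gplus"] == 1

    multi = make_fragment(
        "m", [("chr1", ((100, 180),), "+"), ("chr2", ((10, 90),), "+")]
    )
    assert count_genes([multi], GENES).counts["sample"].sum() == 0

    # 3' window mode: transcript bases 200..700 -> [(200,400),(600,900))
    early = make_fragment("e", [("chr1", ((100, 150),), "+")])
    late = make_fragment("l", [("chr1", ((650, 700),), "+")])
    win_counts = count_genes([early, late], GENES, mode="last500bp").counts["sample"]
    assert win_counts["gplus"] == 1  # only the late read


def test_mostly_intronic_fragment_is_not_gene_assigned():
    # 80-base read with 30 exonic bases (< 50%)
    frag = make_fragment("i", [("chr1", ((370, 450),), "+")])
    assert count_genes([frag], GENES).counts["sample"].sum() == 0


def test_count_all_levels_equals_independent_runs(small_reference, small_groups):
    groups = small_groups["nuc1"]
    copies = small_reference.copies
    tax = small_reference.taxonomy
    genes = small_reference.genes
    combined = count_all_levels(groups, copies, tax, genes)
    for level in ("element", "family", "class"):
        solo = count_repeats(groups, copies, tax, level)
        assert combined[level].counts.equals(solo.counts)
    solo_genes = count_genes(groups, genes)
    assert combined["gene"].counts.equals(solo_genes.counts)


def test_hierarchy_monotonicity_on_simulated_data(small_reference, small_groups):
    tax = small_reference.taxonomy
    for groups in small_groups.values():
        tables = count_all_levels(groups, small_reference.copies, tax,
                                  small_reference.genes)
        elem = tables["element"].counts["sample"]
        fam = tables["family"].counts["sample"]
        cls = tables["class"].counts["sample"]
        for family in fam.index:
            members = [e for e in elem.index if tax.family_of(e) == family]
            assert fam[family] >= elem[members].sum()
        for klass in cls.index:
            members = [f for f in fam.index
                       if tax.class_of_family(f) == klass]
            assert cls[klass] >= fam[members].sum()


def test_unstranded_dominates_same_strand(small_reference, small_groups):
    groups = small_groups["nuc1"]
    un = count_repeats(groups, small_reference.copies,
                       small_reference.taxonomy, "element", "unstranded")
    same = count_repeats(groups, small_reference.copies,
                         small_reference.taxonomy, "element", "same")
    assert (un.counts["sample"] >= same.counts["sample"]).all()


def test_cytoplasmic_element_counts_equal_truth(small_reference, small_samples):
    """With fully spliced cytoplasmic reads there is no pre-mRNA passenger
    signal, so element counts equal the truth read counts exactly."""
    cyt = [s for s in small_samples if s.fraction == "cytoplasmic"][0]
    table = count_repeats(cyt.groups(), small_reference.copies,
                          small_reference.taxonomy, "element")
    truth = cyt.read_truth
    for el in small_reference.element_abundance:
        expected = int((truth["feature"] == el).sum())
        assert int(table.counts["sample"][el]) == expected
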