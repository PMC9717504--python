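# retroloc

Nuclear/cytoplasmic localization analysis of retroelement transcripts from
fractionation RNA-seq.

## The problem

Retroelements (LINE, SINE, LTR and Retroposon class repeats) populate
vertebrate genomes in thousands of near-identical copies, so RNA-seq reads
from their transcripts map ambiguously and standard gene-level pipelines
discard them. `retroloc` implements a repeat-aware analysis of paired
nuclear/cytoplasmic RNA-seq fractions that asks where repeat-derived
transcripts reside in the cell:

* **Hierarchical counting.** Reads are counted against repeat copies only
  when they map *entirely within* a copy. A multimapping fragment whose
  placements all fall in copies of one element type (e.g. L1-Hs) adds 1 at
  the element level; a fragment spanning several element types of one
  family (e.g. AluYb8 + AluSx) still adds 1 to the family (Alu) and class
  (SINE) but nothing at the element level — each fragment counts at most
  once per taxonomy level.
* **Fractionation & integrity QC.** Per-gene splicing index
  SI = (reads indicating splicing) / (informative reads) — near 1 in clean
  cytoplasm, below 1 in nuclei — and a 5′/3′ gene-body coverage ratio over
  the 500 most expressed genes (normalized position 15 vs 85); samples with
  a > 2.5-fold disparity are flagged degraded and excluded.
* **Localization statistics.** Counts are normalized with median-of-ratios
  size factors derived from single-copy protein-coding genes (scPCGs), or
  from spike-in reads. For each feature, log2(Nuc/Cyt) > 0 is called
  nuclear. Retroelement-vs-scPCG shifts are tested with a one-tailed
  Mann–Whitney U test (exact by enumeration for small samples); per-feature
  calls use a conditional negative-binomial exact test with
  Benjamini–Hochberg FDR control (nuclear if log2FC > 0 at FDR < 0.05).
* **Metagene profiles.** Strand-aware scale-regions matrices (±1 kb flanks
  at 10 bp/bin, 100 body bins → 300 columns) over conserved full-length
  copies (< 10 mismatches vs consensus), grouped by genic context
  (intergenic / genic sense / genic antisense), in unique-only and
  all-mappable read modes.

A built-in synthetic fraction-seq generator produces a toy genome, gene and
repeat annotations and truth-labelled nuclear/cytoplasmic libraries with
configurable repeat nuclear enrichment, partial nuclear splicing,
byte-identical copies (multimapping), spike-ins and 5′ degradation, so the
whole pipeline is testable end to end without any downloads.

## Worked example

```python
from retroloc import RunConfig, run, SimulationConfig

config = RunConfig(
    out_dir="retroloc_demo",
    simulation=SimulationConfig(seed=7, depth=50_000, replicates=2),
    seed=7,
)
result = run(config)

elem = result.ratio_tables["element"]
gene = result.ratio_tables["gene"]
print(f"retroelement types analysed : {len(elem)}")
print(f"scPCGs analysed             : {len(gene)}")
print(f"median retro log2(Nuc/Cyt)  : {elem['log2_ratio'].median():.3f}")
print(f"median scPCG log2(Nuc/Cyt)  : {gene['log2_ratio'].median():.3f}")
print(f"one-tailed MWU p            : {result.mwu['p']:.3g}")
print(f"NB exact-test calls         : "
      f"{result.dge['element']['call'].value_counts().to_dict()}")
```

prints

```
retroelement types analysed : 54
scPCGs analysed             : 60
median retro log2(Nuc/Cyt)  : 2.155
median scPCG log2(Nuc/Cyt)  : -0.000
one-tailed MWU p            : 1.95e-20
NB exact-test calls         : {'nuclear': 54}
```

The simulated libraries carry a 4-fold nuclear enrichment of repeat
transcripts (default), and the pipeline recovers it: the median repeat
log2(Nuc/Cyt) sits near log2(4) = 2 (slightly above — see
`docs/methods.md` on intron-nested passenger reads), scPCG ratios center
on 0, every element is called nuclear at FDR < 0.05, and the
retro-vs-scPCG Mann–Whitney shift is overwhelming. `retroloc_demo/`
contains the QC tables, count matrices (gene/element/family/class),
enrichment tables, class percentages and metagene matrices.

The same analysis runs from the shell:

```bash
retroloc simulate --out-dir sim            # FASTA/GTF/SAM/FASTQ + truth
retroloc qc --sam sim/samples/nuc1.sam --genes sim/genes.gtf --out-prefix nuc1
retroloc count --sam sim/samples/nuc1.sam --repeats sim/repeats.gtf \
    --genes sim/genes.gtf --sample nuc1 --out-dir counts
retroloc run --config run.yaml             # full pipeline from YAML
```

and `retroloc annotate` converts RepeatMasker `.out` tables to GTF/BED with
conservation filtering and genic-context classification.

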