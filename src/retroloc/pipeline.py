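"""End-to-end orchestration: simulate/load -> QC -> count -> normalize ->
enrichment statistics -> metagene matrices.

One configuration object drives the whole analysis; every threshold used in
the study is a named key with its published value as default.  Samples
failing the RNA-integrity filter are excluded from all downstream stages
and listed in the QC report.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation, counting, enrichment, metagene, qc
from .annotation import RepeatTaxonomy
from .counting import CountTable
from .metagene import MetageneParams
from .samio import ReadAlignmentGroup, group_records, read_sam
from .simulate import (
    FractionSample,
    Reference,
    SimulationConfig,
    generate_reference,
    simulate_all,
    write_reference,
    write_sample,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``simulation`` (generate everything) or ``sam_paths`` +
    ``genes_gtf`` + ``repeats_gtf`` + ``design`` (consume aligner output)
    must be provided.
    """

    out_dir: str
    simulation: SimulationConfig | None = None
    sam_paths: dict[str, str] | None = None
    genes_gtf: str | None = None
    repeats_gtf: str | None = None
    design: dict[str, tuple[str, int]] | None = None
    spike_contig: str = "spikein"
    max_mismatches: int = 10
    top_n: int = 500
    max_fold: float = 2.5
    min_count_ratio: float = 10.0
    min_count_dge: float = 20.0
    fdr: float = 0.05
    min_informative: int = 10
    min_overhang: int = 6
    normalization: str = "median_of_ratios"  # or "spike_in"
    gene_mode: str = "exonic"  # or "last500bp"
    strand_mode: str = "unstranded"
    subsample: bool = False
    run_metagene: bool = True
    metagene_params: MetageneParams = field(default_factory=MetageneParams)
    write_alignments: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            for key in ("exons_per_gene", "exon_length", "intron_length",
                        "consensus_length", "diverged_mismatches",
                        "placement_mix"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "metagene_params" in raw and raw["metagene_params"] is not None:
            raw["metagene_params"] = MetageneParams(**raw["metagene_params"])
        if "design" in raw and raw["design"] is not None:
            raw["design"] = {
                k: (v[0], int(v[1])) for k, v in raw["design"].items()
            }
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory bundle of every table the pipeline emits."""

    design: dict[str, tuple[str, int]]
    qc_summary: dict
    excluded_samples: list[str]
    counts: dict[str, CountTable]
    normalized: dict[str, CountTable]
    size_factors: enrichment.SizeFactors
    ratio_tables: dict[str, pd.DataFrame]
    mwu: dict
    dge: dict[str, pd.DataFrame]
    class_percentages: pd.DataFrame | None
    metagene_matrices: list[metagene.MetageneMatrix]
    reference: Reference | None = None
    samples: list[FractionSample] | None = None


def _spike_counts(
    groups_by_sample: Mapping[str, Sequence[ReadAlignmentGroup]], contig: str
) -> dict[str, int]:
    out = {}
    for name, groups in groups_by_sample.items():
        out[name] = sum(
            1
            for g in groups
            if any(r.chrom == contig for r in g.records)
        )
    return out


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write its report bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    for sub in ("qc", "counts", "enrichment", "metagene"):
        os.makedirs(os.path.join(config.out_dir, sub), exist_ok=True)

    reference: Reference | None = None
    samples: list[FractionSample] | None = None
    if config.simulation is not None:
        reference = generate_reference(config.simulation)
        samples = simulate_all(reference)
        genes = reference.genes
        copies = reference.copies
        taxonomy = reference.taxonomy
        design = {s.name: (s.fraction, s.replicate) for s in samples}
        groups_by_sample = {s.name: s.groups() for s in samples}
        write_reference(reference, os.path.join(config.out_dir, "reference"))
        if config.write_alignments:
            for s in samples:
                write_sample(s, reference, os.path.join(config.out_dir, "samples"))
    else:
        if not (config.sam_paths and config.genes_gtf and config.repeats_gtf
                and config.design):
            raise PipelineError(
                "need either a simulation config or sam_paths + genes_gtf + "
                "repeats_gtf + design"
            )
        genes = annotation.parse_gene_gtf(config.genes_gtf)
        copies = annotation.parse_repeat_gtf(config.repeats_gtf)
        taxonomy = RepeatTaxonomy.from_copies(copies)
        design = dict(config.design)
        groups_by_sample = {
            name: group_records(read_sam(path))
            for name, path in config.sam_paths.items()
        }

    sample_names = sorted(design)
    copies = annotation.classify_genic_context(copies, genes)
    conserved = annotation.filter_conserved(copies, config.max_mismatches)
    annotation.write_context_bed(
        copies, os.path.join(config.out_dir, "repeat_context.bed")
    )

    # ---- QC ----------------------------------------------------------------
    qc_summary: dict = {"samples": {}, "filters": {}}
    passing: dict[str, list[ReadAlignmentGroup]] = {}
    excluded: list[str] = []
    for name in sample_names:
        groups = groups_by_sample[name]
        groups, n_dup = qc.filter_duplicates(groups)
        si_table, si_summary = qc.splicing_index_distribution(
            groups, genes, min_overhang=config.min_overhang,
            min_informative=config.min_informative,
        )
        records = [r for g in groups for r in g.records]
        cov = qc.gene_body_coverage(records, genes, top_n=config.top_n)
        verdict = qc.integrity_filter(cov, max_fold=config.max_fold)
        si_table.to_csv(
            os.path.join(config.out_dir, "qc", f"si_{name}.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
        pd.DataFrame(
            {"position": np.arange(101), "coverage": cov.profile}
        ).to_csv(
            os.path.join(config.out_dir, "qc", f"coverage_{name}.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
        qc_summary["samples"][name] = {
            "fragments": len(groups),
            "duplicates_removed": n_dup,
            "splicing_index": si_summary,
            "coverage_ratio_5p_3p": None
            if verdict.ratio_5p_3p is None
            else round(verdict.ratio_5p_3p, 6),
            "n_genes_used": cov.n_genes_used,
            "integrity": "pass" if verdict.passed else "fail",
            "integrity_reason": verdict.reason,
        }
        if verdict.passed:
            passing[name] = groups
        else:
            excluded.append(name)
    if not passing:
        raise PipelineError("all samples failed integrity QC")
    qc_summary["excluded_samples"] = excluded

    if config.subsample and len(passing) > 1:
        passing = qc.subsample_to_smallest(passing, seed=config.seed)
        qc_summary["subsampled_to"] = min(len(g) for g in passing.values())

    design = {k: v for k, v in design.items() if k in passing}

    # ---- Counting ----------------------------------------------------------
    index = counting.CopyIndex(copies)
    per_level: dict[str, list[CountTable]] = {lvl: [] for lvl in counting.LEVELS}
    for name in sorted(passing):
        tables = counting.count_all_levels(
            passing[name], index, taxonomy, genes,
            strand_mode=config.strand_mode, gene_mode=config.gene_mode,
            sample=name,
        )
        for lvl, tbl in tables.items():
            per_level[lvl].append(tbl)
    counts = {lvl: counting.combine_tables(tbls) for lvl, tbls in per_level.items()}
    for lvl, tbl in counts.items():
        tbl.counts.rename_axis("feature").to_csv(
            os.path.join(config.out_dir, "counts", f"{lvl}.tsv"), sep="\t"
        )
        qc_summary["filters"][f"{lvl}_features"] = int(len(tbl.counts))

    # ---- Normalization & enrichment ---------------------------------------
    if config.normalization == "spike_in":
        spikes = _spike_counts(passing, config.spike_contig)
        factors = enrichment.size_factors_spike_in(spikes)
    else:
        factors = enrichment.size_factors_median_of_ratios(counts["gene"])
    normalized = {
        lvl: enrichment.normalize(tbl, factors) for lvl, tbl in counts.items()
    }

    ratio_tables: dict[str, pd.DataFrame] = {}
    for lvl, tbl in normalized.items():
        ratio_tables[lvl] = enrichment.log2_ratio_table(
            tbl, design, min_count=config.min_count_ratio
        )
        ratio_tables[lvl].to_csv(
            os.path.join(config.out_dir, "enrichment", f"{lvl}_enrichment.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )

    retro = ratio_tables["element"]["log2_ratio"].to_numpy()
    scpcg = ratio_tables["gene"]["log2_ratio"].to_numpy()
    if retro.size and scpcg.size:
        u, p = enrichment.mwu_one_tailed(retro, scpcg)
        mwu = {
            "U": float(u),
            "p": float(p),
            "n_retro": int(retro.size),
            "n_scpcg": int(scpcg.size),
            "median_retro_log2_ratio": float(np.median(retro)),
            "median_scpcg_log2_ratio": float(np.median(scpcg)),
        }
    else:
        mwu = {"U": None, "p": None, "n_retro": int(retro.size),
               "n_scpcg": int(scpcg.size)}
    with open(os.path.join(config.out_dir, "enrichment", "mwu.json"), "w") as fh:
        json.dump(mwu, fh, indent=2, sort_keys=True)

    dge: dict[str, pd.DataFrame] = {}
    for lvl in ("gene", "element"):
        try:
            dge[lvl] = enrichment.nb_exact_test(
                counts[lvl], factors, design,
                min_norm=config.min_count_dge, fdr_threshold=config.fdr,
            )
        except enrichment.EnrichmentError:
            dge[lvl] = pd.DataFrame(
                columns=["feature", "sum_nuclear", "sum_cytoplasmic",
                         "log2FC", "pvalue", "FDR", "call"]
            )
        dge[lvl].to_csv(
            os.path.join(config.out_dir, "enrichment", f"{lvl}_dge.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )

    try:
        class_pct = enrichment.class_percentage(
            normalized["element"], taxonomy, min_count=config.min_count_ratio
        )
        class_pct.to_csv(
            os.path.join(config.out_dir, "enrichment", "class_percentage.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
    except enrichment.EnrichmentError:
        class_pct = None

    # ---- Metagene ----------------------------------------------------------
    matrices: list[metagene.MetageneMatrix] = []
    if config.run_metagene:
        weights = {
            name: 1.0 / float(factors.factors[name]) for name in passing
        }
        matrices = metagene.build_all_groups(
            {name: passing[name] for name in sorted(passing)},
            conserved,
            params=config.metagene_params,
            read_weights=weights,
        )
        for m in matrices:
            strand_tag = "plus" if m.genome_strand == "+" else "minus"
            metagene.write_matrix_tsv(
                m,
                os.path.join(
                    config.out_dir,
                    "metagene",
                    f"{m.group}_{strand_tag}_{m.read_mode}_{m.sample}.tsv",
                ),
            )

    report = {
        "design": {k: list(v) for k, v in design.items()},
        "qc": qc_summary,
        "size_factors": {
            k: round(float(v), 6) for k, v in factors.factors.items()
        },
        "normalization": factors.method,
        "mwu": {k: (round(v, 10) if isinstance(v, float) else v)
                for k, v in mwu.items()},
        "n_conserved_copies": len(conserved),
        "n_copies": len(copies),
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    return RunResult(
        design=design,
        qc_summary=qc_summary,
        excluded_samples=excluded,
        counts=counts,
        normalized=normalized,
        size_factors=factors,
        ratio_tables=ratio_tables,
        mwu=mwu,
        dge=dge,
        class_percentages=class_pct,
        metagene_matrices=matrices,
        reference=reference,
        samples=samples,
    )


__all__ = ["RunConfig", "RunResult", "PipelineError", "run"]
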