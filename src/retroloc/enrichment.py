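"""Normalization, log2(Nuc/Cyt) localization tables and significance tests.

Size factors come either from median-of-ratios normalization of the
single-copy protein-coding gene (scPCG) counts or from spike-in counts, and
the same factors are applied to the repeat-level tables, so repeat
localization is measured against the scPCG compartment baseline.  A feature
with log2(Nuc/Cyt) > 0 is nuclear, < 0 cytoplasmic.  Group-level
differences between retroelement and scPCG ratios are tested with a
one-tailed Mann-Whitney U test; per-feature localization calls use a
conditional negative-binomial exact test with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .annotation import RepeatTaxonomy
from .counting import CountTable

Design = Mapping[str, tuple[str, int]]  # sample -> (fraction, replicate)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class SizeFactors:
    factors: pd.Series  # per-sample positive scale factors
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise EnrichmentError("size factors must be positive")


def size_factors_median_of_ratios(gene_counts: CountTable) -> SizeFactors:
    """Median-of-ratios size factors from the scPCG count table.

    For sample j, the factor is the median over genes with all-positive
    rows of count[g, j] / geometric-mean over samples of count[g, .].
    """
    df = gene_counts.counts.astype(float)
    if df.shape[1] < 2:
        raise EnrichmentError("median-of-ratios needs >= 2 samples")
    positive = df[(df > 0).all(axis=1)]
    if positive.empty:
        raise EnrichmentError(
            "no gene with positive counts in every sample; consider spike-in "
            "normalization"
        )
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return SizeFactors(np.exp(ratios.median(axis=0)), "median_of_ratios")


def size_factors_spike_in(spike_counts: Mapping[str, int] | pd.Series) -> SizeFactors:
    """Size factors from exogenous spike-in read counts (PhiX-style)."""
    s = pd.Series(spike_counts, dtype=float)
    if (s <= 0).any():
        raise EnrichmentError("spike-in counts must all be positive")
    geo = np.exp(np.log(s).mean())
    return SizeFactors(s / geo, "spike_in")


def normalize(counts: CountTable, factors: SizeFactors) -> CountTable:
    """Divide each sample column by its size factor."""
    missing = set(counts.samples) - set(factors.factors.index)
    if missing:
        raise EnrichmentError(f"no size factor for samples: {sorted(missing)}")
    df = counts.counts.astype(float).div(factors.factors[counts.samples], axis=1)
    return CountTable(counts.level, df)


def _split_design(design: Design, samples: Sequence[str]) -> tuple[list[str], list[str]]:
    nuc = [s for s in samples if design[s][0] == "nuclear"]
    cyt = [s for s in samples if design[s][0] == "cytoplasmic"]
    if not nuc or not cyt:
        raise EnrichmentError("design needs >= 1 nuclear and >= 1 cytoplasmic sample")
    return nuc, cyt


def log2_ratio_table(
    norm: CountTable,
    design: Design,
    min_count: float = 10.0,
) -> pd.DataFrame:
    """Per-feature log2(Nuc/Cyt) of replicate-mean normalized counts.

    A feature is retained iff its replicate-mean normalized count exceeds
    ``min_count`` in both fractions (which also guarantees a finite ratio).
    Localization is called from the sign of the ratio.
    """
    nuc, cyt = _split_design(design, norm.samples)
    mean_nuc = norm.counts[nuc].mean(axis=1)
    mean_cyt = norm.counts[cyt].mean(axis=1)
    keep = (mean_nuc > min_count) & (mean_cyt > min_count)
    log2r = np.log2(mean_nuc[keep] / mean_cyt[keep])
    table = pd.DataFrame(
        {
            "feature": log2r.index,
            "level": norm.level,
            "mean_nuclear": mean_nuc[keep].to_numpy(),
            "mean_cytoplasmic": mean_cyt[keep].to_numpy(),
            "log2_ratio": log2r.to_numpy(),
        }
    )
    table["localization"] = np.select(
        [table["log2_ratio"] > 0, table["log2_ratio"] < 0],
        ["nuclear", "cytoplasmic"],
        default="none",
    )
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x vs y: pairs with x > y plus half the tied pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mwu_one_tailed(
    retro_ratios: Sequence[float],
    scpcg_ratios: Sequence[float],
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of retro > scPCG ratios.

    Exact by full enumeration of group assignments when the combined sample
    size is at most ``exact_max_n`` (ties handled by mid-ranking); normal
    approximation with tie correction and continuity correction otherwise.
    Returns (U, p).
    """
    x = np.asarray(retro_ratios, dtype=float)
    y = np.asarray(scpcg_ratios, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EnrichmentError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n)
        total = 0
        hits = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu - 0.5) / math.sqrt(sigma2)
    return u_obs, float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


# ---------------------------------------------------------------------------
# Conditional negative-binomial exact test


def _log_nb_pmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """log PMF of NB by (mean, dispersion); Poisson when dispersion -> 0."""
    k = np.asarray(k, dtype=float)
    if dispersion <= 0:
        return k * math.log(mean) - mean - gammaln(k + 1)
    r = 1.0 / dispersion
    logp = math.log(mean / (mean + r))
    logq = math.log(r / (mean + r))
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1) + k * logp + r * logq


def _conditional_exact_p(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p of the nuclear total given the grand total.

    Group sums are negative binomial with dispersion phi/n_reps (Poisson at
    phi = 0, where the conditional law is binomial with success fraction
    n1/(n1+n2)); the p-value sums conditional probabilities no larger than
    the observed outcome's.
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    k = np.arange(t + 1)
    logf = _log_nb_pmf(k, n1 * mu, phi / n1) + _log_nb_pmf(
        t - k, n2 * mu, phi / n2
    )
    logf -= logf.max()
    f = np.exp(logf)
    f /= f.sum()
    p_obs = f[y1]
    return float(f[f <= p_obs * (1 + 1e-7)].sum())


def estimate_common_dispersion(
    norm_counts: pd.DataFrame, groups: Sequence[Sequence[str]]
) -> float:
    """Method-of-moments common dispersion across features.

    Per feature and replicate group, dispersion = (var - mean) / mean^2 on
    normalized counts; the common value is the median of the positive-mean
    contributions, floored at 0.
    """
    disps: list[float] = []
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = norm_counts[list(cols)]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        disps.extend(((v[ok] - m[ok]) / (m[ok] ** 2)).tolist())
    if not disps:
        return 0.0
    return max(0.0, float(np.median(disps)))


def nb_exact_test(
    raw_counts: CountTable,
    factors: SizeFactors,
    design: Design,
    min_norm: float = 20.0,
    fdr_threshold: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-feature nuclear-vs-cytoplasmic differential localization calls.

    Features with normalized count below ``min_norm`` in every sample are
    filtered out; the rest are tested with the conditional NB exact test on
    library-equalized totals, BH-adjusted, and called nuclear (log2FC > 0)
    or cytoplasmic (log2FC < 0) when FDR < ``fdr_threshold``.
    """
    norm = normalize(raw_counts, factors)
    df = norm.counts
    if not df.to_numpy().any():
        raise EnrichmentError("count table is all zeros")
    nuc, cyt = _split_design(design, norm.samples)
    keep = (df >= min_norm).any(axis=1)
    kept = df[keep]
    n1, n2 = len(nuc), len(cyt)
    if dispersion is None:
        if n1 < 2 and n2 < 2:
            import warnings

            warnings.warn(
                "single replicate per fraction: dispersion fixed to 0 "
                "(Poisson/binomial exact test)",
                stacklevel=2,
            )
            phi = 0.0
        else:
            phi = estimate_common_dispersion(kept, [nuc, cyt])
    else:
        phi = dispersion

    rows = []
    for feature, row in kept.iterrows():
        y1 = int(round(row[nuc].sum()))
        y2 = int(round(row[cyt].sum()))
        m1, m2 = y1 / n1, y2 / n2
        if m1 == 0 or m2 == 0:
            log2fc = math.log2((m1 + 0.5) / (m2 + 0.5))
        else:
            log2fc = math.log2(m1 / m2)
        p = _conditional_exact_p(y1, y2, n1, n2, phi)
        rows.append((feature, y1, y2, log2fc, p))
    result = pd.DataFrame(
        rows, columns=["feature", "sum_nuclear", "sum_cytoplasmic", "log2FC", "pvalue"]
    )
    result["FDR"] = bh_adjust(result["pvalue"]) if len(result) else []
    result["call"] = "none"
    sig = result["FDR"] < fdr_threshold
    result.loc[sig & (result["log2FC"] > 0), "call"] = "nuclear"
    result.loc[sig & (result["log2FC"] < 0), "call"] = "cytoplasmic"
    result.attrs["dispersion"] = phi
    return result


def class_percentage(
    norm_elements: CountTable,
    taxonomy: RepeatTaxonomy,
    min_count: float = 10.0,
) -> pd.DataFrame:
    """Percentage of expressed element types per repeat class.

    An element type is expressed when its mean normalized count across
    samples exceeds ``min_count``; percentages are over expressed types and
    sum to 100.
    """
    if norm_elements.level != "element":
        raise EnrichmentError("class_percentage expects an element-level table")
    mean = norm_elements.counts.mean(axis=1)
    expressed = mean[mean > min_count]
    if expressed.empty:
        raise EnrichmentError("no expressed element passes the count filter")
    classes = pd.Series(
        {el: taxonomy.class_of(el) for el in expressed.index}, name="repclass"
    )
    pct = classes.value_counts() / len(classes) * 100.0
    return (
        pct.rename("percentage")
        .rename_axis("repclass")
        .reset_index()
        .sort_values("repclass")
        .reset_index(drop=True)
    )


__all__ = [
    "EnrichmentError",
    "SizeFactors",
    "size_factors_median_of_ratios",
    "size_factors_spike_in",
    "normalize",
    "log2_ratio_table",
    "mwu_one_tailed",
    "bh_adjust",
    "estimate_common_dispersion",
    "nb_exact_test",
    "class_percentage",
]
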