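"""Normalization, localization tables and significance-test tests."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retroloc.annotation import RepeatTaxonomy
from retroloc.counting import CountTable
from retroloc.enrichment import (
    EnrichmentError,
    SizeFactors,
    bh_adjust,
    class_percentage,
    log2_ratio_table,
    mwu_one_tailed,
    nb_exact_test,
    normalize,
    size_factors_median_of_ratios,
    size_factors_spike_in,
)


def _table(data, level="gene"):
    return CountTable(level, pd.DataFrame(data))


DESIGN = {
    "nuc1": ("nuclear", 1),
    "nuc2": ("nuclear", 2),
    "cyt1": ("cytoplasmic", 1),
    "cyt2": ("cytoplasmic", 2),
}


# ---------------------------------------------------------------------------
# size factors / normalization


def test_median_of_ratios_identity_and_scaling():
    f = size_factors_median_of_ratios(
        _table(pd.DataFrame({"a": [10, 100, 40], "b": [10, 100, 40]},
                            index=["g1", "g2", "g3"]))
    )
    assert np.allclose(f.factors, 1.0)
    doubled = pd.DataFrame(
        {"a": [10, 100, 40], "b": [20, 200, 80]}, index=["g1", "g2", "g3"]
    )
    f = size_factors_median_of_ratios(_table(doubled))
    assert f.factors["b"] / f.factors["a"] == pytest.approx(2.0)


def test_median_of_ratios_matches_hand_computed_values():
    df = pd.DataFrame(
        {
            "s1": [10, 100, 40, 5, 200],
            "s2": [20, 150, 80, 5, 100],
            "s3": [30, 250, 120, 15, 400],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    f = size_factors_median_of_ratios(_table(df))
    # frozen from an independent median-of-ratios computation of this table
    assert np.allclose(
        f.factors[["s1", "s2", "s3"]],
        [0.6436595897, 0.9654893846, 1.6509636244],
    )


def test_median_of_ratios_requires_all_positive_row():
    df = pd.DataFrame({"a": [0, 5], "b": [3, 0]}, index=["g1", "g2"])
    with pytest.raises(EnrichmentError, match="spike-in"):
        size_factors_median_of_ratios(_table(df))


def test_spike_in_factors():
    f = size_factors_spike_in({"a": 500, "b": 500})
    assert np.allclose(f.factors, 1.0)
    f = size_factors_spike_in({"a": 1000, "b": 2000})
    assert f.factors["a"] == pytest.approx(1 / np.sqrt(2))
    assert f.factors["b"] == pytest.approx(np.sqrt(2))
    with pytest.raises(EnrichmentError):
        size_factors_spike_in({"a": 0, "b": 10})


def test_normalize_divides_columns():
    tbl = _table(pd.DataFrame({"a": [10.0, 4.0], "b": [8.0, 2.0]},
                              index=["x", "y"]))
    f = SizeFactors(pd.Series({"a": 1.0, "b": 2.0}), "spike_in")
    out = normalize(tbl, f)
    assert out.counts["a"].tolist() == [10.0, 4.0]
    assert out.counts["b"].tolist() == [4.0, 1.0]
    with pytest.raises(EnrichmentError):
        normalize(tbl, SizeFactors(pd.Series({"a": 1.0}), "spike_in"))


def test_rescaling_one_sample_leaves_log2_ratios_invariant():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(
        rng.integers(30, 500, size=(40, 4)).astype(float),
        index=[f"g{i}" for i in range(40)],
        columns=list(DESIGN),
    )
    def ratios(df):
        f = size_factors_median_of_ratios(_table(df))
        return log2_ratio_table(normalize(_table(df), f), DESIGN, 0.0)

    a = ratios(raw)
    scaled = raw.copy()
    scaled["nuc1"] *= 7.3
    b = ratios(scaled)
    assert np.allclose(a["log2_ratio"], b["log2_ratio"], atol=1e-9)


# ---------------------------------------------------------------------------
# log2 ratio table


def test_log2_ratio_sign_rule_and_filter():
    norm = _table(
        pd.DataFrame(
            {
                "nuc1": [80.0, 20.0, 5.0],
                "nuc2": [80.0, 20.0, 5.0],
                "cyt1": [20.0, 20.0, 5.0],
                "cyt2": [20.0, 20.0, 5.0],
            },
            index=["up", "flat", "low"],
        ),
        level="element",
    )
    out = log2_ratio_table(norm, DESIGN, min_count=10.0).set_index("feature")
    assert out.loc["up", "log2_ratio"] == pytest.approx(2.0)
    assert out.loc["up", "localization"] == "nuclear"
    assert out.loc["flat", "log2_ratio"] == 0.0
    assert out.loc["flat", "localization"] == "none"
    assert "low" not in out.index  # fails the > 10 filter


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_tied_identical_groups():
    u, p = mwu_one_tailed([1, 2, 3], [1, 2, 3])
    assert u == pytest.approx(4.5)
    assert p >= 0.5


def test_mwu_complete_separation_small_n():
    u, p = mwu_one_tailed([5, 6, 7], [1, 2, 3])
    assert u == pytest.approx(9.0)
    assert p == pytest.approx(1 / 20)


def _enumeration_oracle(x, y):
    """Independent exact one-tailed MWU via rank sums over all splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2
    u_obs = u_of(range(n1))
    total = hits = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if u_of(comb) >= u_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def test_mwu_agrees_with_enumeration_for_all_small_sizes():
    rnd = random.Random(5)
    for n1 in range(1, 7):
        for n2 in range(1, 13 - n1):
            if n1 + n2 > 12:
                continue
            x = [rnd.randrange(0, 6) for _ in range(n1)]  # ties likely
            y = [rnd.randrange(0, 6) for _ in range(n2)]
            u, p = mwu_one_tailed(x, y)
            u_ref, p_ref = _enumeration_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)


def test_mwu_exact_agrees_with_scipy_without_ties():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.normal(size=6).tolist()
        y = rng.normal(size=7).tolist()
        u, p = mwu_one_tailed(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_mwu_asymptotic_agrees_with_scipy():
    rng = np.random.default_rng(4)
    x = rng.normal(0.7, 1, size=30).tolist()
    y = rng.normal(0.0, 1, size=25).tolist()
    u, p = mwu_one_tailed(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_mwu_rejects_empty_group():
    with pytest.raises(EnrichmentError):
        mwu_one_tailed([], [1.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_worked_examples():
    assert bh_adjust([0.03]) == [pytest.approx(0.03)]
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    with pytest.raises(EnrichmentError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.uniform(size=50)
    mine = bh_adjust(p)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(mine, ref)


# ---------------------------------------------------------------------------
# NB exact test


def _raw(nuc, cyt, n=20, seed=0, level="element"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "nuc1": rng.poisson(nuc, n),
            "nuc2": rng.poisson(nuc, n),
            "cyt1": rng.poisson(cyt, n),
            "cyt2": rng.poisson(cyt, n),
        },
        index=[f"f{i}" for i in range(n)],
    )
    return CountTable(level, df)


def _unit_factors():
    return SizeFactors(pd.Series(1.0, index=list(DESIGN)), "spike_in")


def test_nb_test_identical_fractions_is_null():
    df = pd.DataFrame(
        {"nuc1": [50, 100], "nuc2": [50, 100],
         "cyt1": [50, 100], "cyt2": [50, 100]},
        index=["a", "b"],
    )
    out = nb_exact_test(CountTable("element", df), _unit_factors(), DESIGN,
                        dispersion=0.0).set_index("feature")
    assert np.allclose(out["log2FC"], 0.0)
    assert np.allclose(out["pvalue"], 1.0)
    assert (out["call"] == "none").all()


def test_nb_test_dispersion_zero_equals_binomial_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        y = rng.integers(0, 300, size=4)
        df = pd.DataFrame(
            {s: [int(v) + 20] for s, v in zip(DESIGN, y)}, index=["f"]
        )
        out = nb_exact_test(CountTable("element", df), _unit_factors(),
                            DESIGN, dispersion=0.0)
        y1 = int(df[["nuc1", "nuc2"]].sum(axis=1).iloc[0])
        t = int(df.sum(axis=1).iloc[0])
        expected = stats.binomtest(y1, t, 0.5).pvalue
        assert out["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_nb_test_detects_strong_enrichment():
    out = nb_exact_test(_raw(nuc=400, cyt=50), _unit_factors(), DESIGN)
    assert (out["call"] == "nuclear").all()
    assert (out["log2FC"] > 0).all()


def test_nb_test_min_count_filter():
    df = pd.DataFrame(
        {"nuc1": [5, 100], "nuc2": [5, 100], "cyt1": [5, 100], "cyt2": [5, 100]},
        index=["low", "high"],
    )
    out = nb_exact_test(CountTable("element", df), _unit_factors(), DESIGN)
    assert out["feature"].tolist() == ["high"]


def test_nb_test_all_zero_errors():
    df = pd.DataFrame({s: [0, 0] for s in DESIGN}, index=["a", "b"])
    with pytest.raises(EnrichmentError):
        nb_exact_test(CountTable("element", df), _unit_factors(), DESIGN)


# ---------------------------------------------------------------------------
# class percentages


TAX = RepeatTaxonomy(
    {"L1-1": "L1", "L1-2": "L1", "Alu-1": "Alu", "Alu-2": "Alu", "SVA-1": "SVA"},
    {"L1": "LINE", "Alu": "SINE", "SVA": "Retroposon"},
)


def test_class_percentage_even_split():
    df = pd.DataFrame(
        {"s1": [50, 60, 70, 80, 1]},
        index=["L1-1", "L1-2", "Alu-1", "Alu-2", "SVA-1"],
    )
    out = class_percentage(CountTable("element", df), TAX, min_count=10)
    pct = dict(zip(out["repclass"], out["percentage"]))
    assert pct == {"LINE": pytest.approx(50.0), "SINE": pytest.approx(50.0)}
    assert out["percentage"].sum() == pytest.approx(100.0)


def test_class_percentage_single_class_and_empty():
    df = pd.DataFrame({"s1": [50, 60]}, index=["L1-1", "L1-2"])
    out = class_percentage(CountTable("element", df), TAX, min_count=10)
    assert out["percentage"].tolist() == [pytest.approx(100.0)]
    low = pd.DataFrame({"s1": [1, 2]}, index=["L1-1", "L1-2"])
    with pytest.raises(EnrichmentError):
        class_percentage(CountTable("element", low), TAX, min_count=10)
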