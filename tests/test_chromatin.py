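"""Differential window signal and the epigenome gene sets."""

import numpy as np
import pandas as pd
import pytest

from epismad.chromatin import (ALL_FACTORS, build_epigenome_sets,
                               differential_test, gene_set_enrichment,
                               quantify_window_counts)
from epismad.io import CountTable


def table_from_counts(a, b, lib=1e6):
    ids = [f"w{i}" for i in range(len(a))]
    counts = pd.DataFrame({"A.f.1": a, "B.f.1": b}, index=pd.Index(ids, name="window_id"))
    return CountTable(counts, pd.Series({"A.f.1": lib, "B.f.1": lib}))


def test_quantify_passthrough_and_missing_window():
    table = table_from_counts([5, 10], [1, 2])
    out = quantify_window_counts(["w0", "w1"], table)
    pd.testing.assert_frame_equal(out.counts, table.counts)
    with pytest.raises(ValueError, match="missing"):
        quantify_window_counts(["w0", "nope"], table)


def test_differential_example_log2fc_and_direction():
    table = table_from_counts([100], [20])
    calls = differential_test(table)
    row = calls.iloc[0]
    assert row["log2fc"] == pytest.approx(np.log2(100.5 / 20.5), abs=1e-9)
    assert row["direction"] == "higher_A"


def test_equal_counts_are_ns_with_zero_lfc():
    table = table_from_counts([50, 200], [50, 200])
    calls = differential_test(table)
    assert (calls["log2fc"] == 0).all()
    assert (calls["direction"] == "ns").all()


def test_direction_antisymmetry_under_condition_swap():
    rng = np.random.default_rng(0)
    a = rng.poisson(100, 200)
    b = rng.poisson(60, 200)
    table = table_from_counts(a, b)
    fwd = differential_test(table, "A", "B")
    rev = differential_test(table, "B", "A")
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
    np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)
    flip = {"higher_A": "higher_B", "higher_B": "higher_A", "ns": "ns"}
    assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])


def test_null_simulation_fdr_controlled():
    rng = np.random.default_rng(1)
    n = 1.0 / 0.01
    mu = 100.0
    draws_a = rng.negative_binomial(n, n / (n + mu), 2000)
    draws_b = rng.negative_binomial(n, n / (n + mu), 2000)
    calls = differential_test(table_from_counts(draws_a, draws_b))
    assert (calls["direction"] != "ns").mean() < 0.01


def test_replicated_counts_use_welch_path():
    rng = np.random.default_rng(2)
    ids = [f"w{i}" for i in range(300)]
    cols = {}
    for cond, mu in (("A", 200), ("B", 50)):
        for rep in (1, 2, 3):
            cols[f"{cond}.f.{rep}"] = rng.poisson([mu] * 150 + [100] * 150)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="window_id"))
    table = CountTable(counts, pd.Series({c: 1e6 for c in cols}))
    calls = differential_test(table)
    assert (calls["direction"][:150] == "higher_A").mean() > 0.9
    assert (calls["direction"][150:] == "ns").mean() > 0.9


def calls_frame(factor, higher_a=(), higher_b=(), universe=()):
    rows = []
    for g in universe:
        direction = "higher_A" if g in higher_a else "higher_B" if g in higher_b else "ns"
        rows.append((g, factor, 0.0, 1.0, 1.0, direction))
    return pd.DataFrame(rows, columns=["window_id", "factor", "log2fc",
                                       "pvalue", "fdr", "direction"])


UNIVERSE = [f"g{i}" for i in range(10)]


def all_factor_calls(**overrides):
    calls = {f: calls_frame(f, universe=UNIVERSE) for f in ALL_FACTORS}
    calls.update(overrides)
    return calls


class TestEpigenomeSets:
    def test_open_chromatin_union_rule(self):
        calls = all_factor_calls(h3k27ac=calls_frame("h3k27ac", higher_a={"g1"}, universe=UNIVERSE))
        sets = build_epigenome_sets(calls)
        assert "g1" in sets.open_chromatin_high["A"]
        assert "g1" not in sets.smad3_high["A"]

    def test_hypo_methylation_inversion(self):
        calls = all_factor_calls(
            methylation=calls_frame("methylation", higher_b={"g2"}, universe=UNIVERSE))
        sets = build_epigenome_sets(calls)
        assert "g2" in sets.hypo_methylation["A"]
        assert "g2" not in sets.hypo_methylation["B"]

    def test_missing_factor_rejected(self):
        calls = all_factor_calls()
        del calls["polii"]
        with pytest.raises(ValueError, match="polii"):
            build_epigenome_sets(calls)


class TestGeneSetEnrichment:
    def test_example_universe_20(self):
        universe = {f"g{i}" for i in range(20)}
        context = {f"g{i}" for i in range(5)}
        differential = {"g0", "g1", "g2", "g3", "g10"}  # overlap 4
        res = gene_set_enrichment(differential, context, universe)
        from math import comb
        expected = (comb(5, 4) * comb(15, 1) + comb(5, 5)) / comb(20, 5)
        assert res["pvalue"] == pytest.approx(expected, abs=1e-12)
        assert res["overlap"] == 4

    def test_differential_set_equals_universe_uninformative(self):
        universe = {f"g{i}" for i in range(10)}
        res = gene_set_enrichment(universe, {"g1", "g2"}, universe)
        assert res["pvalue"] == pytest.approx(1.0)

    def test_overlap_at_expectation_not_significant(self):
        rng = np.random.default_rng(3)
        universe = {f"g{i}" for i in range(1000)}
        pvals = []
        for _ in range(50):
            diff = set(rng.choice(sorted(universe), 200, replace=False))
            ctx = set(rng.choice(sorted(universe), 100, replace=False))
            pvals.append(gene_set_enrichment(diff, ctx, universe)["pvalue"])
        assert np.median(pvals) > 0.2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gene_set_enrichment(set(), set(), set())
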