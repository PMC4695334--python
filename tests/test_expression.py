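"""Responsive-gene calling and the context-set partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epismad.expression import (call_responsive, partition_context_sets,
                                sets_from_lists)
from epismad.io import ExpressionMatrix, SampleAnnotation
from epismad.stats import bh_adjust


def build_matrix(values: dict[str, np.ndarray], gene_ids):
    """values: token -> column vector."""
    samples = []
    frame = {}
    for token, col in values.items():
        cond, treat, time, rep = token.split(".")
        samples.append(SampleAnnotation(cond, treat, int(time), int(rep)))
        frame[token] = col
    return ExpressionMatrix(pd.DataFrame(frame, index=list(gene_ids)), samples)


def matrix_from_groups(control: np.ndarray, treated: np.ndarray, condition="A", time=6):
    gene_ids = [f"g{i}" for i in range(control.shape[0])]
    cols = {}
    for r in range(control.shape[1]):
        cols[f"{condition}.control.{time}.{r + 1}"] = control[:, r]
    for r in range(treated.shape[1]):
        cols[f"{condition}.treated.{time}.{r + 1}"] = treated[:, r]
    return build_matrix(cols, gene_ids)


def test_identical_groups_yield_no_responsive_genes():
    rng = np.random.default_rng(0)
    control = rng.normal(6, 0.5, (50, 3))
    expr = matrix_from_groups(control, control.copy())
    calls = call_responsive(expr, "A", 6)
    assert (calls["pvalue"] == 1.0).all()
    assert not calls["responsive"].any()


def test_planted_gene_recovered_with_oracle_statistics():
    """One strong gene among 100 nulls; expected p from a hand Welch t and
    the expected FDR from an independent BH pass."""
    rng = np.random.default_rng(1)
    control = rng.normal(5, 0.05, (101, 3))
    treated = rng.normal(5, 0.05, (101, 3))
    control[0] = [5.0, 5.1, 4.9]
    treated[0] = [7.0, 7.1, 6.9]
    expr = matrix_from_groups(control, treated)
    calls = call_responsive(expr, "A", 6, method="welch")
    top = calls.iloc[0]
    assert top["log2fc"] == pytest.approx(2.0, abs=1e-9)
    t_oracle, p_oracle = sps.ttest_ind([7.0, 7.1, 6.9], [5.0, 5.1, 4.9], equal_var=False)
    assert top["pvalue"] == pytest.approx(p_oracle, rel=1e-9)
    q_oracle = bh_adjust(calls["pvalue"].to_numpy())[0]
    assert top["fdr"] == pytest.approx(q_oracle, rel=1e-12)
    assert bool(top["responsive"])


def test_null_simulation_p_uniform_and_fdr_controls():
    rng = np.random.default_rng(2)
    m = 1000
    expr = matrix_from_groups(rng.normal(6, 0.5, (m, 3)), rng.normal(6, 0.5, (m, 3)))
    calls = call_responsive(expr, "A", 6)
    assert sps.kstest(calls["pvalue"], "uniform").pvalue > 0.01
    assert calls["responsive"].mean() < 0.01


def test_monotonicity_in_effect_size():
    """Enlarging the planted effect never loses responsive genes at fixed noise."""
    rng = np.random.default_rng(3)
    m, n_true = 300, 60
    control = rng.normal(6, 0.5, (m, 3))
    noise = rng.normal(0, 0.5, (m, 3))
    previous = -1
    for effect in (0.5, 1.0, 2.0, 4.0):
        treated = control + noise
        treated[:n_true] += effect
        expr = matrix_from_groups(control, treated)
        n_resp = int(call_responsive(expr, "A", 6)["responsive"].sum())
        assert n_resp >= previous
        previous = n_resp
    assert previous >= 0.9 * n_true


def make_calls(universe, responsive, condition, time=6):
    return pd.DataFrame({
        "gene_id": list(universe),
        "condition": condition,
        "time": time,
        "responsive": [g in responsive for g in universe],
    })


def test_partition_set_algebra():
    universe = [f"g{i}" for i in range(1, 6)]
    calls_a = make_calls(universe, {"g1", "g2"}, "A")
    calls_b = make_calls(universe, {"g2", "g3"}, "B")
    sets = partition_context_sets(calls_a, calls_b)
    assert sets.at(6, "A_unique") == {"g1"}
    assert sets.at(6, "B_unique") == {"g3"}
    assert sets.at(6, "shared") == {"g2"}
    assert sets.at(6, "independent") == {"g4", "g5"}
    assert sets.background == {"g4", "g5"}


def test_partition_identical_conditions_no_uniques():
    universe = [f"g{i}" for i in range(10)]
    calls = make_calls(universe, {"g0", "g1"}, "A")
    sets = partition_context_sets(calls, calls.assign(condition="B"))
    assert sets.at(6, "A_unique") == set()
    assert sets.at(6, "B_unique") == set()
    assert sets.at(6, "shared") == {"g0", "g1"}


def test_partition_is_a_partition_each_time_point():
    universe = {f"g{i}" for i in range(40)}
    rng = np.random.default_rng(4)
    resp_a = {t: set(rng.choice(sorted(universe), 10, replace=False)) for t in (1, 3, 6, 24)}
    resp_b = {t: set(rng.choice(sorted(universe), 10, replace=False)) for t in (1, 3, 6, 24)}
    sets = sets_from_lists(universe, resp_a, resp_b)
    for t, groups in sets.per_time.items():
        union = set().union(*groups.values())
        assert union == universe
        total = sum(len(g) for g in groups.values())
        assert total == len(universe)  # pairwise disjoint
    # background: responsive nowhere
    ever = set().union(*(resp_a[t] | resp_b[t] for t in resp_a))
    assert sets.background == universe - ever


def test_universe_mismatch_rejected():
    calls_a = make_calls(["g1", "g2"], set(), "A")
    calls_b = make_calls(["g1", "g3"], set(), "B")
    with pytest.raises(ValueError, match="universe"):
        partition_context_sets(calls_a, calls_b)
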