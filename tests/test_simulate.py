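"""The synthetic-data generator: determinism, marginals, consistency."""

import numpy as np
import pandas as pd
import pytest

from epismad.peaks import match_peaks
from epismad.simulate import (SimulationConfig, SimulationError, accuracy,
                              confusion_matrix, set_metrics, simulate,
                              truth_vs_result_report)


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=5, n_genes=60, n_chromosomes=2)
    for name in ("run1", "run2"):
        (tmp_path / name).mkdir()
        simulate(cfg).write(tmp_path / name)
    files1 = sorted((tmp_path / "run1").rglob("*"))
    files2 = sorted((tmp_path / "run2").rglob("*"))
    assert [f.name for f in files1] == [f.name for f in files2]
    for f1, f2 in zip(files1, files2):
        if f1.is_file():
            assert f1.read_bytes() == f2.read_bytes(), f1.name


def test_different_seeds_differ():
    d1 = simulate(SimulationConfig(seed=1, n_genes=60, n_chromosomes=2))
    d2 = simulate(SimulationConfig(seed=2, n_genes=60, n_chromosomes=2))
    assert not d1.expression.values.equals(d2.expression.values)


def test_nb_counts_match_configured_moments():
    cfg = SimulationConfig(seed=9, n_genes=5000, n_chromosomes=4,
                           frac_a_unique=0, frac_b_unique=0, frac_shared=0,
                           background_mode_probs={4: 1.0})
    data = simulate(cfg)
    # all genes unbound -> every smad3 count drawn at the low mean
    draws = data.counts["smad3"].counts["A.smad3.1"].to_numpy(float)
    mu, phi = cfg.nb_mean_low, cfg.nb_dispersion
    assert draws.mean() == pytest.approx(mu, rel=0.05)
    assert draws.var() == pytest.approx(mu + phi * mu**2, rel=0.2)


def test_zero_jitter_identical_genes_all_shared(small_dataset=None):
    cfg = SimulationConfig(seed=3, n_genes=80, n_chromosomes=2,
                           shared_jitter=0, fp_rate=0.0, fn_rate=0.0)
    data = simulate(cfg)
    matches = match_peaks(data.peaks[("smad3", "A")], data.peaks[("smad3", "B")])
    by_status = {}
    for m in matches:
        by_status.setdefault(m.status, []).append(m)
    # every planted identical-occupancy gene contributes only shared events
    identical = set(data.truth.loc[data.truth["category"] == "identical", "gene_id"])
    assert identical
    for m in by_status.get("unique_A", []) + by_status.get("unique_B", []):
        gene = (m.id_a or m.id_b).split("_")[1]
        assert gene not in identical


def test_infeasible_placement_names_the_gene():
    cfg = SimulationConfig(seed=4, n_genes=10, n_chromosomes=1,
                           gene_length_min=100, gene_length_max=150,
                           peak_width_mean=3000.0)
    with pytest.raises(SimulationError, match="g00"):
        simulate(cfg)


def test_truth_internal_consistency(small_dataset):
    truth = small_dataset.truth
    # directed genes carry equal TF binding (mode 3) and at least one
    # permissive epigenetic difference in their own condition
    directed = truth[truth["context_label"] == "epigenome_directed"]
    assert (directed["mode"] == 3).all()
    for row in directed.itertuples():
        own = "A" if row.gene_id in set(
            truth.loc[truth["class"] == "A_unique", "gene_id"]) else "B"
        other = "B" if own == "A" else "A"
        open_diff = any(getattr(row, f"{m}_{own}") == "high" and getattr(row, f"{m}_{other}") == "low"
                        for m in ("h3k4me3", "h3k27ac", "polii"))
        hypo_diff = (getattr(row, f"methylation_{own}") == "low"
                     and getattr(row, f"methylation_{other}") == "high")
        assert open_diff or hypo_diff
    # assisted genes have differential TF binding (own-unique mode)
    assisted = truth[truth["context_label"] == "epigenome_assisted"]
    assert assisted["mode"].isin([1, 2]).all()


class TestTruthVsResultReport:
    def test_perfect_agreement_identity_confusion(self, small_dataset):
        truth = small_dataset.truth
        pred = truth.set_index("gene_id")["mode"]
        report = truth_vs_result_report(truth, {"mode": pred})
        mat = report["mode"]["confusion"].to_numpy()
        assert report["mode"]["accuracy"] == 1.0
        assert mat.sum() == np.diag(mat).sum()

    def test_permuted_predictions_score_at_chance(self, small_dataset):
        truth = small_dataset.truth
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(200):
            pred = pd.Series(rng.permutation(truth["mode"].to_numpy()),
                             index=truth["gene_id"].to_numpy())
            accs.append(accuracy(truth.set_index("gene_id")["mode"], pred))
        chance = float((truth["mode"].value_counts(normalize=True) ** 2).sum())
        assert np.mean(accs) == pytest.approx(chance, abs=0.02)

    def test_controlled_corruption_rate(self, small_dataset):
        truth = small_dataset.truth
        rng = np.random.default_rng(1)
        labels = truth["mode"].to_numpy().copy()
        corrupt = rng.random(len(labels)) < 0.25
        labels[corrupt] = [(m % 4) + 1 for m in labels[corrupt]]  # always wrong
        pred = pd.Series(labels, index=truth["gene_id"].to_numpy())
        acc = accuracy(truth.set_index("gene_id")["mode"], pred)
        assert acc == pytest.approx(1 - corrupt.mean(), abs=1e-9)

    def test_id_mismatch_rejected(self, small_dataset):
        truth = small_dataset.truth
        pred = truth.set_index("gene_id")["mode"].iloc[:-1]
        with pytest.raises(ValueError, match="different gene ids"):
            confusion_matrix(truth.set_index("gene_id")["mode"], pred)


def test_set_metrics_edge_cases():
    assert set_metrics({"a", "b"}, {"a"}) == {
        "sensitivity": 0.5, "precision": 1.0, "n_truth": 2, "n_predicted": 1}
    assert set_metrics(set(), set())["sensitivity"] == 1.0
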