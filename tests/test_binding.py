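"""Binding modes, occupancy categories and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from epismad.binding import (assign_proximal_peaks, bound_fraction_enrichment,
                             build_profiles, classify_mode,
                             composite_profile_table, mode_enrichment)
from epismad.genome import ProximalWindow
from epismad.peaks import PeakMatch


def make_window(gene_id, start, end, chrom="chr1"):
    return ProximalWindow(gene_id, "gene_proximal", chrom, start, end)


def shared(start, end, chrom="chr1"):
    return PeakMatch("a", "b", "shared", chrom, start, end, (start + end) // 2)


def unique_a(start, end, chrom="chr1"):
    return PeakMatch("a", None, "unique_A", chrom, start, end, (start + end) // 2)


class TestProximalAssignment:
    def test_partial_overlap_assigns(self):
        windows = {"g": make_window("g", 3500, 8000)}
        assigned = assign_proximal_peaks(windows, [shared(3400, 3600)])
        assert assigned["g"] == [0]

    def test_half_open_boundary_not_assigned(self):
        windows = {"g": make_window("g", 3500, 8000)}
        assigned = assign_proximal_peaks(windows, [shared(8000, 8100)])
        assert assigned["g"] == []

    def test_match_spanning_two_windows_assigned_to_both(self):
        windows = {"g1": make_window("g1", 0, 5000), "g2": make_window("g2", 4500, 9000)}
        assigned = assign_proximal_peaks(windows, [shared(4800, 5200)])
        assert assigned["g1"] == [0] and assigned["g2"] == [0]

    def test_containment_rule_stricter(self):
        windows = {"g": make_window("g", 3500, 8000)}
        matches = [shared(3400, 3600), shared(4000, 4200)]
        assigned = assign_proximal_peaks(windows, matches, rule="containment")
        assert assigned["g"] == [1]

    def test_agreement_with_brute_force_scan(self):
        rng = np.random.default_rng(8)
        windows = {}
        pos = 0
        for i in range(30):
            w = int(rng.integers(2000, 6000))
            windows[f"g{i}"] = make_window(f"g{i}", pos, pos + w)
            pos += w + int(rng.integers(0, 3000))
        matches = []
        for k in range(200):
            start = int(rng.integers(0, pos))
            end = start + int(rng.integers(50, 800))
            matches.append(PeakMatch(f"a{k}", None, "unique_A", "chr1", start, end, start))
        got = assign_proximal_peaks(windows, matches)
        for gid, w in windows.items():
            brute = [i for i, m in enumerate(matches) if m.start < w.end and m.end > w.start]
            assert sorted(got[gid]) == brute


class TestModeClassification:
    @pytest.mark.parametrize("ua,ub,sh,mode,category", [
        (2, 0, 0, 1, "A_only"),
        (0, 2, 0, 2, "B_only"),
        (0, 0, 3, 3, "identical"),
        (1, 0, 2, 3, "mixed"),
        (0, 1, 1, 3, "mixed"),
        (1, 2, 0, 3, "mutually_exclusive"),  # common mode via different sites
        (0, 0, 0, 4, "unbound"),
    ])
    def test_rule_table(self, ua, ub, sh, mode, category):
        prof = classify_mode("g", ua, ub, sh)
        assert (prof.mode, prof.category) == (mode, category)

    def test_swap_symmetry_and_category_refinement(self):
        rng = np.random.default_rng(1)
        swap_mode = {1: 2, 2: 1, 3: 3, 4: 4}
        swap_cat = {"A_only": "B_only", "B_only": "A_only"}
        allowed = {1: {"A_only"}, 2: {"B_only"}, 4: {"unbound"},
                   3: {"identical", "mixed", "mutually_exclusive"}}
        for _ in range(200):
            ua, ub, sh = rng.integers(0, 4, size=3)
            p = classify_mode("g", ua, ub, sh)
            q = classify_mode("g", ub, ua, sh)
            assert q.mode == swap_mode[p.mode]
            assert q.category == swap_cat.get(p.category, p.category)
            assert p.category in allowed[p.mode]


def profiles_from_modes(modes: dict[str, int]) -> pd.DataFrame:
    counts = {1: (1, 0, 0), 2: (0, 1, 0), 3: (0, 0, 1), 4: (0, 0, 0)}
    rows = [(g, *counts[m], m, classify_mode(g, *counts[m]).category)
            for g, m in modes.items()]
    return pd.DataFrame(rows, columns=["gene_id", "n_unique_A", "n_unique_B",
                                       "n_shared", "mode", "category"])


class TestEnrichment:
    def test_bound_fraction_fixed_table(self):
        # 50/100 responsive bound vs 200/1000 background bound
        modes = {}
        for i in range(100):
            modes[f"r{i}"] = 1 if i < 50 else 4
        for i in range(1000):
            modes[f"b{i}"] = 1 if i < 200 else 4
        profiles = profiles_from_modes(modes)
        res = bound_fraction_enrichment({f"r{i}" for i in range(100)},
                                        {f"b{i}" for i in range(1000)}, profiles, "A")
        assert res["chi2"] == pytest.approx(46.58823529411765, abs=1e-9)
        assert res["fold"] == pytest.approx(0.5 / 0.2)

    def test_extreme_case_all_responsive_bound(self):
        modes = {f"r{i}": 3 for i in range(50)}
        modes.update({f"b{i}": 4 for i in range(500)})
        profiles = profiles_from_modes(modes)
        res = bound_fraction_enrichment(set(f"r{i}" for i in range(50)),
                                        set(f"b{i}" for i in range(500)), profiles, "A")
        assert res["fold"] == float("inf")
        assert res["pvalue"] < 1e-20

    def test_overlapping_sets_rejected(self):
        profiles = profiles_from_modes({"g1": 1, "g2": 4})
        with pytest.raises(ValueError, match="disjoint"):
            bound_fraction_enrichment({"g1"}, {"g1", "g2"}, profiles)

    def test_mode_enrichment_fold_and_fdr(self):
        modes = {f"s{i}": 3 if i < 50 else 4 for i in range(100)}
        modes.update({f"b{i}": 3 if i < 200 else 4 for i in range(1000)})
        profiles = profiles_from_modes(modes)
        table = mode_enrichment({f"s{i}" for i in range(100)},
                                {f"b{i}" for i in range(1000)}, profiles)
        row3 = table[table["mode"] == 3].iloc[0]
        assert row3["fold"] == pytest.approx(0.5 / 0.2)
        # BH across exactly the four modes
        assert len(table) == 4
        assert (table["fdr"] >= table["pvalue"] - 1e-12).all()

    def test_mode_enrichment_null_folds_near_one(self):
        rng = np.random.default_rng(12)
        all_modes = {f"g{i}": int(rng.choice([1, 2, 3, 4])) for i in range(2000)}
        profiles = profiles_from_modes(all_modes)
        sample = set(rng.choice(sorted(all_modes), 400, replace=False))
        background = set(all_modes) - sample
        table = mode_enrichment(sample, background, profiles)
        assert ((table["fold"] - 1).abs() < 0.3).all()

    def test_empty_set_rejected(self):
        profiles = profiles_from_modes({"g1": 1})
        with pytest.raises(ValueError, match="empty"):
            mode_enrichment(set(), {"g1"}, profiles)


class TestCompositeProfiles:
    def test_counts_sum_and_category_order(self):
        rng = np.random.default_rng(5)
        modes = {f"g{i}": int(rng.choice([1, 2, 3, 4])) for i in range(60)}
        profiles = profiles_from_modes(modes)
        table = composite_profile_table(set(modes), profiles)
        assert len(table) == 60
        assert table["category_count"].iloc[0] == (table["category"] == table["category"].iloc[0]).sum()
        # brute-force recount
        for cat, group in table.groupby("category"):
            assert (group["category_count"] == len(group)).all()
        # canonical order is respected
        order = ["identical", "mixed", "mutually_exclusive", "A_only", "B_only", "unbound"]
        seen = [c for c in order if c in set(table["category"])]
        assert list(table["category"].unique()) == seen

    def test_single_gene_set(self):
        profiles = profiles_from_modes({"g1": 3})
        table = composite_profile_table({"g1"}, profiles)
        assert table.loc[0, "category"] == "identical"
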