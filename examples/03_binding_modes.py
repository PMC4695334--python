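"""Match TF peaks across conditions and classify genes into binding modes.

Shared events are peaks whose summits fall inside each other's intervals;
per gene the event counts give the four-way mode and, for commonly bound
genes, the occupancy category.  Mode enrichment is measured against the
treatment-independent background with a 2x2 chi-square.
"""

from epismad import (SimulationConfig, simulate, match_peaks, derive_windows,
                     build_profiles, mode_enrichment, truth_context_sets)

data = simulate(SimulationConfig(seed=42, n_genes=400, n_chromosomes=2))

matches = match_peaks(data.peaks[("smad3", "A")], data.peaks[("smad3", "B")])
n_shared = sum(m.status == "shared" for m in matches)
print(f"{len(matches)} binding events: {n_shared} shared, "
      f"{sum(m.status == 'unique_A' for m in matches)} A-unique, "
      f"{sum(m.status == 'unique_B' for m in matches)} B-unique")

windows = derive_windows(data.genes, data.layout, "gene_proximal")
profiles = build_profiles(windows, matches)
print("\ngene binding modes (1=A only, 2=B only, 3=both, 4=neither):")
print(profiles["mode"].value_counts().sort_index().to_string())
print("\noccupancy categories:")
print(profiles["category"].value_counts().to_string())

# enrichment of each mode among the A-unique responders at 24 h,
# using the planted truth sets for a self-contained example
sets = truth_context_sets(data.truth)
table = mode_enrichment(sets.at(24, "A_unique"), sets.background, profiles,
                        label="A_unique_24h")
print("\nmode enrichment of A-unique 24 h responders over background:")
print(table[["mode", "fold", "chi2", "pvalue", "fdr"]].to_string(index=False))
print("fold > 1 with small p marks modes over-represented among these "
      "responders relative to non-responsive genes.")
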