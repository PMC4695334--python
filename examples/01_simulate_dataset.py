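"""Generate a synthetic two-condition dataset and look at its ground truth.

The generator plants responsive-gene classes, TF binding modes, chromatin
states and context labels consistently, then writes standard-format files
(narrowPeak/broadPeak, count TSVs, an expression TSV) plus truth.tsv.
"""

from epismad import SimulationConfig, simulate

cfg = SimulationConfig(seed=42, n_genes=300, n_chromosomes=2)
data = simulate(cfg)

print(f"genome: {data.layout.lengths}")
print(f"TF peaks: {len(data.peaks[('smad3', 'A')])} in A, "
      f"{len(data.peaks[('smad3', 'B')])} in B")
print("\nplanted responsive classes:")
print(data.truth["class"].value_counts().to_string())
print("\nplanted binding modes (1=A only, 2=B only, 3=both, 4=neither):")
print(data.truth["mode"].value_counts().sort_index().to_string())
print("\nplanted context labels (context-specific genes only):")
print(data.truth.loc[data.truth["context_label"] != "", "context_label"]
      .value_counts().to_string())

data.write("scratch/example_dataset")
print("\nfiles written to scratch/example_dataset/ "
      "(peaks/, counts/, expression.tsv, truth.tsv)")
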