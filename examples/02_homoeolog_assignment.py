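"""Assign allopolyploid reads to their progenitor subgenomes.

Simulates homoeologous reference pairs at 2% divergence, draws error-free
reads of known origin, assigns each read by preferential ungapped match,
and scores the result against the per-read truth table.
"""

from triadexpr import homoeolog as hm
from triadexpr.synthdata import SimConfig, simulate_reads, simulate_references

cfg = SimConfig(n_genes=100, divergence_rate=0.02, error_rate=0.0,
                gene_length=400, read_length=100, seed=3)
refs, _ = simulate_references(cfg)
index = hm.build_index(refs, k=21)
reads, truth = simulate_reads(refs, cfg, n_reads=5000)

assignments = hm.assign_reads(reads, index)
merged = assignments.merge(truth, on="read", suffixes=("", "_true"))
called = merged[merged["subgenome"].isin(["D3", "D4"])]
accuracy = (called["subgenome"] == called["subgenome_true"]).mean()

print(assignments["subgenome"].value_counts().to_string())
print(f"\nassignment accuracy (ties excluded): {accuracy:.4f}")

counts = hm.count_homoeologs(assignments, sorted(refs))
summary = hm.usage_percentages(counts)
print(f"genes with homoeologue counts: {summary.genes_used}")
print(f"mean percent-D3 usage: {summary.mean_percent_d3:.2f}%")
print("\nAt 2% homoeologue divergence most 100 bp reads cover a diagnostic "
      "site and sort cleanly; reads in identical windows stay ambiguous and "
      "never enter the usage percentages.")
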