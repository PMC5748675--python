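"""Exact conditional NB test of the inoculation response within one species.

Simulates counts with 15% of genes responding to inoculation at |log2FC| = 2
in D3, runs the full contrast pipeline (size factors -> CPM filter ->
common dispersion -> exact test -> BH), and scores detection against truth.
"""

import numpy as np

from triadexpr import diffexpr as de
from triadexpr.synthdata import SimConfig, simulate_counts

cfg = SimConfig(
    n_genes=2000, category_fractions={}, inoculation_de_fraction=0.15,
    lfc_magnitude=2.0, baseline_log2_mean=(np.log2(200.0), 0.0),
    dispersion=0.05, n_modules=0, seed=4,
)
counts, samples, truth = simulate_counts(cfg)

mock = list(samples.index[(samples.species == "D3") & (samples.treatment == "MOCK")])
inoc = list(samples.index[(samples.species == "D3") & (samples.treatment == "INOC")])
res = de.de_contrast(counts, mock, inoc, label="D3:INOC-vs-MOCK")

planted = truth.index[truth["true_lfc_inoc_D3"] != 0]
detected = res.loc[res.index.intersection(planted), "fdr"] < 0.05
null_calls = res.loc[res.index.difference(planted), "fdr"] < 0.05

print(f"genes tested after CPM filter: {len(res)}")
print(f"common dispersion estimate:    {res['dispersion'].iloc[0]:.4f} (true 0.05)")
print(f"DEGs at FDR < 0.05:            {(res['direction'] != 'ns').sum()} "
      f"({(res['direction'] == 'up').sum()} up, {(res['direction'] == 'down').sum()} down)")
print(f"power on planted |log2FC|=2:   {detected.mean():.3f}")
print(f"false positives among nulls:   {null_calls.mean():.4f}")
print("\nThe conditional exact test sums group counts, conditions on their "
      "total, and rejects by minimum likelihood; at 3 vs 3 replicates it "
      "recovers essentially all two-fold changes at this depth.")
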