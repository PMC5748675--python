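"""Signed co-expression network: modules, eigengenes, trait links, hubs.

Builds a planted-block expression matrix, picks the soft-threshold power by
the scale-free topology criterion, detects modules on TOM dissimilarity,
and relates module eigengenes to a trait generated from the first block.
"""

import numpy as np
import pandas as pd

from triadexpr import coexpnet as cx

rng = np.random.default_rng(6)
rows, truth = [], []
for b, size in enumerate([60, 60, 60, 60, 60]):
    z = rng.normal(size=50)
    for _ in range(size):
        rows.append(np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(size=50))
        truth.append(b)
expr = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(len(rows))],
                    columns=[f"s{j:02d}" for j in range(50)])

beta, fit = cx.pick_soft_threshold(expr)
adj = cx.signed_adjacency(expr, beta)
tom = cx.tom_similarity(adj)
labels = cx.detect_modules(1 - tom, min_module_size=30)
ms = cx.compute_eigengenes(expr, labels)

print(f"soft-threshold power chosen: beta = {beta} "
      f"(scale-free fit target reached: {fit.attrs['target_reached']})")
print("module sizes:", labels.value_counts().to_dict())
print("variance explained by eigengenes:",
      {m: round(v, 2) for m, v in ms.var_explained.items()})

# trait generated from the first planted block's eigengene plus noise
e = ms.eigengenes.iloc[0]
trait = (e - e.mean()) / e.std(ddof=1) + rng.normal(0, 0.3, size=len(e))
traits = pd.DataFrame({"had_ratio": trait}, index=expr.columns)
cor = cx.module_trait_cor(ms.eigengenes, traits, p_threshold=0.01)
print("\nmodule-trait correlations:")
print(cor.round(4).to_string(index=False))

gs, mm = cx.gene_significance_and_mm(expr, ms.eigengenes, traits["had_ratio"])
hubs = cx.select_hub_genes(gs, mm, labels, gs_min=0.7, mm_min=0.7)
print(f"\nhub genes at (GS > 0.7, MM > 0.7): {len(hubs)}, "
      f"all in {hubs['module'].unique().tolist()}")
print("\nOnly the trait-generating module correlates with the trait, and "
      "its members dominate the hub list - the pattern used to nominate "
      "candidate genes for a phenotype.")
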