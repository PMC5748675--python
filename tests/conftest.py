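import numpy as np
import pandas as pd
import pytest

from triadexpr.synthdata import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_refs():
    """Three short homoeologue pairs with known diagnostic positions."""
    rng = np.random.default_rng(42)

    def seq(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    def substitute(s, pos):
        repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
        out = list(s)
        for p in pos:
            out[p] = repl[out[p]]
        return "".join(out)

    d3_a, d3_b, d3_c = seq(128), seq(128), seq(128)
    return {
        "geneA": {"D3": d3_a, "D4": substitute(d3_a, [10, 50])},
        "geneB": {"D3": d3_b, "D4": substitute(d3_b, [33])},
        "geneC": {"D3": d3_c, "D4": d3_c},  # identical homoeologues
    }


@pytest.fixture(scope="session")
def null_counts():
    """Counts with no planted effects: mu = 100, phi = 0.1, no modules."""
    cfg = SimConfig(
        n_genes=2000,
        category_fractions={},
        inoculation_de_fraction=0.0,
        baseline_log2_mean=(np.log2(100.0), 0.0),
        dispersion=0.1,
        n_modules=0,
        seed=11,
    )
    return simulate_counts(cfg)


def group_samples(samples: pd.DataFrame, species: str, treatment: str) -> list[str]:
    sel = (samples["species"] == species) & (samples["treatment"] == treatment)
    return list(samples.index[sel])
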