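"""Hypergeometric overrepresentation testing of gene sets.

Tests whether an annotation term's members are overrepresented in a query
gene set (a DEG list or a co-expression module) relative to a background
universe, with Benjamini–Hochberg adjustment within each ontology class.
The annotation is user-supplied (two-column gene/term TSV plus term
metadata); no live ontology database is consulted, and parent-term
propagation is expected to have been applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

ONTOLOGY_CLASSES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class EnrichmentRecord:
    x: int  # query genes carrying the term
    n: int  # query size
    K: int  # term size in the universe
    N: int  # universe size
    fold: float
    p: float


def hypergeom_overrep(query, term_members, universe) -> EnrichmentRecord:
    """One-sided hypergeometric overrepresentation test.

    p = sum_{i = x..min(n, K)} C(K, i) C(N-K, n-i) / C(N, n), the upper
    tail at the observed overlap x; fold = (x/n) / (K/N).
    """
    universe = set(universe)
    query = set(query)
    term = set(term_members)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if not term <= universe:
        raise ValueError("term members must be a subset of the universe")
    N, n, K = len(universe), len(query), len(term)
    x = len(query & term)
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    fold = (x / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentRecord(x=x, n=n, K=K, N=N, fold=fold, p=min(p, 1.0))


def enrich_table(
    query,
    annotation: pd.DataFrame,
    universe,
    correction: str = "BH",
) -> pd.DataFrame:
    """Per-term overrepresentation table, BH-adjusted within ontology class.

    ``annotation`` columns: ``gene``, ``term`` and optionally ``ontology``
    (one of the three GO classes; absent -> a single class) and ``name``.
    Returns rows sorted by ascending adjusted then raw p.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    query = set(query)
    universe = set(universe)
    if not query:
        import warnings

        warnings.warn("empty query; returning empty table")
        return pd.DataFrame(
            columns=["term", "name", "ontology", "x", "n", "K", "N", "fold", "p", "fdr"]
        )
    ann = annotation[annotation["gene"].isin(universe)]
    if "ontology" not in ann.columns:
        ann = ann.assign(ontology="all")
    names = (
        ann.drop_duplicates("term").set_index("term")["name"]
        if "name" in ann.columns
        else pd.Series(dtype=object)
    )
    rows = []
    for (onto, term), members in ann.groupby(["ontology", "term"])["gene"]:
        rec = hypergeom_overrep(query, set(members), universe)
        rows.append(
            {
                "term": term,
                "name": names.get(term, term),
                "ontology": onto,
                "x": rec.x,
                "n": rec.n,
                "K": rec.K,
                "N": rec.N,
                "fold": rec.fold,
                "p": rec.p,
            }
        )
    table = pd.DataFrame(rows)
    if correction == "BH":
        table["fdr"] = 1.0
        for onto, idx in table.groupby("ontology").groups.items():
            table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table.sort_values(["fdr", "p"], kind="mergesort").reset_index(drop=True)
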