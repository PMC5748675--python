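"""Twelve-category expression-level dominance classification.

Each gene's allopolyploid (T2) total expression is compared with both
diploid progenitors (D3, D4) and the progenitors with each other, giving
a sign triple (s1, s2, s3) = (T2 vs D3, T2 vs D4, D3 vs D4) with each
component in {+1, 0, -1} derived from FDR-thresholded differential
expression calls. The 27 possible triples map onto the classical twelve
roman-numeral categories covering additivity, expression-level dominance
toward either parent, and transgressive up/down expression; triples that
match no category (e.g. a "dominance" pattern without parental
divergence) are ambiguous, and the all-zero triple is no-change.
Silencing and novel-expression calls use raw counts: silencing is absence
of expression in all allopolyploid accessions of a gene expressed in at
least one diploid accession; novel expression is the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

Sign = int  # -1, 0, +1

#: (s1, s2, s3) -> (functional class, roman numeral, dominant parent)
CLASS_TABLE: dict[tuple[Sign, Sign, Sign], tuple[str, str, str]] = {
    (0, 0, 0): ("no_change", "none", "none"),
    # additivity: T2 strictly between diverged parents
    (-1, +1, +1): ("additivity", "I", "none"),   # D3 > T2 > D4
    (+1, -1, -1): ("additivity", "XII", "none"),  # D4 > T2 > D3
    # dominance: T2 equals one parent, parents diverged
    (0, +1, +1): ("dominance_high_parent", "II", "D3"),   # T2 = D3, D3 high
    (+1, 0, -1): ("dominance_high_parent", "IV", "D4"),   # T2 = D4, D4 high
    (-1, 0, +1): ("dominance_low_parent", "IX", "D4"),    # T2 = D4, D4 low
    (0, -1, -1): ("dominance_low_parent", "XI", "D3"),    # T2 = D3, D3 low
    # transgressive: T2 above / below both parents
    (+1, +1, 0): ("transgressive_up", "III", "none"),
    (+1, +1, +1): ("transgressive_up", "VII", "none"),
    (+1, +1, -1): ("transgressive_up", "X", "none"),
    (-1, -1, 0): ("transgressive_down", "VI", "none"),
    (-1, -1, +1): ("transgressive_down", "VIII", "none"),
    (-1, -1, -1): ("transgressive_down", "V", "none"),
}


@dataclass
class DominanceCall:
    functional_class: str
    roman: str
    dominant_parent: str


def classify(s1: Sign, s2: Sign, s3: Sign) -> DominanceCall:
    """Map one sign triple to its dominance category.

    ``s1`` is the direction of T2 vs D3 (+1 = T2 higher), ``s2`` of T2 vs
    D4, ``s3`` of D3 vs D4. Triples outside the twelve categories and
    no-change are ambiguous.
    """
    for s in (s1, s2, s3):
        if s not in (-1, 0, 1):
            raise ValueError(f"invalid sign {s!r}; must be -1, 0 or +1")
    cls, roman, parent = CLASS_TABLE.get((s1, s2, s3), ("ambiguous", "none", "none"))
    return DominanceCall(cls, roman, parent)


def signs_from_de(
    de_t2_d3: pd.DataFrame, de_t2_d4: pd.DataFrame, de_d3_d4: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Derive per-gene sign triples from three DE tables.

    Contrast orientation: each table's log2fc must be the *first-named*
    group over the second, i.e. T2 over D3, T2 over D4, D3 over D4.
    Only genes present in all three tables (i.e. passing the expression
    filter in every pairwise comparison) are returned.
    """
    genes = de_t2_d3.index.intersection(de_t2_d4.index).intersection(de_d3_d4.index)

    def sign(df: pd.DataFrame) -> pd.Series:
        sig = df.loc[genes, "fdr"] < alpha
        pos = df.loc[genes, "log2fc"] > 0
        return (sig * (pos * 2 - 1)).astype(int)

    return pd.DataFrame({"s1": sign(de_t2_d3), "s2": sign(de_t2_d4), "s3": sign(de_d3_d4)})


def classify_genes(signs: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`classify` over a gene x (s1,s2,s3) table."""
    calls = [classify(*row) for row in signs[["s1", "s2", "s3"]].itertuples(index=False)]
    return pd.DataFrame(
        {
            "functional_class": [c.functional_class for c in calls],
            "roman": [c.roman for c in calls],
            "dominant_parent": [c.dominant_parent for c in calls],
        },
        index=signs.index,
    )


def call_silencing_novel(
    counts: pd.DataFrame, samples: pd.DataFrame, expressed_threshold: int = 1
) -> pd.DataFrame:
    """Flag silenced and novel-expression genes from raw counts.

    silenced: below threshold in all T2 accessions and at or above it in at
    least one accession of at least one diploid. novel: at or above the
    threshold in at least one T2 accession while below it in every accession
    of both diploids. Computed per treatment.
    """
    out = []
    for tr, sub in samples.groupby("treatment"):
        cols = {sp: sub.index[sub["species"] == sp] for sp in ("D3", "D4", "T2")}
        t2 = counts[cols["T2"]]
        d3 = counts[cols["D3"]]
        d4 = counts[cols["D4"]]
        thr = expressed_threshold
        t2_off = (t2 < thr).all(axis=1)
        t2_on = (t2 >= thr).any(axis=1)
        dip_on = (d3 >= thr).any(axis=1) | (d4 >= thr).any(axis=1)
        dip_off = (d3 < thr).all(axis=1) & (d4 < thr).all(axis=1)
        out.append(
            pd.DataFrame(
                {
                    "treatment": tr,
                    "silenced": t2_off & dip_on,
                    "novel": t2_on & dip_off,
                },
                index=counts.index,
            )
        )
    return pd.concat(out).rename_axis("gene")


ROMANS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")


def summarize_categories(calls: pd.DataFrame, gene_subset=None) -> pd.DataFrame:
    """Count genes per roman/functional category, with II+IV and XI+IX sums.

    ``calls`` is a classify_genes output (optionally with a ``treatment``
    column; if present, summaries are per treatment). ``gene_subset``
    restricts to a gene list, e.g. the genes passing the expression filter
    in one treatment's three-species comparison.
    """
    df = calls if gene_subset is None else calls.loc[calls.index.intersection(gene_subset)]

    def _one(d: pd.DataFrame) -> pd.Series:
        row = {r: int((d["roman"] == r).sum()) for r in ROMANS}
        for cls in (
            "no_change",
            "additivity",
            "dominance_high_parent",
            "dominance_low_parent",
            "transgressive_up",
            "transgressive_down",
            "ambiguous",
        ):
            row[cls] = int((d["functional_class"] == cls).sum())
        row["II+IV"] = row["II"] + row["IV"]
        row["XI+IX"] = row["XI"] + row["IX"]
        return pd.Series(row)

    if "treatment" in df.columns:
        return df.groupby("treatment").apply(_one, include_groups=False)
    return _one(df).to_frame("count").T
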