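"""Subgenome assignment of allopolyploid reads by preferential match.

Homoeologous transcript pairs from the two diploid progenitors (D3, D4)
are colinear and differ by substitutions; an allopolyploid read is placed
ungapped on both homoeologues via a shared k-mer seed index and assigned
to the subgenome with strictly fewer mismatches. Ties between subgenomes
are ambiguous; ties between *genes* (or no acceptable placement) are
unmapped. Per-gene homoeologue counts, transcriptome-wide usage
percentages and a paired inoculation-effect t-test sit on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

SUBGENOMES = ("D3", "D4")


@dataclass
class AssignmentResult:
    read: str
    subgenome: str  # D3 | D4 | ambiguous | unmapped | rejected
    gene: str | None
    mismatches_d3: int | None
    mismatches_d4: int | None


class KmerIndex:
    """Exact k-mer seed index over both subgenomes' reference transcripts.

    Homoeologue pairs must share gene ids and have equal lengths so that a
    placement on one subgenome defines the matching window on the other.
    """

    def __init__(self, references: Mapping[str, Mapping[str, str]], k: int = 21):
        if not references:
            raise ValueError("empty reference set")
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.refs: dict[str, dict[str, np.ndarray]] = {}
        self.seeds: dict[bytes, list[tuple[str, str, int]]] = {}
        seen: set[tuple[str, str]] = set()
        for gid, pair in references.items():
            for sub in SUBGENOMES:
                if sub not in pair:
                    raise ValueError(f"gene {gid!r} lacks a {sub} homoeologue")
                if (gid, sub) in seen:
                    raise ValueError(f"duplicate gene/subgenome pair ({gid}, {sub})")
                seen.add((gid, sub))
            d3, d4 = pair["D3"], pair["D4"]
            if len(d3) != len(d4):
                raise ValueError(f"homoeologues of {gid!r} differ in length")
            if len(d3) < k:
                raise ValueError(f"gene {gid!r} shorter than k={k}")
            arrs = {}
            for sub in SUBGENOMES:
                seq = pair[sub].upper().encode()
                arrs[sub] = np.frombuffer(seq, dtype=np.uint8)
                for off in range(len(seq) - k + 1):
                    self.seeds.setdefault(seq[off : off + k], []).append((gid, sub, off))
            self.refs[gid] = arrs

    def __len__(self) -> int:
        return sum(len(v) for v in self.seeds.values())


def build_index(references: Mapping[str, Mapping[str, str]], k: int = 21) -> KmerIndex:
    """Build the subgenome seed index from ``{gene: {"D3": seq, "D4": seq}}``."""
    return KmerIndex(references, k=k)


_VALID = frozenset(b"ACGTN")


def assign_read(
    read: str, index: KmerIndex, max_mismatch_per_100: float = 5.0, read_id: str = "read"
) -> AssignmentResult:
    """Assign one read to a subgenome by preferential ungapped match.

    Candidate placements come from exact k-mer seeds sampled along the read
    (stride k, plus the final window). Every candidate start is scored on
    *both* homoeologues of its gene — the pairs are colinear — and the best
    gene keeps the smaller of its two subgenome scores. Rules:

    * best mismatch count > ``max_mismatch_per_100`` scaled to read length,
      or no seed at all -> unmapped;
    * two genes tie for best -> unmapped (unique mapping only);
    * within the best gene, strictly fewer mismatches on one homoeologue ->
      that subgenome; equal -> ambiguous.

    Bases outside ACGTN reject the read (counted by the caller).
    """
    seq = read.upper().encode()
    if not (set(seq) <= _VALID):
        return AssignmentResult(read_id, "rejected", None, None, None)
    L = len(seq)
    k = index.k
    if L < k:
        return AssignmentResult(read_id, "unmapped", None, None, None)
    max_mm = max_mismatch_per_100 * L / 100.0
    arr = np.frombuffer(seq, dtype=np.uint8)

    # candidate (gene, start) placements from seeds at stride-k offsets
    positions = list(range(0, L - k + 1, k))
    if positions[-1] != L - k:
        positions.append(L - k)
    candidates: set[tuple[str, int]] = set()
    for pos in positions:
        for gid, _sub, off in index.seeds.get(seq[pos : pos + k], []):
            candidates.add((gid, off - pos))

    # score each placement on both subgenomes
    best: dict[str, dict[str, int]] = {}
    for gid, start in candidates:
        refs = index.refs[gid]
        if start < 0 or start + L > len(refs["D3"]):
            continue
        for sub in SUBGENOMES:
            mm = int(np.count_nonzero(refs[sub][start : start + L] != arr))
            cur = best.setdefault(gid, {})
            if sub not in cur or mm < cur[sub]:
                cur[sub] = mm
    if not best:
        return AssignmentResult(read_id, "unmapped", None, None, None)

    scored = {g: min(d.values()) for g, d in best.items()}
    top = min(scored.values())
    if top > max_mm:
        return AssignmentResult(read_id, "unmapped", None, None, None)
    winners = [g for g, s in scored.items() if s == top]
    if len(winners) > 1:
        return AssignmentResult(read_id, "unmapped", None, None, None)
    gid = winners[0]
    mm3, mm4 = best[gid]["D3"], best[gid]["D4"]
    if mm3 < mm4:
        sub = "D3"
    elif mm4 < mm3:
        sub = "D4"
    else:
        sub = "ambiguous"
    return AssignmentResult(read_id, sub, gid, mm3, mm4)


def assign_reads(
    reads: Iterable[tuple[str, str]], index: KmerIndex, max_mismatch_per_100: float = 5.0
) -> pd.DataFrame:
    """Assign many reads; returns a tidy per-read table."""
    rows = [
        assign_read(seq, index, max_mismatch_per_100, read_id=rid).__dict__
        for rid, seq in reads
    ]
    return pd.DataFrame(rows)


def count_homoeologs(
    assignments: pd.DataFrame, genes: Iterable[str], by: list[str] | None = None
) -> pd.DataFrame:
    """Sum uniquely assigned reads per gene and subgenome.

    Only D3/D4 assignments contribute to ``count_D3``/``count_D4``;
    ambiguous and unmapped reads are tallied in their own columns. ``by``
    names extra grouping columns present in ``assignments`` (e.g. accession,
    treatment); the output has one row per gene per group, zero-filled over
    the supplied gene universe.
    """
    genes = list(genes)
    known = set(genes)
    bad = set(assignments["gene"].dropna()) - known
    if bad:
        raise ValueError(f"assignments reference unknown genes: {sorted(bad)[:5]}")
    by = by or []

    def _tab(df: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(genes, name="gene"))
        for sub, col in (("D3", "count_D3"), ("D4", "count_D4"), ("ambiguous", "ambiguous")):
            sel = df[df["subgenome"] == sub]
            out[col] = sel.groupby("gene").size().reindex(genes, fill_value=0)
        out["unmapped_total"] = int((df["subgenome"] == "unmapped").sum())
        return out

    if not by:
        return _tab(assignments).reset_index()
    parts = []
    for key, df in assignments.groupby(by):
        tab = _tab(df).reset_index()
        key = key if isinstance(key, tuple) else (key,)
        for col, val in zip(by, key):
            tab[col] = val
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)


@dataclass
class UsageSummary:
    genes_used: int
    mean_percent_d3: float
    per_gene: pd.DataFrame  # gene, percent_d3


def usage_percentages(counts: pd.DataFrame) -> UsageSummary:
    """Homoeologue usage for one accession/treatment's HomoeologCounts.

    Genes with zero counts for both homoeologous copies are excluded from
    ``genes_used`` and from the mean.
    """
    total = counts["count_D3"] + counts["count_D4"]
    used = counts.loc[total > 0, ["gene", "count_D3", "count_D4"]].copy()
    if len(used) == 0:
        return UsageSummary(0, float("nan"), used.assign(percent_d3=[]))
    used["percent_d3"] = 100.0 * used["count_D3"] / (used["count_D3"] + used["count_D4"])
    return UsageSummary(len(used), float(used["percent_d3"].mean()), used[["gene", "percent_d3"]])


def paired_usage_test(mock: Mapping[str, float], inoc: Mapping[str, float]):
    """Paired t-test of inoculation effect on accession-level mean %D3 usage.

    ``mock`` and ``inoc`` map accession id -> mean percent-D3. Returns a dict
    with ``t``, ``df``, ``p`` and a ``degenerate`` flag. All differences
    exactly zero gives p = 1 (flagged); zero variance with nonzero mean gives
    infinite t and the smallest positive float as p (flagged).
    """
    acc = sorted(mock)
    if set(acc) != set(inoc):
        raise ValueError("mock and inoc must cover the same accessions")
    n = len(acc)
    if n < 2:
        raise ValueError("paired test needs at least 2 accessions")
    d = np.array([inoc[a] - mock[a] for a in acc], dtype=float)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "degenerate": True}
        t = np.inf if d.mean() > 0 else -np.inf
        return {"t": t, "df": n - 1, "p": float(np.nextafter(0.0, 1.0)), "degenerate": True}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "df": n - 1, "p": float(min(p, 1.0)), "degenerate": False}
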