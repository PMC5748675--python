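"""Signed weighted co-expression network analysis.

A from-scratch implementation of the standard weighted-network workflow:
signed adjacency a_ij = ((1 + cor_ij)/2)^beta, soft-threshold selection by
the approximate scale-free topology criterion, topological overlap (TOM),
module detection by average-linkage hierarchical clustering of TOM
dissimilarity with a static height cut and minimum module size, module
eigengenes (first principal component of the standardised module
submatrix), module–trait correlations, gene significance / module
membership, hub-gene selection, one-way eigengene ANOVA across species,
and a variance-ranked sample ordination.

Module labels follow the field's colour-name convention, with ``grey``
reserved for genes not placed in any module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GREY = "grey"

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "plum1",
)


def vst(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilising transform: log2(count / size_factor + 1).

    A stated, monotone substitute for regularised-log transforms; zero
    counts map to exactly 0.
    """
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / size_factors + 1.0)


def filter_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with missing values or zero variance across samples."""
    ok = expr.notna().all(axis=1) & (expr.std(axis=1, ddof=0) > 0)
    return expr.loc[ok]


def signed_adjacency(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + pearson(x_i, x_j)) / 2) ** beta."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sd = expr.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance genes must be filtered before adjacency")
    cor = np.corrcoef(expr.to_numpy())
    a = np.clip((1.0 + cor) / 2.0, 0.0, 1.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index for a connectivity vector.

    Connectivities are discretised into ``n_bins`` equal-width bins;
    log10 p(k) is regressed on log10 mean(k) over occupied bins and the
    index is -sign(slope) * R^2, so positive values indicate the
    decreasing power-law shape. NaN when the regression is degenerate
    (e.g. all connectivities equal).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return float("nan")
    res = stats.linregress(xs, ys)
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    target_r2: float = 0.8,
):
    """Choose the soft-threshold power by approximate scale-free topology.

    Returns ``(beta, fit_table)`` where the fit table lists the signed fit
    index and mean connectivity per candidate power. The chosen beta is the
    smallest reaching ``target_r2``; if none does, the argmax of the fit
    (flagged in the table attrs as ``target_reached = False``).
    """
    rows = []
    cor = np.corrcoef(expr.to_numpy())
    half = np.clip((1.0 + cor) / 2.0, 0.0, 1.0)
    np.fill_diagonal(half, 0.0)  # exclude self from connectivity
    for b in candidate_betas:
        a = half**b
        k = a.sum(axis=1)
        rows.append({"beta": b, "fit": scale_free_fit(k), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["fit"])
    reached = ok[ok["fit"] >= target_r2]
    if len(reached):
        beta = int(reached["beta"].iloc[0])
        table.attrs["target_reached"] = True
    else:
        beta = int(ok.loc[ok["fit"].idxmax(), "beta"]) if len(ok) else int(candidate_betas[0])
        table.attrs["target_reached"] = False
    return beta, table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, TOM_ii = 1, with k_i the whole-network connectivity of i.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = a.sum(axis=0) - 1.0
    # shared-neighbour term: (A @ A)_ij minus the u = i and u = j terms
    num = a @ a - 2.0 * a
    num = num + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom[den == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModuleSet:
    """Gene -> module partition with eigengene summaries."""

    labels: pd.Series  # gene -> colour (grey = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    var_explained: pd.Series = field(default_factory=pd.Series)
    beta: float | None = None

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 100,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The dendrogram is cut at ``cut_height`` (default 0.995 of the maximum
    merge height); clusters smaller than ``min_module_size`` go to ``grey``.
    Surviving clusters receive colour labels in decreasing size order.
    """
    genes = dissimilarity.index
    if min_module_size > len(genes):
        import warnings

        warnings.warn("min_module_size exceeds gene count; all genes grey")
        return pd.Series(GREY, index=genes, name="module")
    d = dissimilarity.to_numpy(dtype=float)
    z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    h = cut_height if cut_height is not None else 0.995 * z[:, 2].max()
    raw = fcluster(z, t=h, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    labels = pd.Series(GREY, index=genes, name="module", dtype=object)
    palette = list(MODULE_COLORS) + [f"module{i}" for i in range(len(keep))]
    for color, cl in zip(palette, sizes.loc[keep].index):
        labels[raw == cl] = color
    return labels


def _standardize(expr: pd.DataFrame) -> pd.DataFrame:
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1).replace(0.0, 1.0)
    return expr.sub(mu, axis=0).div(sd, axis=0)


def module_eigengene(expr: pd.DataFrame, module_genes) -> tuple[pd.Series, float]:
    """First principal component of a module's standardised expression.

    Returns the unit-norm per-sample eigengene (sign fixed so its mean
    correlation with member genes is non-negative) and the fraction of
    module variance it explains.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must have at least 2 genes")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = _standardize(expr.loc[module_genes]).to_numpy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    # orient toward the module: positive mean correlation with members
    if np.corrcoef(np.vstack([e, x]))[0, 1:].mean() < 0:
        e = -e
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(e, index=expr.columns, name="eigengene"), var_explained


def compute_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> ModuleSet:
    """Eigengenes for every non-grey module, ordered by decreasing size."""
    ms = ModuleSet(labels=labels)
    eg, ve = {}, {}
    for mod in ms.modules:
        genes = labels.index[labels == mod]
        eg[mod], ve[mod] = module_eigengene(expr, genes)
    ms.eigengenes = pd.DataFrame(eg).T
    ms.var_explained = pd.Series(ve, dtype=float)
    return ms


def _cor_pvalue(r: float, n: int) -> float:
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_cor(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait, with p-values.

    Rows are (module, trait) with ``r``, ``p`` (t-distribution, df = n-2)
    and a ``significant`` flag at ``p_threshold``. Samples are matched on
    the shared columns/index; zero-variance traits yield NaN, flagged False.
    """
    common = eigengenes.columns.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod, common].to_numpy(dtype=float)
        for tr in traits.columns:
            y = traits.loc[common, tr].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(e) == 0:
                rows.append({"module": mod, "trait": tr, "r": np.nan, "p": np.nan,
                             "significant": False})
                continue
            r = float(np.corrcoef(e, y)[0, 1])
            p = _cor_pvalue(r, len(common))
            rows.append({"module": mod, "trait": tr, "r": r, "p": p,
                         "significant": bool(p < p_threshold)})
    return pd.DataFrame(rows)


def gene_significance_and_mm(
    expr: pd.DataFrame, eigengenes: pd.DataFrame, trait: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Signed gene significance and module membership tables.

    GS_i = pearson(x_i, trait) over the trait's samples; MM_{i,M} =
    pearson(x_i, eigengene_M) over all samples.
    """
    common = expr.columns.intersection(trait.index)
    x = expr[common].to_numpy(dtype=float)
    y = trait.loc[common].to_numpy(dtype=float)
    gs = pd.Series(_rowwise_cor(x, y), index=expr.index, name="GS")
    mm = pd.DataFrame(index=expr.index)
    for mod in eigengenes.index:
        e = eigengenes.loc[mod, expr.columns].to_numpy(dtype=float)
        mm[mod] = _rowwise_cor(expr.to_numpy(dtype=float), e)
    return gs, mm


def _rowwise_cor(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc @ yc / denom
    return np.clip(r, -1.0, 1.0)


def select_hub_genes(
    gs: pd.Series, mm: pd.DataFrame, labels: pd.Series, gs_min: float = 0.7, mm_min: float = 0.7
) -> pd.DataFrame:
    """Hub genes: |GS| > gs_min and |MM to own module| > mm_min (strict).

    Grey genes are never hubs. Returns gene, module, GS, MM rows.
    """
    rows = []
    for gene, mod in labels.items():
        if mod == GREY or mod not in mm.columns:
            continue
        g, m = gs.get(gene, np.nan), mm.loc[gene, mod]
        if np.isfinite(g) and np.isfinite(m) and abs(g) > gs_min and abs(m) > mm_min:
            rows.append({"gene": gene, "module": mod, "GS": g, "MM": m})
    return pd.DataFrame(rows, columns=["gene", "module", "GS", "MM"])


def eigengene_anova(eigengene: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA of eigengene scores across groups (e.g. species).

    Returns F, (df_between, df_within), p; zero within-group variance with
    differing means gives infinite F, flagged degenerate.
    """
    g = groups.loc[eigengene.index]
    samples = [eigengene[g == lev].to_numpy(dtype=float) for lev in g.unique()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = sum(len(s) for s in samples)
    k = len(samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        degenerate = True
        f = np.inf if ss_between > 0 else np.nan
        p = 0.0 if ss_between > 0 else float("nan")
    else:
        degenerate = False
        f = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(f, df1, df2))
    return {"F": float(f), "df": (df1, df2), "p": p, "degenerate": degenerate}


def sample_ordination(expr: pd.DataFrame, top_n: int = 500) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the ``top_n`` most variable genes.

    Returns (scores, variance_fractions): samples x PCs coordinates and the
    fraction of variance carried by each PC (summing to 1).
    """
    if top_n > expr.shape[0]:
        raise ValueError("top_n exceeds gene count")
    top = expr.loc[expr.var(axis=1, ddof=1).nlargest(top_n).index]
    x = top.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = pd.DataFrame(
        u * s,
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    return scores, frac
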