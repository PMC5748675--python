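"""End-to-end orchestration of the comparative-transcriptomics analysis.

One config drives simulate -> homoeologue assignment -> differential
expression -> dominance classification -> co-expression network ->
enrichment, writing every stage's tables as TSV plus a JSON manifest of
files, SHA-256 checksums and parameters. Reruns with the same config and
seed reproduce the manifest checksums bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpnet, diffexpr, dominance, enrichment, homoeolog
from .synthdata import SimConfig, simulate_counts, simulate_references, simulate_reads, simulate_traits

log = logging.getLogger("triadexpr.pipeline")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    The qc block records the read-processing thresholds of the emulated
    study (minimum base quality 30, minimum read length 50) as provenance
    only: synthetic reads are pre-clean and no trimmer runs.
    """

    simulate: SimConfig = field(default_factory=SimConfig)
    qc: dict = field(default_factory=lambda: {"min_base_quality": 30, "min_read_length": 50})
    de: dict = field(default_factory=lambda: {"alpha": 0.05, "min_cpm": 1.0, "min_samples": 3})
    network: dict = field(
        default_factory=lambda: {
            "beta": "auto",
            "min_module_size": 100,
            "cut_height": None,
            "trait_p_threshold": 0.01,
            "hub_gs_min": 0.7,
            "hub_mm_min": 0.7,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)
        if not (isinstance(self.network.get("beta"), (int, float)) or self.network.get("beta") == "auto"):
            raise ValueError("network.beta must be a number or 'auto'")
        if not 0 < self.de.get("alpha", 0.05) < 1:
            raise ValueError("de.alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.setdefault("simulate", {})
        raw["simulate"].setdefault("seed", raw.get("seed", 0))
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {"parameters": _config_dict(config), "stages": {}}

    def add(self, stage: str, name: str, df: pd.DataFrame, index: bool = True) -> Path:
        path = self.outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        entry = self.data["stages"].setdefault(stage, {"files": {}})
        entry["files"][path.name] = _sha256(path)
        return path

    def time(self, stage: str, seconds: float) -> None:
        self.data["stages"].setdefault(stage, {"files": {}})["seconds"] = round(seconds, 3)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["simulate"]["category_fractions"] = dict(d["simulate"]["category_fractions"])
    return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir, config)
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("homoeolog", _stage_homoeolog),
        ("diffexpr", _stage_diffexpr),
        ("dominance", _stage_dominance),
        ("network", _stage_network),
        ("enrichment", _stage_enrichment),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            fn(config, state, man)
        except Exception as exc:  # halt with the stage name and partial manifest
            man.write()
            raise StageError(name, exc) from exc
        man.time(name, time.perf_counter() - t0)
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
    path = man.write()
    log.info("manifest written to %s", path)
    return man.data


def _stage_simulate(config: RunConfig, state: dict, man: _Manifest) -> None:
    sim = config.simulate
    counts, samples, truth = simulate_counts(sim)
    traits = simulate_traits(counts, samples, truth, seed=sim.seed + 1)
    refs, ref_truth = simulate_references(sim)
    state.update(counts=counts, samples=samples, truth=truth, traits=traits, refs=refs)
    man.add("simulate", "counts", counts)
    man.add("simulate", "samples", samples)
    man.add("simulate", "truth", truth)
    man.add("simulate", "traits", traits)
    man.add("simulate", "reference_truth", ref_truth, index=False)


def _stage_homoeolog(config: RunConfig, state: dict, man: _Manifest) -> None:
    sim = config.simulate
    index = homoeolog.build_index(state["refs"], k=21)
    # gene-level true subgenome proportions are a property of the gene, shared
    # by all libraries; each library gets its own read stream
    props = state["truth"]["true_prop_d3"].to_dict()
    parts = []
    stream = 0
    for a in range(1, sim.n_accessions_per_species + 1):
        for tr in ("MOCK", "INOC"):
            stream += 1
            reads, rtruth = simulate_reads(
                state["refs"], sim, subgenome_proportions=props, stream=stream
            )
            asn = homoeolog.assign_reads(reads, index)
            asn["accession"] = f"T2_A{a}"
            asn["treatment"] = tr
            parts.append(asn)
    assignments = pd.concat(parts, ignore_index=True)
    hcounts = homoeolog.count_homoeologs(
        assignments, state["refs"].keys(), by=["accession", "treatment"]
    )
    usage_rows = []
    usage = {"MOCK": {}, "INOC": {}}
    for (acc, tr), grp in hcounts.groupby(["accession", "treatment"]):
        s = homoeolog.usage_percentages(grp)
        usage[tr][acc] = s.mean_percent_d3
        usage_rows.append(
            {"accession": acc, "treatment": tr, "genes_used": s.genes_used,
             "mean_percent_d3": s.mean_percent_d3}
        )
    test = homoeolog.paired_usage_test(usage["MOCK"], usage["INOC"])
    state["usage_test"] = test
    man.add("homoeolog", "homoeolog_counts", hcounts, index=False)
    man.add("homoeolog", "usage_summary", pd.DataFrame(usage_rows), index=False)
    man.add("homoeolog", "usage_test", pd.DataFrame([test]), index=False)


def _contrast_samples(samples: pd.DataFrame, species: str, treatment: str) -> list[str]:
    sel = (samples["species"] == species) & (samples["treatment"] == treatment)
    return list(samples.index[sel])


def _stage_diffexpr(config: RunConfig, state: dict, man: _Manifest) -> None:
    counts, samples = state["counts"], state["samples"]
    de = config.de
    kw = dict(alpha=de["alpha"], min_cpm=de["min_cpm"], min_samples=de["min_samples"])
    within = {}
    for sp in ("D3", "D4", "T2"):
        within[sp] = diffexpr.de_contrast(
            counts,
            _contrast_samples(samples, sp, "MOCK"),
            _contrast_samples(samples, sp, "INOC"),
            label=f"{sp}:INOC-vs-MOCK",
            **kw,
        )
        man.add("diffexpr", f"de_{sp}_inoc_vs_mock", within[sp])
    between = {}
    for tr in ("MOCK", "INOC"):
        for a, b, lab in (("D3", "T2", "T2-vs-D3"), ("D4", "T2", "T2-vs-D4"), ("D4", "D3", "D3-vs-D4")):
            between[(tr, lab)] = diffexpr.de_contrast(
                counts,
                _contrast_samples(samples, a, tr),
                _contrast_samples(samples, b, tr),
                label=f"{tr}:{lab}",
                **kw,
            )
            man.add("diffexpr", f"de_{tr}_{lab.replace('-', '_')}", between[(tr, lab)])
    state["de_within"], state["de_between"] = within, between
    venn = compare_species_response(within, alpha=de["alpha"])
    man.add("diffexpr", "inoculation_response_overlap", venn, index=False)


def _stage_dominance(config: RunConfig, state: dict, man: _Manifest) -> None:
    alpha = config.de["alpha"]
    calls = []
    for tr in ("MOCK", "INOC"):
        signs = dominance.signs_from_de(
            state["de_between"][(tr, "T2-vs-D3")],
            state["de_between"][(tr, "T2-vs-D4")],
            state["de_between"][(tr, "D3-vs-D4")],
            alpha=alpha,
        )
        cl = dominance.classify_genes(signs)
        cl["treatment"] = tr
        calls.append(cl.join(signs))
    calls_df = pd.concat(calls)
    flags = dominance.call_silencing_novel(state["counts"], state["samples"])
    summary = dominance.summarize_categories(calls_df)
    state["dominance_calls"] = calls_df
    man.add("dominance", "dominance_calls", calls_df)
    man.add("dominance", "silencing_novel", flags)
    man.add("dominance", "category_summary", summary)


def _stage_network(config: RunConfig, state: dict, man: _Manifest) -> None:
    counts, samples, traits = state["counts"], state["samples"], state["traits"]
    net = config.network
    sf = diffexpr.size_factors(counts)
    expr = coexpnet.filter_expression(coexpnet.vst(counts, sf))
    if net["beta"] == "auto":
        beta, fit = coexpnet.pick_soft_threshold(expr)
    else:
        beta = float(net["beta"])
        _, fit = coexpnet.pick_soft_threshold(expr, candidate_betas=(beta,))
    adj = coexpnet.signed_adjacency(expr, beta)
    tom = coexpnet.tom_similarity(adj)
    labels = coexpnet.detect_modules(
        1.0 - tom, min_module_size=net["min_module_size"], cut_height=net["cut_height"]
    )
    ms = coexpnet.compute_eigengenes(expr, labels)
    ms.beta = beta
    state["modules"] = ms

    trait_cor = coexpnet.module_trait_cor(
        ms.eigengenes, traits, p_threshold=net["trait_p_threshold"]
    ) if not ms.eigengenes.empty else pd.DataFrame()
    gs, mm = (
        coexpnet.gene_significance_and_mm(expr, ms.eigengenes, traits["had_ratio"])
        if not ms.eigengenes.empty
        else (pd.Series(dtype=float), pd.DataFrame())
    )
    hubs = coexpnet.select_hub_genes(gs, mm, labels, net["hub_gs_min"], net["hub_mm_min"])
    state["hubs"] = hubs

    anova_rows = []
    species = samples["species"]
    for mod in ms.eigengenes.index:
        res = coexpnet.eigengene_anova(ms.eigengenes.loc[mod], species)
        anova_rows.append({"module": mod, "F": res["F"], "df1": res["df"][0],
                           "df2": res["df"][1], "p": res["p"], "degenerate": res["degenerate"]})
    scores, frac = coexpnet.sample_ordination(expr, top_n=min(500, expr.shape[0]))

    man.add("network", "soft_threshold_fit", fit, index=False)
    man.add("network", "module_labels", labels.to_frame())
    man.add("network", "eigengenes", ms.eigengenes)
    man.add("network", "module_trait_cor", trait_cor, index=False)
    man.add("network", "gene_significance", gs.to_frame())
    man.add("network", "module_membership", mm)
    man.add("network", "hub_genes", hubs, index=False)
    man.add("network", "eigengene_anova", pd.DataFrame(anova_rows), index=False)
    man.add("network", "sample_ordination", scores)


def _stage_enrichment(config: RunConfig, state: dict, man: _Manifest) -> None:
    # synthetic annotation: one term per planted module plus background terms,
    # so enrichment of detected modules against planted membership is testable
    truth, counts = state["truth"], state["counts"]
    universe = list(counts.index)
    rows = []
    for m in sorted(truth["true_module"].unique()):
        if m == 0:
            continue
        for g in truth.index[truth["true_module"] == m]:
            rows.append({"gene": g, "term": f"MOD{m:04d}", "name": f"planted module {m}",
                         "ontology": "biological_process"})
    rng = __import__("numpy").random.Generator(
        __import__("numpy").random.PCG64(config.seed + 17)
    )
    for t in range(5):  # random background terms
        for g in rng.choice(universe, size=50, replace=False):
            rows.append({"gene": g, "term": f"BG{t:04d}", "name": f"background {t}",
                         "ontology": "biological_process"})
    annotation = pd.DataFrame(rows)
    man.add("enrichment", "annotation", annotation, index=False)

    ms = state.get("modules")
    tables = []
    if ms is not None and not ms.eigengenes.empty:
        for mod in ms.modules:
            query = list(ms.labels.index[ms.labels == mod])
            tab = enrichment.enrich_table(query, annotation, universe)
            tab["module"] = mod
            tables.append(tab)
    result = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    man.add("enrichment", "module_enrichment", result, index=False)


def compare_species_response(de_within: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Venn-region counts of inoculation-responsive genes across species.

    ``de_within`` maps species -> DEResult table on a shared gene universe.
    Returns counts for all seven intersection regions, separately for up,
    down and combined DEG sets.
    """
    species = sorted(de_within)
    if len(species) != 3:
        raise ValueError("expected exactly three species")
    universes = [set(df.index) for df in de_within.values()]
    if not (universes[0] == universes[1] == universes[2]):
        raise ValueError("DE tables must share a gene universe")

    def degs(df: pd.DataFrame, directions) -> set:
        return set(df.index[df["direction"].isin(directions)])

    rows = []
    for which, dirs in (("up", ["up"]), ("down", ["down"]), ("combined", ["up", "down"])):
        sets = {sp: degs(de_within[sp], dirs) for sp in species}
        a, b, c = (sets[sp] for sp in species)
        regions = {
            f"{species[0]}_only": len(a - b - c),
            f"{species[1]}_only": len(b - a - c),
            f"{species[2]}_only": len(c - a - b),
            f"{species[0]}_{species[1]}": len((a & b) - c),
            f"{species[0]}_{species[2]}": len((a & c) - b),
            f"{species[1]}_{species[2]}": len((b & c) - a),
            "all_three": len(a & b & c),
        }
        for sp in species:
            regions[f"{sp}_total"] = len(sets[sp])
        rows.append({"direction": which, **regions})
    return pd.DataFrame(rows)
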