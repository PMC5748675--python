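"""Synthetic data generation for the diploid–diploid–allopolyploid study design.

Everything the analysis pipeline consumes can be simulated here with full
ground truth: homoeologous reference transcript pairs for the two diploid
progenitors (D3, D4), short reads of known subgenome origin for the
allopolyploid (T2), negative-binomial count matrices for the
3 species x 2 treatments x 3 accessions design with planted
additivity / dominance / transgression and inoculation-response structure,
and an accession-level nodulation trait table driven by a designated
co-expression module.

Counts are generated directly at the gene level; read simulation exists
only to exercise the homoeologue-assignment arm. All randomness derives
from ``SimConfig.seed`` via :class:`numpy.random.SeedSequence` stream
splitting, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SPECIES = ("D3", "D4", "T2")
TREATMENTS = ("MOCK", "INOC")

#: functional classes a gene can be planted with (remainder = no_change)
FUNCTIONAL_CLASSES = (
    "additivity",
    "dominance_high_parent",
    "dominance_low_parent",
    "transgressive_up",
    "transgressive_down",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults mirror the study design being emulated: three species
    (two diploid progenitors and their allopolyploid), two inoculation
    treatments, three accessions per species per treatment.

    Parameters
    ----------
    n_genes : int
        Number of genes (homoeologous pairs).
    n_accessions_per_species : int
        Biological replicates per species per treatment (study design: 3).
    category_fractions : mapping
        Proportion of genes planted in each expression-pattern class
        (see :data:`FUNCTIONAL_CLASSES`); must sum to <= 1, remainder is
        no-change.
    inoculation_de_fraction : float
        Per-species proportion of genes whose mean shifts under inoculation.
    lfc_magnitude : float
        log2 separation used both for parental divergence of planted
        pattern genes and for inoculation responses.
    baseline_log2_mean : (float, float)
        Location and scale of the per-gene Normal draw of log2 baseline
        expression (count units at nominal depth).
    dispersion : float
        NB dispersion phi >= 0 (variance = mu + phi * mu^2); 0 gives Poisson.
    library_size : float
        Expected sequencing depth per sample; realised depths are drawn
        log-normally around this with 10% CV to exercise normalisation.
    homoeolog_bias_concentration : float
        Concentration c of the symmetric Beta(c/2, c/2) from which each
        gene's true T2 subgenome (D3) proportion is drawn; large c pushes
        usage towards 50:50.
    divergence_rate : float
        Per-base substitution probability between homoeologues, in [0, 0.25].
    read_length, error_rate : int, float
        Simulated read length and per-base sequencing error probability.
    gene_length : int
        Reference transcript length (constant across genes).
    n_modules, module_size : int
        Planted co-expression modules: module m spans ``module_size`` genes
        drawn at random; module 1 is the trait-generating module.
    module_strength : float
        log2-scale loading of the shared per-sample latent factor that
        induces within-module correlation.
    n_reads_per_accession : int
        Reads simulated per T2 accession by :func:`simulate_reads`.
    """

    n_genes: int = 2000
    n_accessions_per_species: int = 3
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.04 for c in FUNCTIONAL_CLASSES}
    )
    inoculation_de_fraction: float = 0.10
    lfc_magnitude: float = 2.0
    baseline_log2_mean: tuple[float, float] = (6.5, 1.5)
    dispersion: float = 0.05
    library_size: float = 1_000_000.0
    homoeolog_bias_concentration: float = 50.0
    divergence_rate: float = 0.02
    read_length: int = 100
    error_rate: float = 0.0
    gene_length: int = 500
    n_modules: int = 5
    module_size: int = 60
    module_strength: float = 1.0
    n_reads_per_accession: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_accessions_per_species < 1:
            raise ConfigError("n_genes and n_accessions_per_species must be positive")
        fracs = dict(self.category_fractions)
        unknown = set(fracs) - set(FUNCTIONAL_CLASSES)
        if unknown:
            raise ConfigError(f"unknown functional classes: {sorted(unknown)}")
        if any(not 0.0 <= f <= 1.0 for f in fracs.values()):
            raise ConfigError("category fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigError("category fractions must sum to <= 1")
        if not 0.0 <= self.inoculation_de_fraction <= 1.0:
            raise ConfigError("inoculation_de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 0.0 <= self.divergence_rate <= 0.25:
            raise ConfigError("divergence_rate must lie in [0, 0.25]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.gene_length < self.read_length:
            raise ConfigError("gene_length must be >= read_length")
        if self.homoeolog_bias_concentration <= 0:
            raise ConfigError("homoeolog_bias_concentration must be positive")

    # Stage-specific child generators: one fixed stream per stage (and
    # optional substream, e.g. one per simulated accession) so that
    # regenerating reads does not perturb the count matrix.
    def rng(self, stage: str, stream: int = 0) -> np.random.Generator:
        order = {"references": 0, "reads": 1, "counts": 2, "traits": 3}
        ss = np.random.SeedSequence(self.seed, spawn_key=(order[stage], stream))
        return np.random.Generator(np.random.PCG64(ss))


def _gene_ids(n: int) -> list[str]:
    return [f"gene{g:05d}" for g in range(n)]


# ---------------------------------------------------------------------------
# references and reads
# ---------------------------------------------------------------------------

def simulate_references(config: SimConfig):
    """Simulate homoeologous reference pairs for the two progenitors.

    For each gene a random D3 transcript is drawn and the D4 homoeologue is
    derived from it by substituting each base independently with probability
    ``divergence_rate``, so the pair differ at Binomial(L, d) positions.

    Returns
    -------
    references : dict
        ``{gene_id: {"D3": str, "D4": str}}``.
    truth : pandas.DataFrame
        One row per gene: ``gene``, ``n_diverged``, ``diverged_positions``
        (comma-joined 0-based positions).
    """
    rng = config.rng("references")
    L = config.gene_length
    refs: dict[str, dict[str, str]] = {}
    rows = []
    for gid in _gene_ids(config.n_genes):
        d3 = _BASES[rng.integers(0, 4, size=L)]
        mask = rng.random(L) < config.divergence_rate
        d4 = d3.copy()
        if mask.any():
            # substitute to one of the three other bases, uniformly
            shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            d4[mask] = _BASES[(np.searchsorted(_BASES, d4[mask]) + shift) % 4]
        refs[gid] = {"D3": d3.tobytes().decode(), "D4": d4.tobytes().decode()}
        pos = np.flatnonzero(mask)
        rows.append((gid, len(pos), ",".join(map(str, pos))))
    truth = pd.DataFrame(rows, columns=["gene", "n_diverged", "diverged_positions"])
    return refs, truth


def references_to_fasta(references, path_d3, path_d4) -> None:
    """Write the homoeologue pairs as one FASTA per subgenome (Biopython)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    for sub, path in (("D3", path_d3), ("D4", path_d4)):
        recs = [
            SeqRecord(Seq(seqs[sub]), id=gid, description="")
            for gid, seqs in references.items()
        ]
        seqio_write(recs, str(path), "fasta")


def simulate_reads(
    references,
    config: SimConfig,
    n_reads: int | None = None,
    subgenome_proportions: Mapping[str, float] | None = None,
    stream: int = 0,
):
    """Simulate single-end allopolyploid reads of known subgenome origin.

    Reads are drawn uniformly across genes (each gene equally likely unless
    ``subgenome_proportions`` is given per gene), a subgenome is chosen from
    the gene's true D3 proportion, the start position is uniform, and each
    base is flipped to a different base with probability ``error_rate``.
    Read names carry no truth; the side table does. ``stream`` selects an
    independent substream of the read RNG (one per simulated library).

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` a DataFrame with columns
    ``read``, ``gene``, ``subgenome``, ``start``, ``n_errors``.
    """
    if not references:
        raise ValueError("empty reference set")
    rng = config.rng("reads", stream=stream)
    genes = sorted(references)
    n = n_reads if n_reads is not None else config.n_reads_per_accession
    c = config.homoeolog_bias_concentration
    if subgenome_proportions is None:
        prop_d3 = {g: rng.beta(c / 2.0, c / 2.0) for g in genes}
    else:
        prop_d3 = dict(subgenome_proportions)

    rl = config.read_length
    gene_idx = rng.integers(0, len(genes), size=n)
    u_sub = rng.random(n)
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n):
        gid = genes[gene_idx[i]]
        sub = "D3" if u_sub[i] < prop_d3[gid] else "D4"
        ref = references[gid][sub]
        start = int(rng.integers(0, len(ref) - rl + 1))
        arr = np.frombuffer(ref[start : start + rl].encode(), dtype=np.uint8).copy()
        errs = rng.random(rl) < config.error_rate
        n_err = int(errs.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            arr[errs] = _BASES[(np.searchsorted(_BASES, arr[errs]) + shift) % 4]
        rid = f"read{i:07d}"
        reads.append((rid, arr.tobytes().decode()))
        rows.append((rid, gid, sub, start, n_err))
    truth = pd.DataFrame(rows, columns=["read", "gene", "subgenome", "start", "n_errors"])
    return reads, truth


def reads_to_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write reads as FASTQ (Phred+33, constant Q40 qualities)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for tr in TREATMENTS:
            for a in range(1, config.n_accessions_per_species + 1):
                rows.append(
                    {
                        "sample": f"{sp}_{tr}_A{a}",
                        "species": sp,
                        "treatment": tr,
                        "accession": f"{sp}_A{a}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(config: SimConfig):
    """Simulate the full 3 species x 2 treatments x n accessions count matrix.

    Per-gene NB means are built on the log2 scale from a baseline draw, then

    * planted pattern genes separate the parents by ``lfc_magnitude`` (which
      parent is high is random) and set the allopolyploid mean to:
      midparent (arithmetic mean of parental means) for additivity, the
      high/low parent's mean for dominance, or max(parents) * 2**lfc /
      min(parents) * 2**-lfc for transgressive up/down;
    * inoculation-responsive genes shift the mean by +/- ``lfc_magnitude``
      in their designated species under INOC;
    * module member genes share a per-sample latent factor (loading
      ``module_strength`` on the log2 scale) to create co-expression blocks.

    Counts are NB(mean * depth_j / library_size, phi) with depth_j
    log-normal around ``library_size`` (CV 10%).

    Returns ``(counts, samples, truth)``: genes x samples integer DataFrame,
    sample sheet, and the per-gene ground-truth table.
    """
    rng = config.rng("counts")
    n_g = config.n_genes
    genes = _gene_ids(n_g)
    samples = _sample_sheet(config)
    n_s = len(samples)

    # functional classes
    classes = np.array(["no_change"] * n_g, dtype=object)
    order = rng.permutation(n_g)
    pos = 0
    for cls in FUNCTIONAL_CLASSES:
        k = int(round(dict(config.category_fractions).get(cls, 0.0) * n_g))
        classes[order[pos : pos + k]] = cls
        pos += k

    loc, scale = config.baseline_log2_mean
    base = rng.normal(loc, scale, size=n_g)
    lfc = config.lfc_magnitude
    high_parent = np.where(rng.random(n_g) < 0.5, "D3", "D4")

    # per-species baseline log2 means (before inoculation shifts)
    log_mu = {sp: base.copy() for sp in SPECIES}
    patterned = classes != "no_change"
    hi = np.where(high_parent == "D3", "D3", "D4")
    for g in np.flatnonzero(patterned):
        h, l = (hi[g], "D4" if hi[g] == "D3" else "D3")
        log_mu[h][g] = base[g] + lfc / 2.0
        log_mu[l][g] = base[g] - lfc / 2.0
        mu_h, mu_l = 2.0 ** log_mu[h][g], 2.0 ** log_mu[l][g]
        cls = classes[g]
        if cls == "additivity":
            t2 = (mu_h + mu_l) / 2.0
        elif cls == "dominance_high_parent":
            t2 = mu_h
        elif cls == "dominance_low_parent":
            t2 = mu_l
        elif cls == "transgressive_up":
            t2 = mu_h * 2.0**lfc
        else:  # transgressive_down
            t2 = mu_l * 2.0**-lfc
        log_mu["T2"][g] = np.log2(t2)

    # inoculation responses, chosen independently per species
    inoc_lfc = {sp: np.zeros(n_g) for sp in SPECIES}
    for sp in SPECIES:
        resp = rng.random(n_g) < config.inoculation_de_fraction
        sign = np.where(rng.random(n_g) < 0.5, 1.0, -1.0)
        inoc_lfc[sp] = np.where(resp, sign * lfc, 0.0)

    # planted co-expression modules on genes not used for patterns, so module
    # recovery is not confounded with species effects
    module = np.zeros(n_g, dtype=int)  # 0 = none
    free = np.flatnonzero(~patterned)
    need = config.n_modules * config.module_size
    chosen = rng.permutation(free)[: min(need, len(free))]
    for m in range(config.n_modules):
        module[chosen[m * config.module_size : (m + 1) * config.module_size]] = m + 1
    latent = rng.normal(0.0, 1.0, size=(config.n_modules, n_s))

    # true T2 subgenome proportion (shared stream with the counts stage; read
    # simulation draws its own unless proportions are passed through)
    c = config.homoeolog_bias_concentration
    prop_d3 = rng.beta(c / 2.0, c / 2.0, size=n_g)

    depth = rng.lognormal(
        mean=np.log(config.library_size) - 0.5 * np.log(1.01), sigma=np.sqrt(np.log(1.01)), size=n_s
    )  # mean = library_size, CV ~= 10%
    depth_factor = depth / config.library_size

    log2mu = np.empty((n_g, n_s))
    for j, (sname, srow) in enumerate(samples.iterrows()):
        sp, tr = srow["species"], srow["treatment"]
        col = log_mu[sp].copy()
        if tr == "INOC":
            col = col + inoc_lfc[sp]
        memb = module > 0
        col[memb] = col[memb] + config.module_strength * latent[module[memb] - 1, j]
        log2mu[:, j] = col

    mu = 2.0**log2mu * depth_factor[None, :]
    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_class": classes,
            "high_parent": np.where(patterned, high_parent, "none"),
            "true_lfc_inoc_D3": inoc_lfc["D3"],
            "true_lfc_inoc_D4": inoc_lfc["D4"],
            "true_lfc_inoc_T2": inoc_lfc["T2"],
            "true_prop_d3": prop_d3,
            "true_module": module,
            "baseline_log2_mean": base,
        }
    ).set_index("gene")
    truth.attrs["trait_module"] = 1
    truth.attrs["depths"] = depth
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

#: target correlations of the secondary nodulation traits with the HAD ratio
TRAIT_CORS = {"nodule_mass": 0.8, "nodule_number": 0.7, "percent_nodulated": 0.6}


def simulate_traits(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    truth: pd.DataFrame,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Simulate the accession-level nodulation trait table.

    The root-hair deformation (HAD) ratio is a linear function of the
    trait-generating module's mean standardised expression in the inoculated
    samples plus Gaussian noise; nodule mass, nodule number and percent
    nodulated are built with fixed target correlations to HAD
    (:data:`TRAIT_CORS`).

    Returns a DataFrame indexed by inoculated sample id with the four traits.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    m = truth.attrs.get("trait_module", 1)
    members = truth.index[truth["true_module"] == m]
    if len(members) == 0:
        raise ValueError("no genes in the designated trait-generating module")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    inoc = samples.index[samples["treatment"] == "INOC"]
    # library-size-normalised log expression of module members
    lib = counts[inoc].sum(axis=0).astype(float)
    expr = np.log2(counts.loc[members, inoc] / (lib / lib.mean()) + 1.0)
    z = expr.sub(expr.mean(axis=1), axis=0)
    sd = expr.std(axis=1, ddof=1)
    z = z.div(sd.replace(0.0, 1.0), axis=0)
    score = z.mean(axis=0)  # per inoculated sample

    had = 2.0 + 1.0 * score + rng.normal(0.0, noise_sd, size=len(inoc))
    zhad = (had - had.mean()) / (had.std(ddof=1) if had.std(ddof=1) > 0 else 1.0)
    traits = pd.DataFrame({"had_ratio": had}, index=inoc)
    for name, rho in TRAIT_CORS.items():
        eps = rng.normal(0.0, 1.0, size=len(inoc))
        traits[name] = rho * zhad + np.sqrt(1.0 - rho**2) * eps
    traits.index.name = "sample"
    return traits
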