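"""Synthetic data generators matching the statistical structure the
downstream inference assumes.

Three community regimes are generated:

* **Neutral** metacommunities sample the stationary Sloan distribution
  directly -- each taxon's local relative abundance is Beta(Nm p_i,
  Nm (1 - p_i)) and N individuals are then drawn multinomially -- so the
  occurrence frequencies converge to the neutral-model prediction and a
  downstream fit should recover the planted migration rate.
* **Selection-structured** metacommunities place a Brownian-motion trait on
  a unit-depth pure-birth (Yule) tree and weight each taxon at each site by
  a Gaussian environmental filter around the site's environment value;
  homogeneous mode gives all sites the same environment (phylogenetically
  clustered, low-turnover communities), variable mode splits sites into two
  environment clusters (high between-cluster turnover).
* **Genome communities** plant per-taxon life-history traits (genome size,
  16S copy number, GC, transposase count, ribosomal codon bias as a target
  ENC-prime) and emit the gene catalog, single-copy-marker coverages and
  read summaries the trait estimators consume, together with the planted
  abundance-weighted community averages for closed-loop testing.

Chemistry tables draw each variable uniformly and independently within the
observed per-region ranges for the Yangtze River Estuary (YRE) and East
China Sea (ECS).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import GeneCatalog, MarkerCoverage, OtuTable, ValidationError
from .traits import enc_prime, _synonymous_families

DEFAULT_MARKER_IDS = tuple(f"SCM{i:02d}" for i in range(1, 36))


# ---------------------------------------------------------------------------
# Metacommunity abundance helpers
# ---------------------------------------------------------------------------

def logseries_abundances(n_taxa: int, x: float = 0.998) -> np.ndarray:
    """Ranked log-series metacommunity relative abundances (p_i ~ x^i / i)."""
    ranks = np.arange(1, n_taxa + 1)
    p = x**ranks / ranks
    return p / p.sum()


# ---------------------------------------------------------------------------
# Neutral (Sloan) metacommunities
# ---------------------------------------------------------------------------

@dataclass
class NeutralSimSpec:
    n_sites: int
    n_taxa: int
    n_individuals: int           # N, individuals per local community
    m: float                     # migration probability in (0, 1]
    metacommunity_abundances: np.ndarray | None = None  # default: log-series
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.m <= 1.0:
            raise ValidationError(f"migration rate m must be in (0, 1], got {self.m}")
        if self.n_individuals < 1:
            raise ValidationError("N must be >= 1")
        if self.metacommunity_abundances is None:
            self.metacommunity_abundances = logseries_abundances(self.n_taxa)
        else:
            self.metacommunity_abundances = np.asarray(self.metacommunity_abundances, float)
            if len(self.metacommunity_abundances) != self.n_taxa:
                raise ValidationError("metacommunity abundance vector length != n_taxa")
            if not np.isclose(self.metacommunity_abundances.sum(), 1.0):
                raise ValidationError("metacommunity abundances must sum to 1")


def simulate_neutral_metacommunity(spec: NeutralSimSpec) -> OtuTable:
    """Draw local communities from the stationary Sloan neutral distribution."""
    rng = np.random.default_rng(spec.seed)
    p = spec.metacommunity_abundances
    nm = spec.n_individuals * spec.m
    a = nm * p
    b = nm * (1.0 - p)
    counts = np.zeros((spec.n_sites, spec.n_taxa), dtype=np.int64)
    for s in range(spec.n_sites):
        x = rng.beta(a, b)
        total = x.sum()
        if total == 0:  # pathological tiny-Nm draw; retry within the stream
            x = p
            total = 1.0
        counts[s] = rng.multinomial(spec.n_individuals, x / total)
    table = pd.DataFrame(
        counts,
        index=[f"S{s:03d}" for s in range(spec.n_sites)],
        columns=[f"OTU{t:04d}" for t in range(spec.n_taxa)],
    )
    return OtuTable(table)


# ---------------------------------------------------------------------------
# Pure-birth trees and selection-structured metacommunities
# ---------------------------------------------------------------------------

def yule_tree(n_taxa: int, seed: int = 0, prefix: str = "OTU") -> TreeNode:
    """Pure-birth tree with exponential waiting times, rescaled to unit depth."""
    if n_taxa < 2:
        raise ValidationError("a tree needs >= 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    tips: list[tuple[TreeNode, float]] = []  # (node, birth time)
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        tips.append((child, 0.0))
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / len(tips))
        idx = rng.integers(len(tips))
        node, birth = tips.pop(idx)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            tips.append((child, t))
    depth = t + rng.exponential(1.0 / n_taxa)
    for node, birth in tips:
        node.length = depth - birth
    for i, tip in enumerate(root.tips()):
        tip.name = f"{prefix}{i:04d}"
    for node in root.traverse(include_self=False):
        node.length /= depth
    return root


def brownian_traits(
    tree: TreeNode, rate: float, seed: int = 0, burst: float = 0.0
) -> dict[str, float]:
    """Brownian-motion trait values at the tips.

    ``burst`` > 0 applies an early-burst rate decay ``rate * exp(-burst * t)``
    with ``t`` the depth from the root, concentrating trait divergence on
    deep branches.  That strengthens phylogenetic niche conservatism: taxa
    with similar traits are then close relatives rather than convergent
    members of distant clades.  ``burst=0`` is plain Brownian motion.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    depths: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        t0 = depths[id(node.parent)]
        t1 = t0 + node.length
        depths[id(node)] = t1
        if burst > 0:
            var = rate * (np.exp(-burst * t0) - np.exp(-burst * t1)) / burst
        else:
            var = rate * node.length
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, np.sqrt(var))
    return {tip.name: values[id(tip)] for tip in tree.tips()}


@dataclass
class SelectionSimSpec:
    n_sites: int
    n_taxa: int
    mode: str = "homogeneous"          # or "variable"
    filter_width: float = 0.1          # Gaussian filter sd on the trait scale
    trait_rate: float = 1.0            # Brownian-motion rate on the unit-depth tree
    trait_burst: float = 5.0           # early-burst decay (phylogenetic conservatism)
    drift_sd: float = 2.0              # lognormal site-level abundance noise
    n_individuals: int = 100
    env_values: np.ndarray | None = None  # default set from the trait spread
    tree: TreeNode | None = None          # default: fresh Yule tree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "variable"):
            raise ValidationError(f"mode must be homogeneous or variable, got {self.mode!r}")
        if self.filter_width <= 0:
            raise ValidationError("filter_width must be positive")
        if self.env_values is not None:
            env = np.asarray(self.env_values, float)
            if len(env) != self.n_sites:
                raise ValidationError("env_values length != n_sites")
            if self.mode == "homogeneous" and len(np.unique(env)) != 1:
                raise ValidationError("homogeneous mode requires identical env values")
            if self.mode == "variable" and len(np.unique(env)) < 2:
                raise ValidationError("variable mode requires >= 2 distinct env clusters")
            self.env_values = env


def simulate_selection_metacommunity(spec: SelectionSimSpec) -> tuple[OtuTable, TreeNode]:
    """Environmentally filtered communities on a phylogenetically conserved trait."""
    tree = spec.tree if spec.tree is not None else yule_tree(spec.n_taxa, seed=spec.seed)
    tip_names = [t.name for t in tree.tips()]
    if len(tip_names) != spec.n_taxa:
        raise ValidationError(
            f"tree has {len(tip_names)} tips but spec.n_taxa = {spec.n_taxa}"
        )
    traits = brownian_traits(tree, spec.trait_rate, seed=spec.seed + 1, burst=spec.trait_burst)
    trait_vec = np.array([traits[name] for name in tip_names])
    # standardize so filter_width and env_values are in trait-sd units
    trait_vec = (trait_vec - trait_vec.mean()) / trait_vec.std()
    if spec.env_values is None:
        if spec.mode == "homogeneous":
            env = np.full(spec.n_sites, np.median(trait_vec))
        else:
            lo, hi = np.quantile(trait_vec, [0.2, 0.8])
            env = np.where(np.arange(spec.n_sites) % 2 == 0, lo, hi)
    else:
        env = spec.env_values
    rng = np.random.default_rng(spec.seed + 2)
    counts = np.zeros((spec.n_sites, spec.n_taxa), dtype=np.int64)
    for s in range(spec.n_sites):
        w = np.exp(-((env[s] - trait_vec) ** 2) / (2.0 * spec.filter_width**2))
        if spec.drift_sd > 0:  # ecological drift: site-level abundance noise
            w = w * np.exp(rng.normal(0.0, spec.drift_sd, size=spec.n_taxa))
        if w.sum() == 0:
            raise ValidationError("selection filter left no viable taxa; widen filter_width")
        counts[s] = rng.multinomial(spec.n_individuals, w / w.sum())
    table = pd.DataFrame(
        counts, index=[f"S{s:03d}" for s in range(spec.n_sites)], columns=tip_names
    )
    return OtuTable(table), tree


# ---------------------------------------------------------------------------
# Genome communities with planted life-history traits
# ---------------------------------------------------------------------------

@dataclass
class GenomeCommunitySpec:
    genome_size: np.ndarray         # bp, per taxon
    rrna16s_copies: np.ndarray      # integer copies >= 1, per taxon
    gc: np.ndarray                  # fraction in (0, 1), per taxon
    transposase_genes: np.ndarray   # counts, per taxon
    ribo_enc_target: np.ndarray     # target ENC-prime in [20, 61], per taxon
    relative_abundance: np.ndarray  # sums to 1
    coverage_dispersion: float = 0.0  # CV of per-gene coverage noise
    depth_scale: float = 50.0         # community sequencing depth multiplier
    n_ribo_genes: int = 10
    n_other_genes: int = 20
    gene_codons: int = 300            # CDS length in codons
    marker_ids: tuple[str, ...] = DEFAULT_MARKER_IDS
    marker_length: int = 900
    rrna_length: int = 1500
    transposase_length: int = 950
    seed: int = 0

    def __post_init__(self) -> None:
        arrays = {
            "genome_size": self.genome_size,
            "rrna16s_copies": self.rrna16s_copies,
            "gc": self.gc,
            "transposase_genes": self.transposase_genes,
            "ribo_enc_target": self.ribo_enc_target,
            "relative_abundance": self.relative_abundance,
        }
        n = None
        for name, arr in arrays.items():
            arr = np.asarray(arr, float)
            setattr(self, name, arr)
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != {n}")
        if self.coverage_dispersion < 0:
            raise ValidationError("coverage dispersion must be >= 0")
        if not np.isclose(self.relative_abundance.sum(), 1.0):
            raise ValidationError("relative abundances must sum to 1")
        if ((self.gc <= 0) | (self.gc >= 1)).any():
            raise ValidationError("gc must be in (0, 1)")
        if (self.rrna16s_copies < 1).any():
            raise ValidationError("each genome needs >= 1 rRNA copy")
        if ((self.ribo_enc_target < 20) | (self.ribo_enc_target > 61)).any():
            raise ValidationError("ENC-prime targets must lie in [20, 61]")

    @property
    def n_taxa(self) -> int:
        return len(self.relative_abundance)


@dataclass
class GenomeCommunitySim:
    catalog: GeneCatalog
    markers: MarkerCoverage
    total_bp: float       # coverage-weighted read bp
    gc_fraction: float    # read-pool GC
    planted: dict[str, float] = field(default_factory=dict)


class _CodonSampler:
    """Two-regime codon sampler: preferred codons get extra probability q.

    Base within-family codon probabilities follow the taxon's GC content;
    the preferred-codon mass q is tuned by bisection until a long probe gene
    realizes the target ENC-prime within +-0.5.
    """

    def __init__(self, gc: float, seed: int, genetic_code: int = 11):
        self.families = _synonymous_families(genetic_code)
        self.aas = sorted(self.families)
        rng = np.random.default_rng(seed)
        base = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
        self.base_probs = {}
        self.preferred = {}
        for aa in self.aas:
            codons = sorted(self.families[aa])
            w = np.array([base[c[0]] * base[c[1]] * base[c[2]] for c in codons])
            self.base_probs[aa] = (codons, w / w.sum())
            self.preferred[aa] = int(rng.integers(len(codons)))

    def codon_probs(self, aa: str, q: float) -> tuple[list[str], np.ndarray]:
        codons, base = self.base_probs[aa]
        probs = (1.0 - q) * base
        probs[self.preferred[aa]] += q
        return codons, probs

    def gene(self, q: float, n_codons: int, rng: np.random.Generator) -> str:
        aa_seq = rng.choice(self.aas, size=n_codons)
        parts = []
        for aa in aa_seq:
            codons, probs = self.codon_probs(aa, q)
            parts.append(codons[rng.choice(len(codons), p=probs)])
        return "".join(parts)

    def tune_q(self, target_enc: float, probe_codons: int = 3000, tol: float = 0.5) -> float:
        """Bisection on q so a probe gene's realized ENC-prime hits the target."""

        def realized(q: float) -> float:
            probe_rng = np.random.default_rng(12345)  # common random numbers
            return enc_prime(self.gene(q, probe_codons, probe_rng), min_codons=100)

        lo, hi = 0.0, 0.999
        if realized(lo) <= target_enc + tol:
            return lo
        if realized(hi) >= target_enc - tol:
            return hi
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            val = realized(mid)
            if abs(val - target_enc) <= tol * 0.5:
                return mid
            if val > target_enc:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def simulate_genome_community(spec: GenomeCommunitySpec) -> GenomeCommunitySim:
    """Generate the metagenome summaries of a community with known traits."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_taxa
    a = spec.relative_abundance
    depths = spec.depth_scale * a

    def noisy(depth: float, size: int) -> np.ndarray:
        if spec.coverage_dispersion == 0:
            return np.full(size, depth)
        c2 = spec.coverage_dispersion**2
        return depth * rng.gamma(1.0 / c2, c2, size=size)

    records = []
    cds: dict[str, str] = {}
    marker_cov = np.zeros(len(spec.marker_ids))
    taxon_marker_mean = np.zeros(n)
    for t in range(n):
        tid = f"T{t:03d}"
        mcov = noisy(depths[t], len(spec.marker_ids))
        marker_cov += mcov
        taxon_marker_mean[t] = mcov.mean()
        for m, cov in zip(spec.marker_ids, mcov):
            records.append((f"{tid}_{m}", "other", spec.marker_length, cov))
        for k, cov in enumerate(noisy(depths[t], int(spec.rrna16s_copies[t]))):
            records.append((f"{tid}_16S_{k}", "rrna16S", spec.rrna_length, cov))
        for k, cov in enumerate(noisy(depths[t], int(spec.transposase_genes[t]))):
            records.append((f"{tid}_tnp_{k}", "transposase", spec.transposase_length, cov))
        sampler = _CodonSampler(spec.gc[t], seed=spec.seed + 1000 + t)
        q = sampler.tune_q(float(spec.ribo_enc_target[t]))
        for k, cov in enumerate(noisy(depths[t], spec.n_ribo_genes)):
            gid = f"{tid}_rpl_{k}"
            records.append((gid, "ribosomal_protein", spec.gene_codons * 3, cov))
            cds[gid] = sampler.gene(q, spec.gene_codons, rng)
        for k, cov in enumerate(noisy(depths[t], spec.n_other_genes)):
            gid = f"{tid}_cds_{k}"
            records.append((gid, "other", spec.gene_codons * 3, cov))
            cds[gid] = sampler.gene(0.0, spec.gene_codons, rng)

    genes = pd.DataFrame(records, columns=["gene_id", "label", "length", "mean_coverage"])
    catalog = GeneCatalog(sample_id=f"SIM{spec.seed}", genes=genes, cds=cds)
    markers = MarkerCoverage(
        sample_id=catalog.sample_id,
        coverage=pd.Series(marker_cov, index=list(spec.marker_ids)),
    )
    # read-pool summaries consistent with each taxon's realized depth
    total_bp = float(np.sum(taxon_marker_mean * spec.genome_size))
    gc_fraction = float(
        np.sum(taxon_marker_mean * spec.genome_size * spec.gc) / total_bp
    )

    annotated_bp = (
        len(spec.marker_ids) * spec.marker_length
        + spec.transposase_genes * spec.transposase_length
        + (spec.n_ribo_genes + spec.n_other_genes) * spec.gene_codons * 3
    )
    planted = {
        "avg_16s_copies": float(np.sum(a * spec.rrna16s_copies)),
        "avg_genome_size_bp": float(np.sum(a * spec.genome_size)),
        "gc_content": float(np.sum(a * spec.genome_size * spec.gc) / np.sum(a * spec.genome_size)),
        "transposase_pct": float(
            100.0
            * np.sum(a * spec.transposase_genes * spec.transposase_length)
            / np.sum(a * annotated_bp)
        ),
        "mean_enc_prime": float(np.mean(spec.ribo_enc_target)),
        "cub": float(1.0 / np.mean(spec.ribo_enc_target)),
        "genome_equivalents": float(spec.depth_scale),
    }
    return GenomeCommunitySim(
        catalog=catalog, markers=markers, total_bp=total_bp,
        gc_fraction=gc_fraction, planted=planted,
    )


# ---------------------------------------------------------------------------
# Chemistry within the observed regional ranges
# ---------------------------------------------------------------------------

#: Observed per-region ranges for overlying water (umol/L except where noted)
#: and sediments (% dry weight).  Salinity and bottom-water temperature are
#: not constrained by the survey summaries; their ranges are plausible July
#: values for each region.
CHEMISTRY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "YRE": {
        "ammonia_umol_l": (7.43, 15.21),
        "nitrite_umol_l": (0.29, 2.21),
        "nitrate_umol_l": (1.29, 129.21),
        "phosphate_umol_l": (0.05, 3.19),
        "silicate_umol_l": (14.27, 118.29),
        "chl_a_ug_l": (0.12, 0.95),
        "do_mg_l": (0.59, 4.34),
        "salinity": (18.0, 31.0),
        "temperature_c": (22.0, 28.0),
        "toc_pct": (0.63, 2.87),
        "tn_pct": (0.15, 0.49),
    },
    "ECS": {
        "ammonia_umol_l": (0.07, 2.36),
        "nitrite_umol_l": (0.20, 0.48),
        "nitrate_umol_l": (1.02, 4.97),
        "phosphate_umol_l": (0.02, 0.33),
        "silicate_umol_l": (0.25, 12.06),
        "chl_a_ug_l": (0.20, 0.65),
        "do_mg_l": (3.0, 10.4),
        "salinity": (30.0, 34.5),
        "temperature_c": (18.0, 24.0),
        "toc_pct": (0.06, 1.10),
        "tn_pct": (0.05, 0.20),
    },
}

WATER_VARS = (
    "chl_a_ug_l", "do_mg_l", "ammonia_umol_l", "nitrite_umol_l", "nitrate_umol_l",
    "phosphate_umol_l", "silicate_umol_l", "salinity", "temperature_c",
)
SEDIMENT_VARS = ("toc_pct", "tn_pct")


def simulate_chemistry(
    region: str, n_sites: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform, independent draws of water and sediment chemistry per region."""
    if region not in CHEMISTRY_RANGES:
        raise ValidationError(
            f"unknown region {region!r}; expected one of {sorted(CHEMISTRY_RANGES)}"
        )
    rng = np.random.default_rng(seed)
    ranges = CHEMISTRY_RANGES[region]
    site_ids = [f"{region}{i:02d}" for i in range(n_sites)]
    water = {"site_id": site_ids}
    for var in WATER_VARS:
        lo, hi = ranges[var]
        water[var] = rng.uniform(lo, hi, size=n_sites)
    sediment = {"site_id": site_ids}
    for var in SEDIMENT_VARS:
        lo, hi = ranges[var]
        sediment[var] = rng.uniform(lo, hi, size=n_sites)
    water_df = pd.DataFrame(water)
    water_df["do_saturation_pct"] = np.nan  # computed from T/S unless measured
    return water_df, pd.DataFrame(sediment)
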