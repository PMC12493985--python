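"""Diversity, niche breadth, dissimilarity, distance-decay, phylogenetic
distance, and thresholded co-occurrence networks from OTU tables.

Alpha diversity uses the standard estimators: observed richness, the
bias-corrected Chao1 (``S_obs + F1(F1-1)/(2(F2+1))``), Shannon entropy in
nats and the Gini-Simpson index ``1 - sum(p^2)``.  Levins niche breadth for
OTU j is ``B_j = 1 / sum_i P_ij^2`` where ``P_ij`` is the share of OTU j's
total found at site i, so ``B_j`` runs from 1 (single-site specialist) to
the number of sites (perfectly even generalist); ``Bcom`` is its unweighted
mean over OTUs.  Co-occurrence networks keep the top-k most abundant OTUs
and retain Spearman correlations passing both a coefficient cutoff and a
Benjamini-Hochberg-corrected significance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity import alpha as skbio_alpha
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable, SiteRecord, ValidationError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable, shannon_base: float = np.e) -> pd.DataFrame:
    """Per-site observed richness, Chao1 (bias-corrected), Shannon, Simpson."""
    rows = []
    for site in table.sites:
        counts = table.counts.loc[site].to_numpy()
        rows.append(
            {
                "site_id": site,
                "observed_richness": int(skbio_alpha.sobs(counts)),
                "chao1": float(skbio_alpha.chao1(counts, bias_corrected=True)),
                "shannon": float(skbio_alpha.shannon(counts, base=shannon_base)),
                "simpson": float(skbio_alpha.simpson(counts)),
            }
        )
    return pd.DataFrame(rows)


def chao1_classic(counts: np.ndarray) -> float:
    """Classical (non-bias-corrected) Chao1; undefined at F2 = 0."""
    return float(skbio_alpha.chao1(counts, bias_corrected=False))


# ---------------------------------------------------------------------------
# Niche breadth
# ---------------------------------------------------------------------------

@dataclass
class NicheBreadthResult:
    b: pd.Series           # per-OTU Levins breadth
    bcom: float            # community-level mean breadth
    excluded: list[str] = field(default_factory=list)  # zero-total OTUs


def niche_breadth(table: OtuTable) -> NicheBreadthResult:
    """Levins habitat niche breadth per OTU and its community mean."""
    counts = table.counts
    totals = counts.sum(axis=0)
    excluded = totals.index[totals == 0].tolist()
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-total OTUs from niche breadth")
    kept = counts.loc[:, totals > 0]
    p = kept.div(kept.sum(axis=0), axis=1)  # site share of each OTU's total
    b = 1.0 / (p**2).sum(axis=0)
    return NicheBreadthResult(b=b, bcom=float(b.mean()), excluded=excluded)


# ---------------------------------------------------------------------------
# Dissimilarity and geography
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, transform: str = "relative") -> pd.DataFrame:
    """Site x site Bray-Curtis dissimilarity matrix.

    ``transform='relative'`` (default) compares relative abundances so that
    sequencing depth differences do not masquerade as turnover; ``'counts'``
    compares raw counts.
    """
    if transform not in ("counts", "relative"):
        raise ValueError(f"transform must be 'counts' or 'relative', got {transform!r}")
    data = table.relative_abundance() if transform == "relative" else table.counts
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(data.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sites, columns=table.sites)


def geographic_distance(a: SiteRecord, b: SiteRecord) -> float:
    """Great-circle (haversine) distance in km."""
    return haversine_km(a.latitude, a.longitude, b.latitude, b.longitude)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(sites: list[SiteRecord]) -> pd.DataFrame:
    ids = [s.site_id for s in sites]
    n = len(sites)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = geographic_distance(sites[i], sites[j])
    return pd.DataFrame(dm, index=ids, columns=ids)


@dataclass
class DistanceDecayFit:
    slope: float       # similarity change per km
    intercept: float
    r_squared: float
    n_pairs: int


def distance_decay(similarity: pd.DataFrame, distance_km: pd.DataFrame) -> DistanceDecayFit:
    """OLS regression of community similarity on geographic distance.

    ``similarity`` is typically ``1 - Bray-Curtis``; only upper-triangle site
    pairs enter the fit.
    """
    if list(similarity.index) != list(distance_km.index):
        raise ValidationError("similarity and distance matrices must share site order")
    iu = np.triu_indices(similarity.shape[0], k=1)
    y = similarity.to_numpy(float)[iu]
    x = distance_km.to_numpy(float)[iu]
    if len(y) < 3:
        raise ValidationError(f"distance-decay needs >= 3 site pairs, got {len(y)}")
    if np.ptp(y) == 0:  # constant similarity: flat line, no variance explained
        return DistanceDecayFit(0.0, float(y[0]), 0.0, len(y))
    fit = stats.linregress(x, y)
    return DistanceDecayFit(float(fit.slope), float(fit.intercept), float(fit.rvalue**2), len(y))


# ---------------------------------------------------------------------------
# Phylogenetic distance
# ---------------------------------------------------------------------------

def patristic_matrix(tree: TreeNode) -> pd.DataFrame:
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def phylo_distance(
    table: OtuTable, tree: TreeNode, weighting: str = "abundance"
) -> pd.Series:
    """Per-site mean pairwise phylogenetic distance (MPD).

    ``weighting='abundance'`` returns ``sum_{i!=j} p_i p_j d_ij`` over taxa
    present at the site (Rao-style quadratic entropy on patristic distances);
    ``'presence'`` returns the plain mean over distinct present-taxon pairs.
    Sites with fewer than two taxa are reported as missing.
    """
    if weighting not in ("abundance", "presence"):
        raise ValueError(f"weighting must be 'abundance' or 'presence', got {weighting!r}")
    dmat = patristic_matrix(tree)
    missing = set(table.otus) - set(dmat.index)
    if missing:
        raise ValidationError(f"tree lacks tips for OTUs: {sorted(missing)[:5]}...")
    d = dmat.loc[table.otus, table.otus].to_numpy()
    rel = table.relative_abundance().to_numpy()
    out = {}
    for i, site in enumerate(table.sites):
        present = np.flatnonzero(rel[i] > 0)
        if len(present) < 2:
            out[site] = np.nan
            continue
        sub = d[np.ix_(present, present)]
        if weighting == "abundance":
            w = rel[i, present]
            out[site] = float(w @ sub @ w)  # diagonal is zero
        else:
            iu = np.triu_indices(len(present), k=1)
            out[site] = float(sub[iu].mean())
    return pd.Series(out, name=f"mpd_{weighting}")


# ---------------------------------------------------------------------------
# Co-occurrence network
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    nodes: list[str]
    edges: pd.DataFrame  # columns: otu_a, otu_b, rho, q_value
    k: int
    rho_cutoff: float
    q_cutoff: float
    sign_mode: str


def cooccurrence_network(
    table: OtuTable,
    k: int = 1000,
    rho_cutoff: float = 0.6,
    q_cutoff: float = 0.001,
    sign_mode: str = "positive",
) -> NetworkResult:
    """Thresholded Spearman co-occurrence network over the top-k OTUs.

    OTUs are ranked by overall relative abundance (ties broken by id for
    determinism).  All retained pairs are tested; BH-FDR correction is
    applied across every tested pair; edges must pass both the correlation
    cutoff (``rho > rho_cutoff``, or ``|rho|`` with ``sign_mode='absolute'``)
    and ``q < q_cutoff``.
    """
    if k < 2:
        raise ValidationError(f"network needs k >= 2 OTUs, got k={k}")
    if sign_mode not in ("positive", "absolute"):
        raise ValueError(f"sign_mode must be 'positive' or 'absolute', got {sign_mode!r}")
    if table.n_sites < 4:
        raise ValidationError("Spearman p-values need >= 4 sites")
    mean_rel = table.relative_abundance().mean(axis=0)
    ranking = pd.DataFrame({"abund": mean_rel}).sort_values(
        ["abund"], ascending=False, kind="mergesort"
    )
    # mergesort is stable; pre-sort index lexicographically so ties break by id
    ranking = ranking.loc[sorted(ranking.index)].sort_values(
        "abund", ascending=False, kind="mergesort"
    )
    top = list(ranking.index[: min(k, table.n_otus)])
    data = table.counts[top].to_numpy(float)
    if len(top) == 2:
        rho_val, p_val = stats.spearmanr(data[:, 0], data[:, 1])
        rho = np.array([[1.0, rho_val], [rho_val, 1.0]])
        pvals = np.array([[0.0, p_val], [p_val, 0.0]])
    else:
        rho, pvals = stats.spearmanr(data)
    iu = np.triu_indices(len(top), k=1)
    flat_p = pvals[iu]
    flat_rho = rho[iu]
    _, q, _, _ = multipletests(flat_p, method="fdr_bh")
    strength = np.abs(flat_rho) if sign_mode == "absolute" else flat_rho
    keep = (strength > rho_cutoff) & (q < q_cutoff)
    a_idx, b_idx = iu[0][keep], iu[1][keep]
    edges = pd.DataFrame(
        {
            "otu_a": [top[i] for i in a_idx],
            "otu_b": [top[j] for j in b_idx],
            "rho": flat_rho[keep],
            "q_value": q[keep],
        }
    )
    # enforce undirected a < b ordering
    swap = edges["otu_a"] > edges["otu_b"]
    edges.loc[swap, ["otu_a", "otu_b"]] = edges.loc[swap, ["otu_b", "otu_a"]].to_numpy()
    return NetworkResult(
        nodes=top, edges=edges, k=k, rho_cutoff=rho_cutoff, q_cutoff=q_cutoff,
        sign_mode=sign_mode,
    )
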