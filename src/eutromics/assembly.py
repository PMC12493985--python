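"""Community assembly inference: Sloan neutral model and null models.

Neutral community model (NCM)
-----------------------------
Sloan's model predicts a taxon's occurrence frequency across local
communities from its metacommunity mean relative abundance ``p_i``:

    Freq_i = 1 - I(1/N | N m p_i, N m (1 - p_i)),

with ``I`` the regularized incomplete beta function (beta CDF), ``N`` the
number of individuals per community and ``m`` the immigration probability.
``N`` defaults to the mean per-site total count and the detection limit to
``1/N``.  ``m`` is fitted by bounded least squares on the observed
frequencies; ``Nm`` summarizes dispersal (larger = less dispersal-limited).

Null models
-----------
Phylogenetic turnover is measured by the between-community mean
nearest-taxon distance (betaMNTD); its z-score against a taxa-shuffle null
(tip labels permuted within a taxa pool) is betaNTI.  |betaNTI| > 2 flags
deterministic selection (+2 variable, -2 homogeneous).  For pairs with
|betaNTI| <= 2, the Bray-Curtis Raup-Crick metric (RC_Bray, rescaled to
[-1, 1]) separates dispersal limitation (> 0.95) from homogenizing
dispersal (< -0.95); the remainder is "undominated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skbio import TreeNode

from .containers import OtuTable, ValidationError
from .metrics import patristic_matrix

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Neutral community model
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceStats:
    per_otu: pd.DataFrame  # columns: p, freq (index: otu ids, zero-total OTUs dropped)
    n: float               # individuals per community (mean site total)
    detection_limit: float
    n_sites: int           # trials behind each freq_i (for binomial envelopes)


def occurrence_stats(table: OtuTable, detection_limit: float | None = None) -> OccurrenceStats:
    """Per-OTU mean relative abundance and detection frequency.

    ``p_i`` is the across-site mean relative abundance; ``freq_i`` the
    fraction of sites where the OTU's relative abundance reaches the
    detection limit (default ``1/N`` with ``N`` = mean site total).
    """
    if table.n_sites == 0 or table.n_otus == 0:
        raise ValidationError("empty OTU table")
    rel = table.relative_abundance()
    n = float(table.site_totals().mean())
    limit = 1.0 / n if detection_limit is None else float(detection_limit)
    p = rel.mean(axis=0)
    freq = (rel >= limit).mean(axis=0)
    df = pd.DataFrame({"p": p, "freq": freq})
    df = df[df["p"] > 0]  # taxa absent everywhere carry no information
    return OccurrenceStats(per_otu=df, n=n, detection_limit=limit, n_sites=table.n_sites)


def ncm_predict(p: np.ndarray, n: float, m: float, detection_limit: float | None = None) -> np.ndarray:
    """Predicted occurrence frequency under the neutral model."""
    limit = 1.0 / n if detection_limit is None else detection_limit
    nm = n * m
    return 1.0 - stats.beta.cdf(limit, nm * p, nm * (1.0 - p))


@dataclass
class NcmFit:
    m: float
    n: float
    nm: float
    r_squared: float
    per_otu: pd.DataFrame  # p, freq, predicted, ci_lower, ci_upper, partition
    ci_level: float
    converged: bool
    at_boundary: bool
    detection_limit: float


def ncm_fit(
    stats_in: OccurrenceStats,
    ci_level: float = 0.95,
    r2_centered: bool = True,
) -> NcmFit:
    """Fit the immigration probability m by bounded least squares.

    The sum of squared frequency residuals is minimized over
    ``m in (1e-6, 1]`` from multiple starts (the objective can be flat near
    the boundaries).  R^2 is reported against the centered total sum of
    squares by default (``r2_centered=False`` uses the non-centered form).
    Confidence bounds around the prediction are Wilson binomial envelopes at
    ``n_sites`` trials; OTUs are partitioned as above/within/below them.
    """
    df = stats_in.per_otu
    interior = ((df["freq"] > 0) & (df["freq"] < 1)).sum()
    if len(df) < 10 or interior < 1:
        raise ValidationError(
            f"NCM fit needs >= 10 informative OTUs (got {len(df)}, {interior} interior)"
        )
    p = df["p"].to_numpy()
    freq = df["freq"].to_numpy()
    n = stats_in.n
    limit = stats_in.detection_limit

    def sse(m: float) -> float:
        resid = freq - ncm_predict(p, n, m, limit)
        return float(resid @ resid)

    best = None
    converged = True
    # multi-start bounded scalar minimisation; log-spaced brackets around each start
    for lo, hi in ((1e-6, 0.05), (0.02, 0.3), (0.2, 1.0), (1e-6, 1.0)):
        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        if not res.success:
            converged = False
        if best is None or res.fun < best.fun:
            best = res
    m_hat = float(best.x)
    at_boundary = m_hat >= 1.0 - 1e-6 or m_hat <= 2e-6
    if at_boundary:
        warnings.warn(f"NCM fit at boundary m={m_hat:.3g}; estimate unreliable")

    predicted = ncm_predict(p, n, m_hat, limit)
    sse_val = float(np.sum((freq - predicted) ** 2))
    if r2_centered:
        sst = float(np.sum((freq - freq.mean()) ** 2))
    else:
        sst = float(np.sum(freq**2))
    r2 = 1.0 - sse_val / sst if sst > 0 else np.nan

    lower, upper = _wilson_envelope(predicted, stats_in, ci_level)
    partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))
    per_otu = df.assign(
        predicted=predicted, ci_lower=lower, ci_upper=upper, partition=partition
    )
    return NcmFit(
        m=m_hat, n=n, nm=n * m_hat, r_squared=r2, per_otu=per_otu,
        ci_level=ci_level, converged=converged, at_boundary=at_boundary,
        detection_limit=limit,
    )


def _wilson_envelope(predicted, stats_in, ci_level):
    # number of trials behind each frequency = number of sites
    n_trials = stats_in.n_sites
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ph = predicted
    denom = 1.0 + z**2 / n_trials
    center = (ph + z**2 / (2 * n_trials)) / denom
    half = z * np.sqrt(ph * (1 - ph) / n_trials + z**2 / (4 * n_trials**2)) / denom
    return center - half, center + half


def fit_neutral_model(table: OtuTable, ci_level: float = 0.95, **kwargs) -> NcmFit:
    """Convenience wrapper: occurrence stats + NCM fit from an OTU table."""
    st = occurrence_stats(table, kwargs.pop("detection_limit", None))
    return ncm_fit(st, ci_level=ci_level, **kwargs)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _bmntd_from_submatrix(d_ab: np.ndarray, w_a: np.ndarray, w_b: np.ndarray) -> float:
    """betaMNTD given the patristic submatrix (a-taxa x b-taxa) and weights."""
    to_b = d_ab.min(axis=1)  # each a-taxon's nearest neighbour in b
    to_a = d_ab.min(axis=0)
    return 0.5 * (float(w_a @ to_b) + float(w_b @ to_a))


def _site_profiles(table: OtuTable, weighting: str):
    rel = table.relative_abundance().to_numpy()
    profiles = []
    for i in range(table.n_sites):
        present = np.flatnonzero(rel[i] > 0)
        if len(present) == 0:
            raise ValidationError(f"site {table.sites[i]!r} has no taxa")
        if weighting == "abundance":
            w = rel[i, present]
            w = w / w.sum()
        else:
            w = np.full(len(present), 1.0 / len(present))
        profiles.append((present, w))
    return profiles


def beta_mntd(table: OtuTable, tree: TreeNode, weighting: str = "abundance") -> pd.DataFrame:
    """Pairwise between-community mean nearest-taxon distance matrix."""
    if weighting not in ("abundance", "presence"):
        raise ValueError(f"weighting must be 'abundance' or 'presence', got {weighting!r}")
    d, _ = _aligned_patristic(table, tree)
    profiles = _site_profiles(table, weighting)
    n = table.n_sites
    out = np.full((n, n), np.nan)
    for i in range(n):
        ai, wi = profiles[i]
        for j in range(i + 1, n):
            aj, wj = profiles[j]
            out[i, j] = out[j, i] = _bmntd_from_submatrix(d[np.ix_(ai, aj)], wi, wj)
    return pd.DataFrame(out, index=table.sites, columns=table.sites)


def _aligned_patristic(table: OtuTable, tree: TreeNode):
    dmat = patristic_matrix(tree)
    missing = set(table.otus) - set(dmat.index)
    if missing:
        raise ValidationError(
            f"tree lacks tips for {len(missing)} OTUs, e.g. {sorted(missing)[:5]}"
        )
    aligned = dmat.loc[table.otus, table.otus]
    return aligned.to_numpy(), list(aligned.index)


def _pair_rng(seed: int | None, i: int, j: int) -> np.random.Generator:
    """Independent substream per site pair, so results do not depend on the
    order in which pairs are visited."""
    ss = np.random.SeedSequence(0 if seed is None else seed, spawn_key=(i, j))
    return np.random.default_rng(ss)


def bnti(
    table: OtuTable,
    tree: TreeNode,
    reps: int = 999,
    seed: int | None = None,
    weighting: str = "abundance",
    pool: str = "all",
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """beta nearest-taxon index: z-score of betaMNTD against a taxa-shuffle null.

    The null permutes taxon identities across tree tips within the taxa pool.
    ``pool='all'`` (default) shuffles across every tip of the metacommunity
    tree, the framework's standard randomization -- phylogenetic clustering
    of a pair relative to the whole taxon pool is what makes homogeneous
    selection detectable.  ``pool='pair'`` restricts the shuffle to the two
    sites' union, a stricter null under which fully overlapping communities
    are degenerate (zero null spread, reported as NaN with a warning).
    ``pairs`` optionally restricts computation to the given site-index pairs.
    """
    if pool not in ("pair", "all"):
        raise ValueError(f"pool must be 'pair' or 'all', got {pool!r}")
    d, _ = _aligned_patristic(table, tree)
    profiles = _site_profiles(table, weighting)
    n = table.n_sites
    n_taxa = table.n_otus
    out = np.full((n, n), np.nan)
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    degenerate = 0
    for i, j in pairs:
        ai, wi = profiles[i]
        aj, wj = profiles[j]
        obs = _bmntd_from_submatrix(d[np.ix_(ai, aj)], wi, wj)
        if pool == "pair":
            pool_idx = np.union1d(ai, aj)
        else:
            pool_idx = np.arange(n_taxa)
        # positions of each community's taxa inside the pool
        pos_a = np.searchsorted(pool_idx, ai)
        pos_b = np.searchsorted(pool_idx, aj)
        d_pool = d[np.ix_(pool_idx, pool_idx)]
        rng = _pair_rng(seed, i, j)
        q = len(pool_idx)
        perms = np.argsort(rng.random((reps, q)), axis=1)  # reps random permutations
        # null betaMNTD, vectorized over reps
        rows = perms[:, pos_a]  # (reps, |a|)
        cols = perms[:, pos_b]  # (reps, |b|)
        sub = d_pool[rows[:, :, None], cols[:, None, :]]  # (reps, |a|, |b|)
        null = 0.5 * (sub.min(axis=2) @ wi + sub.min(axis=1) @ wj)
        sd = null.std(ddof=1)
        if sd == 0:
            degenerate += 1
            continue
        out[i, j] = out[j, i] = (obs - null.mean()) / sd
    if degenerate:
        warnings.warn(f"{degenerate} site pairs had zero null spread; betaNTI undefined")
    return pd.DataFrame(out, index=table.sites, columns=table.sites)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / denom)


def rc_bray(
    table: OtuTable,
    reps: int = 999,
    seed: int | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis dissimilarity, rescaled to [-1, 1].

    For each site pair, ``reps`` null community pairs are assembled: each
    null site keeps its observed richness and total abundance, draws that
    many taxa without replacement with probability proportional to
    metacommunity occurrence frequency, seeds each with one individual, and
    fills the rest by multinomial draws proportional to metacommunity
    relative abundance.  RC is the fraction of null Bray-Curtis values below
    the observed one (ties counted half), rescaled by ``2 (RC - 0.5)``.
    """
    if reps < 1:
        raise ValidationError(f"reps must be >= 1, got {reps}")
    counts = table.counts.to_numpy()
    n_sites, n_taxa = counts.shape
    occ = (counts > 0).sum(axis=0).astype(float)
    keep = occ > 0
    occ_w = occ[keep] / occ[keep].sum()
    rel_total = counts[:, keep].sum(axis=0).astype(float)
    ab_w = rel_total / rel_total.sum()
    sub_counts = counts[:, keep]
    richness = (sub_counts > 0).sum(axis=1)
    totals = sub_counts.sum(axis=1)
    m = sub_counts.shape[1]

    def null_site(rng: np.random.Generator, s: int) -> np.ndarray:
        chosen = rng.choice(m, size=richness[s], replace=False, p=occ_w)
        comm = np.zeros(m)
        comm[chosen] = 1.0
        fill = totals[s] - richness[s]
        if fill > 0:
            pw = ab_w[chosen] / ab_w[chosen].sum()
            comm[chosen] += rng.multinomial(fill, pw)
        return comm

    out = np.full((n_sites, n_sites), np.nan)
    if pairs is None:
        pairs = [(i, j) for i in range(n_sites) for j in range(i + 1, n_sites)]
    for i, j in pairs:
        obs = _bray_curtis_pair(sub_counts[i].astype(float), sub_counts[j].astype(float))
        rng = _pair_rng(seed, i, j)
        null = np.empty(reps)
        for r in range(reps):
            null[r] = _bray_curtis_pair(null_site(rng, i), null_site(rng, j))
        rc = (np.sum(null < obs) + 0.5 * np.sum(null == obs)) / reps
        out[i, j] = out[j, i] = 2.0 * (rc - 0.5)
    return pd.DataFrame(out, index=table.sites, columns=table.sites)


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    process_fractions: dict[str, float]
    pair_processes: pd.DataFrame  # site_a, site_b, bnti, rc, process
    n_pairs: int
    n_excluded: int = 0
    reps: int | None = None
    seed: int | None = None
    thresholds: dict = field(
        default_factory=lambda: {"bnti": BNTI_THRESHOLD, "rc": RC_THRESHOLD}
    )


def classify_processes(
    bnti_matrix: pd.DataFrame,
    rc_matrix: pd.DataFrame,
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
    reps: int | None = None,
    seed: int | None = None,
) -> AssemblyResult:
    """Assign each site pair to one of five assembly processes.

    betaNTI > +2: variable selection; < -2: homogeneous selection; otherwise
    RC_Bray > +0.95: dispersal limitation; < -0.95: homogenizing dispersal;
    else undominated.  Pairs with undefined betaNTI are excluded and counted.
    """
    if list(bnti_matrix.index) != list(rc_matrix.index):
        raise ValidationError("betaNTI and RC matrices must share site order")
    sites = list(bnti_matrix.index)
    rows = []
    excluded = 0
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            b = bnti_matrix.iat[i, j]
            r = rc_matrix.iat[i, j]
            if np.isnan(b):
                excluded += 1
                continue
            if b > bnti_threshold:
                proc = "variable_selection"
            elif b < -bnti_threshold:
                proc = "homogeneous_selection"
            elif not np.isnan(r) and r > rc_threshold:
                proc = "dispersal_limitation"
            elif not np.isnan(r) and r < -rc_threshold:
                proc = "homogenizing_dispersal"
            else:
                proc = "undominated"
            rows.append(
                {"site_a": sites[i], "site_b": sites[j], "bnti": b, "rc": r, "process": proc}
            )
    pair_df = pd.DataFrame(rows, columns=["site_a", "site_b", "bnti", "rc", "process"])
    n = len(pair_df)
    fractions = {
        proc: (float((pair_df["process"] == proc).sum()) / n if n else np.nan)
        for proc in PROCESSES
    }
    return AssemblyResult(
        process_fractions=fractions, pair_processes=pair_df, n_pairs=n,
        n_excluded=excluded, reps=reps, seed=seed,
        thresholds={"bnti": bnti_threshold, "rc": rc_threshold},
    )
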