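"""Phylogenetic and taxonomic null models for community assembly inference.

beta-MNTD quantifies phylogenetic turnover between paired communities;
beta-NTI standardizes it against a tip-shuffled null; Raup-Crick on
Bray-Curtis separates dispersal limitation from homogenizing dispersal; and
the joint classification assigns every community pair to selection,
dispersal limitation, homogenizing dispersal, or drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConsistencyError
from .io import OtuTable, relative_abundance
from .stats import MantelResult, mantel, partial_mantel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# beta-MNTD

def _beta_mntd_core(rel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Weighted beta-MNTD over all sample pairs.

    rel: (S, O) relative abundances; dist: (O, O) patristic distances.
    Pairs involving an empty community are NaN.
    """
    n = rel.shape[0]
    present = [np.flatnonzero(rel[i] > 0) for i in range(n)]
    out = np.zeros((n, n))
    for k in range(n):
        pk = present[k]
        wk = rel[k, pk]
        for m in range(k + 1, n):
            pm = present[m]
            if len(pk) == 0 or len(pm) == 0:
                out[k, m] = out[m, k] = np.nan
                continue
            sub = dist[np.ix_(pk, pm)]
            val = 0.5 * (wk @ sub.min(axis=1)
                         + rel[m, pm] @ sub.min(axis=0))
            out[k, m] = out[m, k] = val
    return out


def beta_mntd(rel_table: pd.DataFrame, phylo_dist: pd.DataFrame,
              weighted: bool = True) -> pd.DataFrame:
    """Abundance-weighted beta mean nearest taxon distance between samples.

    For samples k, m:
    0.5 * [ sum_j rel_jk * min_j' d(j, j') + sum_j rel_jm * min_j' d(j, j') ]
    with the minimum taken over taxa present in the other sample.
    """
    missing = sorted(set(rel_table.columns) - set(phylo_dist.index))
    if missing:
        raise ConsistencyError(
            f"OTUs missing from phylogenetic distances, e.g. {missing[:5]}")
    rel = rel_table.to_numpy(dtype=float)
    if not weighted:
        rel = (rel > 0).astype(float)
        sums = rel.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        rel = rel / sums
    d = phylo_dist.loc[rel_table.columns, rel_table.columns].to_numpy(dtype=float)
    mat = _beta_mntd_core(rel, d)
    ids = rel_table.index
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class BetaNtiResult:
    matrix: pd.DataFrame
    observed: pd.DataFrame
    n_null: int


def beta_nti(table: OtuTable, phylo_dist: pd.DataFrame, n_null: int = 1000,
             seed: int | None = None) -> BetaNtiResult:
    """beta-NTI: (observed beta-MNTD - null mean) / null sd, with the null
    generated by shuffling OTU identities across all tips of the phylogeny.

    Standardization is per sample pair. Pairs with zero null variance are
    reported missing.
    """
    rel_df = relative_abundance(table)
    missing = sorted(set(rel_df.columns) - set(phylo_dist.index))
    if missing:
        raise ConsistencyError(
            f"OTUs missing from phylogenetic distances, e.g. {missing[:5]}")
    all_ids = list(phylo_dist.index)
    col_idx = np.array([all_ids.index(o) for o in rel_df.columns])
    d_full = phylo_dist.to_numpy(dtype=float)
    rel = rel_df.to_numpy(dtype=float)

    obs = _beta_mntd_core(rel, d_full[np.ix_(col_idx, col_idx)])
    rng = np.random.default_rng(seed)
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    n_tips = len(all_ids)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        idx = perm[col_idx]
        null = _beta_mntd_core(rel, d_full[np.ix_(idx, idx)])
        s1 += null
        s2 += null ** 2
    mean = s1 / n_null
    var = np.maximum(s2 / n_null - mean ** 2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean) / sd
    zero_sd = (sd == 0) & ~np.eye(len(rel), dtype=bool)
    if zero_sd.any():
        logger.warning("beta_nti: %d pairs with zero null sd reported missing",
                       int(zero_sd.sum() // 2))
        bnti[zero_sd] = np.nan
    np.fill_diagonal(bnti, 0.0)
    ids = rel_df.index
    return BetaNtiResult(matrix=pd.DataFrame(bnti, index=ids, columns=ids),
                         observed=pd.DataFrame(obs, index=ids, columns=ids),
                         n_null=n_null)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis

@dataclass
class RaupCrickResult:
    matrix: pd.DataFrame
    n_null: int


def _null_community(rng, richness: int, total: int, occ_w: np.ndarray,
                    abund_w: np.ndarray) -> np.ndarray:
    """One null sample: presences drawn without replacement with probability
    proportional to occurrence frequency; remaining reads filled
    proportionally to metacommunity relative abundance."""
    n_otus = len(occ_w)
    counts = np.zeros(n_otus, dtype=np.int64)
    richness = min(richness, int((occ_w > 0).sum()))
    chosen = rng.choice(n_otus, size=richness, replace=False,
                        p=occ_w / occ_w.sum())
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        w = abund_w[chosen]
        if w.sum() <= 0:
            w = np.ones(len(chosen))
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def raup_crick_bc(table: OtuTable, n_null: int = 1000,
                  seed: int | None = None) -> RaupCrickResult:
    """Raup-Crick deviation of observed Bray-Curtis from a null that fixes
    each sample's richness and read total.

    RC = [ (#null < obs) + 0.5 * (#null == obs) ] / n_null, rescaled to
    [-1, 1]. Positive extremes: communities more different than expected
    (dispersal limitation); negative: more similar (homogenizing dispersal).
    """
    counts = table.counts
    n, n_otus = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if (richness == 0).any():
        logger.warning("raup_crick_bc: empty samples produce missing pairs")
    occ_w = (counts > 0).sum(axis=0).astype(float)
    abund_w = counts.sum(axis=0).astype(float)
    abund_w = abund_w / max(abund_w.sum(), 1.0)

    obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    for _ in range(n_null):
        null = np.zeros((n, n_otus))
        for i in range(n):
            if richness[i] == 0:
                continue
            null[i] = _null_community(rng, int(richness[i]), int(totals[i]),
                                      occ_w, abund_w)
        null_bc = squareform(pdist(null, metric="braycurtis"))
        less += null_bc < obs - 1e-12
        equal += np.abs(null_bc - obs) <= 1e-12
    rc = ((less + 0.5 * equal) / n_null) * 2.0 - 1.0
    empty = richness == 0
    rc[empty, :] = np.nan
    rc[:, empty] = np.nan
    np.fill_diagonal(rc, 0.0)
    ids = table.sample_ids
    return RaupCrickResult(matrix=pd.DataFrame(rc, index=ids, columns=ids),
                           n_null=n_null)


# ---------------------------------------------------------------------------
# process classification

@dataclass
class ProcessFractions:
    """Fractions of community turnover assigned to each assembly process."""

    fraction_selection: float
    fraction_heterogeneous_selection: float
    fraction_homogeneous_selection: float
    fraction_dispersal_limitation: float
    fraction_homogenizing_dispersal: float
    fraction_drift: float
    n_pairs: int

    @property
    def selection_to_dl_ratio(self) -> float:
        if self.fraction_dispersal_limitation == 0:
            return np.inf if self.fraction_selection > 0 else np.nan
        return self.fraction_selection / self.fraction_dispersal_limitation

    @property
    def dl_to_hd_ratio(self) -> float:
        if self.fraction_homogenizing_dispersal == 0:
            return np.inf if self.fraction_dispersal_limitation > 0 else np.nan
        return (self.fraction_dispersal_limitation
                / self.fraction_homogenizing_dispersal)

    def as_dict(self) -> dict:
        return {
            "selection": self.fraction_selection,
            "heterogeneous_selection": self.fraction_heterogeneous_selection,
            "homogeneous_selection": self.fraction_homogeneous_selection,
            "dispersal_limitation": self.fraction_dispersal_limitation,
            "homogenizing_dispersal": self.fraction_homogenizing_dispersal,
            "drift": self.fraction_drift,
            "n_pairs": self.n_pairs,
        }


def classify_pairs(bnti, rc, bnti_threshold: float = 2.0,
                   rc_threshold: float = 0.95) -> pd.Series:
    """Per-pair process labels from beta-NTI and RC_BC values (condensed
    over the upper triangle)."""
    b = bnti.to_numpy(dtype=float) if isinstance(bnti, pd.DataFrame) else np.asarray(bnti, float)
    r = rc.to_numpy(dtype=float) if isinstance(rc, pd.DataFrame) else np.asarray(rc, float)
    if b.shape != r.shape:
        raise ConsistencyError("beta-NTI and RC matrices must share shape")
    if b.ndim == 1:  # already-condensed pair values
        bv, rv = b, r
    else:
        iu = np.triu_indices(b.shape[0], k=1)
        bv, rv = b[iu], r[iu]
    labels = np.full(len(bv), "drift", dtype=object)
    labels[(np.abs(bv) <= bnti_threshold) & (rv > rc_threshold)] = \
        "dispersal_limitation"
    labels[(np.abs(bv) <= bnti_threshold) & (rv < -rc_threshold)] = \
        "homogenizing_dispersal"
    labels[bv > bnti_threshold] = "heterogeneous_selection"
    labels[bv < -bnti_threshold] = "homogeneous_selection"
    labels[~np.isfinite(bv) | ~np.isfinite(rv)] = "missing"
    return pd.Series(labels)


def classify_processes(bnti, rc, bnti_threshold: float = 2.0,
                       rc_threshold: float = 0.95) -> ProcessFractions:
    """Assign every valid sample pair to an assembly process and return the
    fractions (selection split into heterogeneous/homogeneous sub-fractions,
    reported summed as selection)."""
    labels = classify_pairs(bnti, rc, bnti_threshold, rc_threshold)
    valid = labels[labels != "missing"]
    if len(valid) == 0:
        raise ValueError("no valid sample pairs to classify")
    frac = valid.value_counts(normalize=True)
    get = lambda k: float(frac.get(k, 0.0))
    het = get("heterogeneous_selection")
    hom = get("homogeneous_selection")
    return ProcessFractions(
        fraction_selection=het + hom,
        fraction_heterogeneous_selection=het,
        fraction_homogeneous_selection=hom,
        fraction_dispersal_limitation=get("dispersal_limitation"),
        fraction_homogenizing_dispersal=get("homogenizing_dispersal"),
        fraction_drift=get("drift"),
        n_pairs=len(valid),
    )


def classify_by_stratum(bnti: pd.DataFrame, rc: pd.DataFrame,
                        groups: pd.Series, bnti_threshold: float = 2.0,
                        rc_threshold: float = 0.95) -> dict[str, ProcessFractions]:
    """Process fractions over within-group sample pairs, per group, plus an
    'all' stratum over every pair."""
    out = {"all": classify_processes(bnti, rc, bnti_threshold, rc_threshold)}
    for g in sorted(groups.unique()):
        ids = [s for s in bnti.index if groups.get(s) == g]
        if len(ids) < 2:
            continue
        out[str(g)] = classify_processes(bnti.loc[ids, ids], rc.loc[ids, ids],
                                         bnti_threshold, rc_threshold)
    return out


def bnti_env_tests(bnti: pd.DataFrame, env_dist, controls=None,
                   n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """Mantel (or partial Mantel, given controls) of the beta-NTI matrix
    against an environmental distance matrix."""
    if controls:
        return partial_mantel(bnti, env_dist, controls, n_perm=n_perm,
                              seed=seed)
    return mantel(bnti, env_dist, n_perm=n_perm, seed=seed)
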