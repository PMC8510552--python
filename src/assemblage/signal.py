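"""Phylogenetic signal in OTU niches via Mantel correlograms.

Niche values are abundance-weighted means of an environmental variable; the
correlogram tests, per phylogenetic-distance class, whether closely related
OTUs have more similar niches than expected by chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io import OtuTable, SampleMetadata, relative_abundance
from .stats import _as_matrix, value_distance

logger = logging.getLogger(__name__)


def otu_niche_values(table: OtuTable, metadata: SampleMetadata,
                     variable: str) -> pd.Series:
    """Abundance-weighted mean of ``variable`` per OTU.

    niche_j = sum_i rel_ij * env_i / sum_i rel_ij. OTUs absent from every
    sample are excluded (and logged).
    """
    env = metadata.numeric(variable)
    if not set(table.sample_ids) <= set(env.index):
        raise ConsistencyError("metadata must cover all table samples")
    rel = relative_abundance(table)
    env = env.loc[rel.index]
    weights = rel.sum(axis=0)
    present = weights > 0
    absent = weights.index[~present]
    if len(absent):
        logger.info("otu_niche_values: excluding %d all-zero OTUs", len(absent))
    niche = rel.loc[:, present].mul(env, axis=0).sum(axis=0) / weights[present]
    niche.name = f"niche_{variable}"
    return niche


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics."""

    classes: pd.DataFrame  # midpoint, n_pairs, r, p, p_corrected, significant
    n_perm: int
    alpha: float


def _sturges_classes(n_pairs: int) -> int:
    return max(int(math.ceil(1 + math.log2(max(n_pairs, 2)))), 2)


def mantel_correlogram(phylo_dist, niche_dist, n_classes: int | None = None,
                       n_perm: int = 999, seed: int | None = None,
                       alpha: float = 0.05) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Per distance class the statistic is the negated Pearson correlation
    between the niche distance matrix and the class-membership indicator
    (positive r = within-class similarity). p-values come from simultaneous
    row/column permutations of the niche matrix, one-tailed in the sign of
    the observed statistic, with progressive Holm correction across classes.
    """
    dp = _as_matrix(phylo_dist)
    dn = _as_matrix(niche_dist)
    if dp.shape != dn.shape:
        raise ConsistencyError("matrices must share shape")
    n = dp.shape[0]
    iu = np.triu_indices(n, k=1)
    vp = dp[iu]
    vn = dn[iu]
    n_pairs = len(vp)
    if n_classes is None:
        n_classes = _sturges_classes(n_pairs)
    edges = np.linspace(0.0, vp.max(), n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.digitize(vp, edges) - 1

    indicators = []
    rows = []
    for k in range(n_classes):
        mask = which == k
        if mask.sum() < 2:
            logger.info("correlogram: dropping class %d with %d pairs",
                        k, int(mask.sum()))
            continue
        indicators.append(mask.astype(float))
        rows.append({"class_index": k,
                     "midpoint": 0.5 * (edges[k] + min(edges[k + 1], vp.max())),
                     "n_pairs": int(mask.sum())})
    if not rows:
        raise ValueError("no usable distance classes")

    def class_stats(vniche: np.ndarray) -> np.ndarray:
        out = np.empty(len(indicators))
        vc = vniche - vniche.mean()
        sd_v = vc.std()
        for i, ind in enumerate(indicators):
            ic = ind - ind.mean()
            denom = sd_v * ic.std()
            out[i] = 0.0 if denom == 0 else -(vc @ ic) / len(vc) / denom
        return out

    r_obs = class_stats(vn)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(indicators))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vn_p = dn[np.ix_(perm, perm)][iu]
        r_perm = class_stats(vn_p)
        counts += np.where(r_obs >= 0, r_perm >= r_obs, r_perm <= r_obs)
    p = (counts + 1) / (n_perm + 1)

    # progressive Holm: class k corrected within the first k+1 classes
    p_corr = np.empty_like(p)
    for k in range(len(p)):
        sub = p[:k + 1]
        order = np.argsort(sub)
        adj = np.empty_like(sub)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, sub[idx] * (len(sub) - rank))
            adj[idx] = min(running, 1.0)
        p_corr[k] = adj[k]

    df = pd.DataFrame(rows)
    df["r"] = r_obs
    df["p"] = p
    df["p_corrected"] = p_corr
    df["significant"] = df["p_corrected"] < alpha
    return CorrelogramResult(classes=df, n_perm=n_perm, alpha=alpha)


def niche_signal_correlogram(table: OtuTable, metadata: SampleMetadata,
                             phylo_dist: pd.DataFrame, variable: str,
                             n_classes: int | None = None, n_perm: int = 999,
                             seed: int | None = None,
                             alpha: float = 0.05) -> CorrelogramResult:
    """Convenience wrapper: niche values -> niche distances -> correlogram,
    restricted to OTUs present in the table and the phylogeny."""
    niche = otu_niche_values(table, metadata, variable)
    shared = [o for o in niche.index if o in phylo_dist.index]
    niche = niche.loc[shared]
    nd = value_distance(niche)
    pdm = phylo_dist.loc[shared, shared]
    return mantel_correlogram(pdm, nd, n_classes=n_classes, n_perm=n_perm,
                              seed=seed, alpha=alpha)
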