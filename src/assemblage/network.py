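"""Compositional co-occurrence networks.

SparCC-style correlation inference from count data (log-ratio variances,
sparsity approximation, iterative strong-pair exclusion, bootstrap
p-values), BH-FDR adjustment, thresholded graph construction, topology
metrics, modularity-based module detection, and within-module degree /
participation-coefficient node roles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io import OtuTable, SampleMetadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SparCC

def solve_basis_variances(t_matrix: np.ndarray,
                          excluded: set[tuple[int, int]] | None = None
                          ) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    With t_ij = Var(log x_i / x_j) and the assumption that basis
    correlations are sparse, row sums of t satisfy
    ``M w = t_row`` with ``M = (D - 2) I + 1``; excluded pairs are removed
    from both sides.
    """
    t = np.asarray(t_matrix, dtype=float)
    d = t.shape[0]
    if d < 4:
        raise ValueError("basis system needs at least 4 components "
                         "(use solve_basis_variances_exact for 3)")
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_row = t.sum(axis=1)
    if excluded:
        for i, j in excluded:
            m[i, i] -= 1
            m[j, j] -= 1
            m[i, j] -= 1
            m[j, i] -= 1
            t_row[i] -= t[i, j]
            t_row[j] -= t[i, j]
    omega2 = np.linalg.solve(m, t_row)
    return np.maximum(omega2, 1e-12)


def solve_basis_variances_exact(t_matrix: np.ndarray) -> np.ndarray:
    """Closed-form basis variances for exactly 3 components under zero
    basis correlation: w_i = (t_ij + t_ik - t_jk) / 2."""
    t = np.asarray(t_matrix, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("exact solver requires a 3x3 variation matrix")
    w = np.array([
        (t[0, 1] + t[0, 2] - t[1, 2]) / 2.0,
        (t[0, 1] + t[1, 2] - t[0, 2]) / 2.0,
        (t[0, 2] + t[1, 2] - t[0, 1]) / 2.0,
    ])
    return w


def correlations_from_basis(t_matrix: np.ndarray,
                            omega2: np.ndarray) -> np.ndarray:
    """rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1]."""
    t = np.asarray(t_matrix, dtype=float)
    w = np.asarray(omega2, dtype=float)
    denom = 2.0 * np.sqrt(np.outer(w, w))
    rho = (w[:, None] + w[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var(log f_i / f_j) across samples."""
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def _sparcc_single(fractions: np.ndarray, exclusion_r: float,
                   exclusion_rounds: int) -> tuple[np.ndarray, set]:
    t = variation_matrix(fractions)
    d = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega2 = solve_basis_variances(t, excluded)
    rho = correlations_from_basis(t, omega2)
    for _ in range(exclusion_rounds):
        mask = np.abs(rho.copy())
        np.fill_diagonal(mask, 0.0)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(mask), mask.shape)
        if mask[i, j] <= exclusion_r:
            break
        excluded.add((min(i, j), max(i, j)))
        if len(excluded) > d * (d - 3) // 2:
            raise ValueError("too many excluded pairs; basis system "
                             "unsolvable — raise the exclusion threshold")
        omega2 = solve_basis_variances(t, excluded)
        rho = correlations_from_basis(t, omega2)
    return rho, excluded


def _dirichlet_fractions(counts: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Posterior Dirichlet draw of per-sample compositions (pseudocount 1)."""
    gam = rng.gamma(counts + 1.0)
    return gam / gam.sum(axis=1, keepdims=True)


@dataclass
class CorrelationResult:
    correlations: pd.DataFrame
    p_values: pd.DataFrame | None
    p_adjusted: pd.DataFrame | None
    n_iterations: int
    excluded_pairs: list[tuple[str, str]]


def sparcc(table: OtuTable, n_iter: int = 20, exclusion_r: float = 0.1,
           exclusion_rounds: int = 10, n_bootstrap: int = 100,
           seed: int | None = None) -> CorrelationResult:
    """SparCC correlations with bootstrap p-values.

    Compositions are Dirichlet-resampled ``n_iter`` times and the median
    correlation is taken. Two-sided p-values come from ``n_bootstrap`` null
    datasets in which each OTU's counts are independently permuted across
    samples, then BH-adjusted.
    """
    counts = table.counts.astype(float)
    if table.n_otus < 4:
        raise ValueError("SparCC needs at least 4 OTUs")
    rng = np.random.default_rng(seed)

    def estimate(cnt: np.ndarray, iters: int) -> tuple[np.ndarray, set]:
        rhos = []
        excl: set = set()
        for _ in range(iters):
            frac = _dirichlet_fractions(cnt, rng)
            rho, excl = _sparcc_single(frac, exclusion_r, exclusion_rounds)
            rhos.append(rho)
        return np.median(np.stack(rhos), axis=0), excl

    rho_obs, excluded = estimate(counts, n_iter)

    p_df = p_adj_df = None
    if n_bootstrap and n_bootstrap > 0:
        exceed = np.zeros_like(rho_obs)
        n, d = counts.shape
        for _ in range(n_bootstrap):
            null = np.column_stack([counts[rng.permutation(n), j]
                                    for j in range(d)])
            rho_null, _ = estimate(null, max(n_iter // 4, 1))
            exceed += np.abs(rho_null) >= np.abs(rho_obs)
        p = (exceed + 1) / (n_bootstrap + 1)
        np.fill_diagonal(p, 0.0)
        iu = np.triu_indices(d, k=1)
        adj_flat = bh_adjust(p[iu])
        p_adj = np.zeros_like(p)
        p_adj[iu] = adj_flat
        p_adj = p_adj + p_adj.T
        ids = table.otu_ids
        p_df = pd.DataFrame(p, index=ids, columns=ids)
        p_adj_df = pd.DataFrame(p_adj, index=ids, columns=ids)

    ids = table.otu_ids
    rho_df = pd.DataFrame(rho_obs, index=ids, columns=ids)
    excl_named = [(ids[i], ids[j]) for i, j in sorted(excluded)]
    return CorrelationResult(correlations=rho_df, p_values=p_df,
                             p_adjusted=p_adj_df, n_iterations=n_iter,
                             excluded_pairs=excl_named)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# network construction

@dataclass
class CoNetwork:
    graph: nx.Graph
    modules: dict[str, int] | None = None
    modularity: float | None = None
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_gml(self, path) -> None:
        g = self.graph.copy()
        if self.modules:
            nx.set_node_attributes(g, self.modules, "module")
        nx.write_gml(g, path)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "r": d["weight"],
                 "sign": d["sign"]} for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def build_network(corr: CorrelationResult, r_min: float = 0.7,
                  p_max: float = 0.01,
                  node_groups: dict[str, str] | None = None) -> CoNetwork:
    """Graph with an edge for every pair with |r| >= r_min (inclusive) and
    adjusted p < p_max (strict); isolated nodes are dropped."""
    rho = corr.correlations
    padj = corr.p_adjusted
    ids = list(rho.index)
    g = nx.Graph()
    r = rho.to_numpy()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if abs(r[a, b]) < r_min:
                continue
            if padj is not None and not padj.iloc[a, b] < p_max:
                continue
            g.add_edge(ids[a], ids[b], weight=float(r[a, b]),
                       sign=1 if r[a, b] > 0 else -1)
    if node_groups:
        nx.set_node_attributes(
            g, {n: node_groups.get(n, "") for n in g.nodes}, "group")
    if g.number_of_edges() == 0:
        warnings.warn("no edges passed the thresholds; network is empty")
    return CoNetwork(graph=g)


def balanced_subsample(metadata: SampleMetadata, group_field: str,
                       n_per_group: int, seed: int | None = None) -> list[str]:
    """Randomly select exactly ``n_per_group`` samples from each group."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for g, sub in metadata.data.groupby(group_field, sort=True):
        ids = list(sub.index)
        if len(ids) < n_per_group:
            raise ValueError(
                f"group {g!r} has {len(ids)} samples, need {n_per_group}")
        pick = rng.choice(len(ids), size=n_per_group, replace=False)
        out.extend(ids[i] for i in sorted(pick))
    return out


# ---------------------------------------------------------------------------
# topology

@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    diameter: float
    density: float
    modularity: float | None
    average_clustering: float
    average_path_length: float
    ppe: float
    pne: float
    mean_betweenness: float
    degree_assortativity: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_nodes", "n_edges", "average_degree", "diameter", "density",
            "modularity", "average_clustering", "average_path_length",
            "ppe", "pne", "mean_betweenness", "degree_assortativity")}


def topology_summary(net: CoNetwork, seed: int = 0) -> TopologySummary:
    """Table-2-style metrics on the unsigned, unweighted simple graph.

    Diameter and average path length are computed on the largest connected
    component; sign is used only for the positive/negative edge percentages.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    avg_deg = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else np.nan
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    ppe = 100.0 * pos / e if e else np.nan
    pne = 100.0 - ppe if e else np.nan
    if n == 1 or e == 0:
        diameter = apl = np.nan
    else:
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        diameter = float(nx.diameter(sub))
        apl = float(nx.average_shortest_path_length(sub))
    clustering = float(nx.average_clustering(g)) if n else np.nan
    betw = nx.betweenness_centrality(g, normalized=True)
    mean_betw = float(np.mean(list(betw.values())))
    try:
        assort = float(nx.degree_assortativity_coefficient(g))
    except (ZeroDivisionError, ValueError):
        assort = np.nan
    q = net.modularity
    if q is None and e > 0:
        _, q = detect_modules(net, seed=seed, store=False)
    return TopologySummary(
        n_nodes=n, n_edges=e, average_degree=avg_deg, diameter=diameter,
        density=density, modularity=q, average_clustering=clustering,
        average_path_length=apl, ppe=ppe, pne=pne,
        mean_betweenness=mean_betw, degree_assortativity=assort)


def detect_modules(net: CoNetwork, seed: int = 0,
                   store: bool = True) -> tuple[dict[str, int], float]:
    """Louvain-style modularity optimisation (unsigned, unweighted)."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(net.graph.edges)
    comms = nx.community.louvain_communities(g, seed=seed)
    modules = {node: idx for idx, comm in enumerate(comms) for node in comm}
    q = float(nx.community.modularity(g, comms)) if g.number_of_edges() else 0.0
    if store:
        net.modules = modules
        net.modularity = q
        net.seed = seed
    return modules, q


@dataclass
class NodeRoles:
    table: pd.DataFrame  # z, c, category per node

    def category_fractions(self) -> pd.Series:
        return self.table["category"].value_counts(normalize=True)


def node_roles(net: CoNetwork, modules: dict[str, int] | None = None,
               z_threshold: float = 2.5, c_threshold: float = 0.6) -> NodeRoles:
    """Within-module degree z and participation coefficient c per node.

    z_i = (k_ib - mean_b) / sd_b over node i's module b (z = 0 when the
    module degree variance is zero); c_i = 1 - sum_c (k_ic / k_i)^2.
    Categories partition nodes by the (z_threshold, c_threshold) quadrants.
    """
    if modules is None:
        modules = net.modules
    if modules is None:
        modules, _ = detect_modules(net)
    g = net.graph
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ConsistencyError(f"modules must cover all nodes; missing "
                               f"{missing[:5]}")
    within = {}
    for node in g.nodes:
        b = modules[node]
        within[node] = sum(1 for nb in g.neighbors(node) if modules[nb] == b)
    by_module: dict[int, list] = {}
    for node in g.nodes:
        by_module.setdefault(modules[node], []).append(within[node])
    mod_mean = {b: float(np.mean(v)) for b, v in by_module.items()}
    mod_sd = {b: float(np.std(v)) for b, v in by_module.items()}
    rows = []
    for node in g.nodes:
        b = modules[node]
        sd = mod_sd[b]
        z = 0.0 if sd == 0 else (within[node] - mod_mean[b]) / sd
        k = g.degree(node)
        if k == 0:
            c = 0.0
        else:
            links: dict[int, int] = {}
            for nb in g.neighbors(node):
                links[modules[nb]] = links.get(modules[nb], 0) + 1
            c = 1.0 - sum((kc / k) ** 2 for kc in links.values())
        if z > z_threshold:
            cat = "network hub" if c > c_threshold else "module hub"
        else:
            cat = "connector" if c > c_threshold else "peripheral"
        rows.append({"node": node, "module": b, "z": z, "c": c,
                     "category": cat})
    df = pd.DataFrame(rows).set_index("node")
    return NodeRoles(table=df)


def per_sample_subnetworks(net: CoNetwork, table: OtuTable,
                           metadata: SampleMetadata | None = None,
                           variable: str | None = None,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Induced subgraph per sample (on OTUs detected in that sample) with
    per-sample topology metrics; optionally Spearman rank correlations of
    each metric with a metadata variable."""
    shared = set(net.graph.nodes) & set(table.otu_ids)
    if not shared:
        raise ConsistencyError("network and table share no OTU ids")
    rows = []
    for sid in table.sample_ids:
        present = {o for o in shared
                   if table.data.at[sid, o] > 0}
        sub = net.graph.subgraph(present)
        if sub.number_of_nodes() == 0:
            rows.append({"sample_id": sid, "n_nodes": np.nan,
                         "n_edges": np.nan, "mean_betweenness": np.nan,
                         "degree_assortativity": np.nan})
            continue
        summ = topology_summary(CoNetwork(graph=nx.Graph(sub)), seed=seed)
        rows.append({"sample_id": sid, "n_nodes": summ.n_nodes,
                     "n_edges": summ.n_edges,
                     "mean_betweenness": summ.mean_betweenness,
                     "degree_assortativity": summ.degree_assortativity})
    df = pd.DataFrame(rows).set_index("sample_id")
    corr = None
    if metadata is not None and variable is not None:
        from scipy.stats import spearmanr
        env = metadata.numeric(variable).reindex(df.index)
        recs = []
        for col in df.columns:
            ok = df[col].notna() & env.notna()
            if ok.sum() >= 3 and df.loc[ok, col].std() > 0:
                rho, p = spearmanr(env[ok], df.loc[ok, col])
            else:
                rho, p = np.nan, np.nan
            recs.append({"metric": col, "spearman_rho": rho, "p": p})
        corr = pd.DataFrame(recs).set_index("metric")
    return df, corr
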